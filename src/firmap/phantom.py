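"""Synthetic multi-coil radial IR-LL phantom with known ground truth.

The phantom is a 2-D slice built from ellipses, each carrying a tissue label,
a true longitudinal relaxation time T1 and a proton-density amplitude M0.
Under a Look-Locker readout train (flip angle alpha, repetition TR) the
longitudinal magnetisation relaxes with the apparent constants of the
driven equilibrium,

    1/T1* = 1/T1 - ln(cos alpha)/TR,        M0* = M0 * T1*/T1,

and the sampled signal follows M(t) = M0* - (M0 + M0*) exp(-t/T1*), starting
at -M0 right after inversion and saturating at M0*.  Multiplying by smooth
complex coil sensitivities and extracting golden-angle radial spokes from the
Fourier transform of each time frame yields a dataset with exactly the
(projection, coil, readout) layout of a scanner acquisition — but with every
intermediate quantity known, so each pipeline stage has an oracle.

Two sampling modes are provided.  In ``direct`` mode the spoke values are
read off the Cartesian FFT grid at the snapped spoke coordinates, so
re-gridding them is lossless — ideal for testing the iteration itself.  In
``continuous`` mode the spokes are evaluated off-grid by an explicit discrete
-time Fourier sum and then gridded, which introduces realistic gridding
error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model_io import (
    AcquisitionMeta,
    GriddedProjections,
    InversionTimeAxis,
    ModelSeries,
    RadialKSpace,
)
from .fourier import fft2c
from .trajectory import golden_angle_sequence, grid_spoke, snap_to_grid, spoke_coords

__all__ = [
    "EllipseRegion",
    "PhantomSpec",
    "GroundTruth",
    "default_brain_spec",
    "make_ground_truth",
    "simulate_series",
    "sample_acquisition",
    "simulate_dataset",
]


@dataclass(frozen=True)
class EllipseRegion:
    """One elliptical tissue region (pixel units, 0-based center)."""

    center: tuple[float, float]  # (cy, cx)
    axes: tuple[float, float]  # (ay, ax) semi-axes
    rotation_deg: float
    label: str
    t1_ms: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.t1_ms <= 0:
            raise ValueError("t1_ms must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic acquisition.

    Later regions overwrite earlier ones where ellipses overlap.  Coil
    sensitivities are smooth complex Gaussian-weighted fields with distinct
    phases per coil, normalised so the root-sum-of-squares magnitude is 1 at
    the grid center.  ``noise_sigma`` is the standard deviation of complex
    Gaussian noise added per k-space sample.
    """

    n: int = 64
    regions: tuple[EllipseRegion, ...] = ()
    flip_deg: float = 7.0
    tr_ms: float = 6.0
    te_ms: float = 2.5
    n_coil: int = 4
    n_proj: int = 600
    n_read: int | None = None  # defaults to n
    coil_smoothness: float = 0.7  # Gaussian width as a fraction of n
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.regions:
            raise ValueError("phantom needs at least one region")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for r in self.regions:
            cy, cx = r.center
            if not (0 <= cy < self.n and 0 <= cx < self.n):
                raise ValueError(f"region {r.label!r} center outside the grid")

    @property
    def readout_points(self) -> int:
        return self.n if self.n_read is None else self.n_read

    def meta(self) -> AcquisitionMeta:
        return AcquisitionMeta(
            tr_ms=self.tr_ms,
            te_ms=self.te_ms,
            flip_deg=self.flip_deg,
            n_proj=self.n_proj,
            n_coil=self.n_coil,
            n_read=self.readout_points,
            matrix=self.n,
        )


@dataclass
class GroundTruth:
    """Per-pixel true parameter maps, coil sensitivities and ROI masks.

    Relaxation-time maps are NaN outside the object.  For any positive flip
    angle the apparent constants satisfy T1* <= T1 and M0* <= M0.
    """

    t1_ms: np.ndarray
    t1_star_ms: np.ndarray
    m0: np.ndarray
    m0_star: np.ndarray
    sensitivities: np.ndarray  # (n_coil, N, N) complex
    roi_masks: dict[str, np.ndarray] = field(default_factory=dict)
    meta: AcquisitionMeta | None = None


def apparent_relaxation(
    t1_ms: np.ndarray | float, flip_deg: float, tr_ms: float
) -> np.ndarray | float:
    """Apparent T1* of the driven equilibrium: 1/T1* = 1/T1 - ln(cos a)/TR."""
    t1 = np.asarray(t1_ms, dtype=np.float64)
    rate = 1.0 / t1 - np.log(np.cos(np.deg2rad(flip_deg))) / tr_ms
    out = 1.0 / rate
    return float(out) if np.isscalar(t1_ms) else out


def coil_sensitivities(n: int, n_coil: int, smoothness: float = 0.7) -> np.ndarray:
    """Smooth complex coil sensitivity fields, RSS-normalised to 1 at center.

    Each coil is a Gaussian magnitude bump centered outside the FOV edge at
    equally spaced angles, with a distinct constant phase plus a gentle
    linear phase ramp — enough spatial structure to exercise phase-sensitive
    combination and the per-coil refit nontrivially.
    """
    y, x = np.mgrid[0:n, 0:n].astype(np.float64)
    c = (n - 1) / 2.0
    sigma = smoothness * n
    sens = np.empty((n_coil, n, n), dtype=np.complex128)
    for i in range(n_coil):
        ang = 2.0 * np.pi * i / n_coil
        cy = c + 0.6 * n * np.sin(ang)
        cx = c + 0.6 * n * np.cos(ang)
        mag = np.exp(-(((y - cy) ** 2 + (x - cx) ** 2) / (2.0 * sigma**2)))
        phase = 0.5 * np.pi * i / max(n_coil - 1, 1) + 0.15 * np.pi * (
            np.cos(ang) * (y - c) + np.sin(ang) * (x - c)
        ) / n
        sens[i] = mag * np.exp(1j * phase)
    center = n // 2
    rss = np.sqrt(np.sum(np.abs(sens[:, center, center]) ** 2))
    return sens / rss


def _ellipse_mask(n: int, region: EllipseRegion) -> np.ndarray:
    y, x = np.mgrid[0:n, 0:n].astype(np.float64)
    cy, cx = region.center
    ay, ax = region.axes
    th = np.deg2rad(region.rotation_deg)
    dy, dx = y - cy, x - cx
    u = np.cos(th) * dx + np.sin(th) * dy
    v = -np.sin(th) * dx + np.cos(th) * dy
    return (u / ax) ** 2 + (v / ay) ** 2 <= 1.0


def make_ground_truth(spec: PhantomSpec) -> GroundTruth:
    """Rasterise the region list into ground-truth parameter maps."""
    n = spec.n
    t1 = np.full((n, n), np.nan)
    m0 = np.zeros((n, n))
    label_map = np.full((n, n), "", dtype=object)
    for region in spec.regions:  # later regions overwrite earlier ones
        inside = _ellipse_mask(n, region)
        t1[inside] = region.t1_ms
        m0[inside] = region.amplitude
        label_map[inside] = region.label

    t1_star = apparent_relaxation(t1, spec.flip_deg, spec.tr_ms)
    m0_star = np.where(np.isfinite(t1), m0 * t1_star / t1, 0.0)
    roi_masks = {r.label: label_map == r.label for r in spec.regions}
    return GroundTruth(
        t1_ms=t1,
        t1_star_ms=t1_star,
        m0=m0,
        m0_star=m0_star,
        sensitivities=coil_sensitivities(n, spec.n_coil, spec.coil_smoothness),
        roi_masks=roi_masks,
        meta=spec.meta(),
    )


def relaxation_curve(
    t_ms: np.ndarray, m0: np.ndarray, m0_star: np.ndarray, t1_star_ms: np.ndarray
) -> np.ndarray:
    """Signed IR-LL recovery M(t) = M0* - (M0 + M0*) exp(-t/T1*), broadcasting."""
    t1s_safe = np.where(np.isfinite(t1_star_ms) & (t1_star_ms > 0), t1_star_ms, 1.0)
    return m0_star - (m0 + m0_star) * np.exp(-t_ms / t1s_safe)


def simulate_series(gt: GroundTruth, times: InversionTimeAxis) -> ModelSeries:
    """Noise-free complex image series: coil sensitivity times the recovery curve."""
    t = times.t_ms[:, None, None]
    curve = relaxation_curve(t, gt.m0, gt.m0_star, gt.t1_star_ms)  # (P, N, N)
    curve = np.where(gt.m0[None] > 0, curve, 0.0)
    images = gt.sensitivities[None] * curve[:, None]  # (P, C, N, N)
    return ModelSeries(images=images)


def _dtft_spoke(image: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Unitary off-grid Fourier samples of ``image`` at continuous (ky, kx)."""
    n = image.shape[-1]
    c = n // 2
    pos = np.arange(n, dtype=np.float64) - c
    # separable phase factors: exp(-2pi i ky y / n) and exp(-2pi i kx x / n)
    ey = np.exp(-2j * np.pi * coords[:, 0:1] * pos[None] / n)  # (R, N)
    ex = np.exp(-2j * np.pi * coords[:, 1:2] * pos[None] / n)  # (R, N)
    # sum_{y,x} img[..., y, x] ey[r, y] ex[r, x], unitary scale 1/n
    tmp = np.einsum("...yx,rx->...ry", image, ex)
    return np.einsum("...ry,ry->...r", tmp, ey) / n


def sample_acquisition(
    series: ModelSeries,
    angles_deg: np.ndarray,
    meta: AcquisitionMeta,
    noise_sigma: float = 0.0,
    seed: int = 0,
    mode: str = "direct",
) -> tuple[RadialKSpace, GriddedProjections]:
    """Extract one radial spoke per time frame and coil from the series.

    ``direct`` mode samples the FFT grid at the spoke's snapped node
    coordinates (zero gridding error); ``continuous`` evaluates the spoke at
    its exact off-grid coordinates through a discrete-time Fourier sum.
    Complex Gaussian noise of standard deviation ``noise_sigma`` is added to
    every raw sample, reproducibly for a given ``seed``.
    """
    if mode not in ("direct", "continuous"):
        raise ValueError(f"unknown sampling mode {mode!r}")
    angles_deg = np.asarray(angles_deg, dtype=np.float64)
    n_proj, n_coil, n, _ = series.images.shape
    if angles_deg.shape != (n_proj,):
        raise ValueError("need exactly one spoke angle per projection")
    n_read = meta.n_read
    rng = np.random.default_rng(seed)

    samples = np.empty((n_proj, n_coil, n_read), dtype=np.complex128)
    geoms = [spoke_coords(a, n_read) for a in angles_deg]
    if mode == "direct":
        for p, geom in enumerate(geoms):
            ksp = fft2c(series.images[p])  # (C, N, N)
            idx, inside = snap_to_grid(geom, n)
            vals = np.zeros((n_coil, n_read), dtype=np.complex128)
            vals[:, inside] = ksp[:, idx[inside, 0], idx[inside, 1]]
            samples[p] = vals
    else:
        for p, geom in enumerate(geoms):
            samples[p] = _dtft_spoke(series.images[p], geom.coords)

    if noise_sigma > 0:
        noise = rng.normal(scale=noise_sigma, size=(2, n_proj, n_coil, n_read))
        samples = samples + noise[0] + 1j * noise[1]

    values = np.zeros((n_proj, n_coil, n, n), dtype=np.complex128)
    masks = np.zeros((n_proj, n, n), dtype=bool)
    for p, geom in enumerate(geoms):
        plane, mask = grid_spoke(samples[p], geom, n)
        values[p] = plane
        masks[p] = mask

    radial = RadialKSpace(samples=samples, angles_deg=angles_deg, meta=meta)
    gridded = GriddedProjections(values=values, mask=masks, meta=meta)
    return radial, gridded


def simulate_dataset(
    spec: PhantomSpec, mode: str = "direct"
) -> tuple[GroundTruth, InversionTimeAxis, RadialKSpace, GriddedProjections]:
    """One-call convenience: ground truth, time axis and sampled k-space."""
    gt = make_ground_truth(spec)
    meta = spec.meta()
    times = InversionTimeAxis.from_meta(meta)
    series = simulate_series(gt, times)
    angles = golden_angle_sequence(spec.n_proj)
    radial, gridded = sample_acquisition(
        series, angles, meta, noise_sigma=spec.noise_sigma, seed=spec.seed, mode=mode
    )
    return gt, times, radial, gridded


def default_brain_spec(
    n: int = 64,
    n_proj: int = 600,
    n_coil: int = 4,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> PhantomSpec:
    """Brain-like phantom: WM-, GM- and CSF-like tissue at 700/1400/4000 ms.

    A large white-matter-like ellipse forms the slice, a grey-matter-like
    ring region sits inside it and two small CSF-like ellipses emulate the
    ventricles; later regions overwrite earlier ones.
    """
    s = n / 64.0
    regions = (
        EllipseRegion(
            center=(32 * s, 32 * s), axes=(26 * s, 22 * s), rotation_deg=0.0,
            label="WM", t1_ms=700.0, amplitude=0.8,
        ),
        EllipseRegion(
            center=(14 * s, 32 * s), axes=(6 * s, 12 * s), rotation_deg=0.0,
            label="GM", t1_ms=1400.0, amplitude=0.9,
        ),
        EllipseRegion(
            center=(36 * s, 24 * s), axes=(9 * s, 4 * s), rotation_deg=15.0,
            label="CSF", t1_ms=4000.0, amplitude=1.0,
        ),
        EllipseRegion(
            center=(36 * s, 40 * s), axes=(9 * s, 4 * s), rotation_deg=-15.0,
            label="CSF", t1_ms=4000.0, amplitude=1.0,
        ),
    )
    return PhantomSpec(
        n=n, regions=regions, n_coil=n_coil, n_proj=n_proj,
        noise_sigma=noise_sigma, seed=seed,
    )
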