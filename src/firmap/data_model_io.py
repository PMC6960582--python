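"""Shared container types and their on-disk layouts.

All pipeline stages exchange data through the validated containers defined
here.  Datasets are stored in a single HDF5 file per dataset with one group
per container (``radial_kspace`` with ``samples``/``angles_deg`` or
``gridded_projections`` with ``values``/``mask``; acquisition metadata lives
in the group attributes).  Parameter maps are exported as single-slice NIfTI
volumes (one file per map) plus an optional CSV of ROI statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionMeta",
    "RadialKSpace",
    "GriddedProjections",
    "InversionTimeAxis",
    "ModelSeries",
    "CombinedSeries",
    "CoilPhaseMaps",
    "ParameterMaps",
    "ConvergenceLog",
    "write_dataset",
    "read_dataset",
    "export_maps",
]


class ValidationError(ValueError):
    """A container violates one of its structural invariants."""


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition parameters of a radial IR-LL measurement.

    Parameters
    ----------
    tr_ms : float
        Repetition time between successive small-angle excitations, ms.
    te_ms : float
        Echo time, ms.
    flip_deg : float
        Excitation flip angle, degrees.
    n_proj : int
        Number of radial projections (one per inversion time).
    n_coil : int
        Number of receive coils.
    n_read : int
        Readout points per spoke (even).
    matrix : int
        Reconstructed image side length N in pixels (even).
    fov_mm : float
        Field of view, mm.
    """

    tr_ms: float
    te_ms: float
    flip_deg: float
    n_proj: int
    n_coil: int
    n_read: int
    matrix: int
    fov_mm: float = 220.0

    def __post_init__(self) -> None:
        for name in ("n_proj", "n_coil", "n_read", "matrix"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValidationError(f"{name} must be a positive integer, got {v!r}")
        if self.tr_ms <= 0:
            raise ValidationError("tr_ms must be > 0")
        if self.n_read % 2:
            raise ValidationError("n_read must be even")
        if self.matrix % 2:
            raise ValidationError("matrix must be even")


@dataclass
class RadialKSpace:
    """Raw complex spoke samples, shape (n_proj, n_coil, n_read)."""

    samples: np.ndarray
    angles_deg: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.complex128)
        self.angles_deg = np.asarray(self.angles_deg, dtype=np.float64)
        m = self.meta
        expected = (m.n_proj, m.n_coil, m.n_read)
        if self.samples.shape != expected:
            raise ValidationError(
                f"samples shape {self.samples.shape} != (n_proj, n_coil, n_read) {expected}"
            )
        if self.angles_deg.shape != (m.n_proj,):
            raise ValidationError("angles_deg length must equal n_proj")
        if np.any(self.angles_deg < 0) or np.any(self.angles_deg >= 180):
            raise ValidationError("spoke angles must lie in [0, 180) degrees")


@dataclass
class GriddedProjections:
    """Per-projection, per-coil Cartesian k-space with sampling masks.

    ``values`` has shape (n_proj, n_coil, N, N) and is zero wherever ``mask``
    (shape (n_proj, N, N)) is false; the trajectory is shared by all coils,
    so one mask per projection suffices.
    """

    values: np.ndarray
    mask: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        if not (isinstance(self.values, np.ndarray) and self.values.dtype == np.complex64):
            self.values = np.asarray(self.values, dtype=np.complex128)
        self.mask = np.asarray(self.mask, dtype=bool)
        m = self.meta
        n = m.matrix
        if self.values.shape != (m.n_proj, m.n_coil, n, n):
            raise ValidationError(
                f"values shape {self.values.shape} != {(m.n_proj, m.n_coil, n, n)}"
            )
        if self.mask.shape != (m.n_proj, n, n):
            raise ValidationError(f"mask shape {self.mask.shape} != {(m.n_proj, n, n)}")
        if np.any(self.values[~np.broadcast_to(self.mask[:, None], self.values.shape)] != 0):
            raise ValidationError("values must be zero wherever mask is false")


@dataclass
class InversionTimeAxis:
    """Inversion time of each projection, ms; strictly increasing.

    The default convention assigns t_p = TE + p * TR to 0-based projection p:
    the first readout occurs one echo time after the first excitation.
    """

    t_ms: np.ndarray

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=np.float64)
        if self.t_ms.ndim != 1 or self.t_ms.size == 0:
            raise ValidationError("t_ms must be a non-empty 1-D array")
        if np.any(np.diff(self.t_ms) <= 0):
            raise ValidationError("inversion times must be strictly increasing")

    @classmethod
    def from_meta(cls, meta: AcquisitionMeta) -> "InversionTimeAxis":
        p = np.arange(meta.n_proj, dtype=np.float64)
        return cls(meta.te_ms + p * meta.tr_ms)

    def __len__(self) -> int:
        return self.t_ms.size


@dataclass
class ModelSeries:
    """Complex image-space model, shape (n_proj, n_coil, N, N)."""

    images: np.ndarray

    def __post_init__(self) -> None:
        if not (isinstance(self.images, np.ndarray) and self.images.dtype == np.complex64):
            self.images = np.asarray(self.images, dtype=np.complex128)
        if self.images.ndim != 4:
            raise ValidationError("images must be 4-D (projection, coil, y, x)")
        if not np.all(np.isfinite(self.images)):
            raise ValidationError("model images must be finite")


@dataclass
class CombinedSeries:
    """Signed real coil-combined series, shape (n_proj, N, N).

    The sign carries the inversion-recovery polarity: recovering tissue is
    negative just after the inversion pulse.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValidationError("values must be 3-D (projection, y, x)")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("combined series must be finite")


@dataclass
class CoilPhaseMaps:
    """Per-coil background phase maps in radians, shape (n_coil, N, N)."""

    phi: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=np.float64)
        if self.phi.ndim != 3:
            raise ValidationError("phi must be 3-D (coil, y, x)")


@dataclass
class ParameterMaps:
    """Per-pixel reconstruction output.

    ``t1_ms = t1_star_ms * k`` and ``k = m0 / m0_star`` wherever defined;
    pixels that were never fitted carry 0 in the amplitude maps and NaN in
    the relaxation-time maps.  ``coil_scale`` holds the per-coil complex
    steady-state amplitude from the second fitting step.
    """

    m0: np.ndarray
    m0_star: np.ndarray
    t1_star_ms: np.ndarray
    k: np.ndarray
    t1_ms: np.ndarray
    coil_scale: np.ndarray
    fitted: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("m0", "m0_star", "t1_star_ms", "k", "t1_ms"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            setattr(self, name, arr)
            if arr.ndim != 2:
                raise ValidationError(f"{name} must be a 2-D map")
            if arr.shape != self.m0.shape:
                raise ValidationError("all parameter maps must share one shape")
        self.coil_scale = np.asarray(self.coil_scale, dtype=np.complex128)
        if self.coil_scale.ndim != 3 or self.coil_scale.shape[1:] != self.m0.shape:
            raise ValidationError("coil_scale must be (n_coil, y, x)")
        if self.fitted is None:
            self.fitted = np.isfinite(self.t1_ms)
        self.fitted = np.asarray(self.fitted, dtype=bool)


@dataclass
class ConvergenceLog:
    """Per-iteration termination metric of the reconstruction loop."""

    iterations: list[int] = field(default_factory=list)
    metric: list[float] = field(default_factory=list)
    timestamps: list[float] = field(default_factory=list)

    def append(self, iteration: int, metric: float, timestamp: float) -> None:
        self.iterations.append(int(iteration))
        self.metric.append(float(metric))
        self.timestamps.append(float(timestamp))

    def __len__(self) -> int:
        return len(self.iterations)


# --------------------------------------------------------------------------
# HDF5 persistence


def _write_meta(grp: h5py.Group, meta: AcquisitionMeta) -> None:
    for f in fields(meta):
        grp.attrs[f.name] = getattr(meta, f.name)


def _read_meta(grp: h5py.Group) -> AcquisitionMeta:
    kwargs = {}
    for f in fields(AcquisitionMeta):
        if f.name not in grp.attrs:
            raise ValidationError(f"missing metadata attribute {f.name!r} in {grp.name}")
        v = grp.attrs[f.name]
        kwargs[f.name] = int(v) if f.type == "int" else float(v)
    return AcquisitionMeta(**kwargs)


def write_dataset(data: RadialKSpace | GriddedProjections, path: str | Path) -> None:
    """Write a k-space container to ``path`` as an HDF5 file (lossless)."""
    path = Path(path)
    with h5py.File(path, "w") as h5:
        if isinstance(data, RadialKSpace):
            grp = h5.create_group("radial_kspace")
            grp.create_dataset("samples", data=data.samples)
            grp.create_dataset("angles_deg", data=data.angles_deg)
        elif isinstance(data, GriddedProjections):
            grp = h5.create_group("gridded_projections")
            grp.create_dataset("values", data=data.values)
            grp.create_dataset("mask", data=data.mask)
        else:
            raise TypeError(f"unsupported container type {type(data).__name__}")
        _write_meta(grp, data.meta)


def read_dataset(path: str | Path) -> RadialKSpace | GriddedProjections:
    """Read a container written by :func:`write_dataset`; validates on load."""
    path = Path(path)
    with h5py.File(path, "r") as h5:
        if "radial_kspace" in h5:
            grp = h5["radial_kspace"]
            for name in ("samples", "angles_deg"):
                if name not in grp:
                    raise ValidationError(f"truncated file: missing dataset {name!r}")
            return RadialKSpace(
                samples=grp["samples"][()],
                angles_deg=grp["angles_deg"][()],
                meta=_read_meta(grp),
            )
        if "gridded_projections" in h5:
            grp = h5["gridded_projections"]
            for name in ("values", "mask"):
                if name not in grp:
                    raise ValidationError(f"truncated file: missing dataset {name!r}")
            return GriddedProjections(
                values=grp["values"][()],
                mask=grp["mask"][()],
                meta=_read_meta(grp),
            )
    raise ValidationError(f"{path} contains neither a radial_kspace nor a gridded_projections group")


# --------------------------------------------------------------------------
# Map export


def _save_nifti(arr: np.ndarray, path: Path) -> None:
    img = nib.Nifti1Image(np.asarray(arr, dtype=np.float64), affine=np.eye(4))
    nib.save(img, str(path))


def export_maps(
    maps: ParameterMaps,
    out_dir: str | Path,
    roi_masks: Mapping[str, np.ndarray] | None = None,
) -> dict[str, Path]:
    """Export parameter maps as single-slice NIfTI volumes.

    One volume per real map (``m0``, ``m0_star``, ``t1_star_ms``, ``k``,
    ``t1_ms``); the complex per-coil scales are written as magnitude and
    phase volumes per coil.  When ``roi_masks`` is given, a CSV with columns
    ``roi,mean,std,mean_over_std`` of T1 statistics is written as well.
    Returns the mapping from logical name to file path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name in ("m0", "m0_star", "t1_star_ms", "k", "t1_ms"):
        p = out_dir / f"{name}.nii.gz"
        _save_nifti(getattr(maps, name), p)
        written[name] = p
    for c in range(maps.coil_scale.shape[0]):
        p_mag = out_dir / f"coil{c}_mag.nii.gz"
        p_ph = out_dir / f"coil{c}_phase.nii.gz"
        _save_nifti(np.abs(maps.coil_scale[c]), p_mag)
        _save_nifti(np.angle(maps.coil_scale[c]), p_ph)
        written[f"coil{c}_mag"] = p_mag
        written[f"coil{c}_phase"] = p_ph
    if roi_masks is not None:
        from .reconstructor import roi_stats

        table = roi_stats(maps.t1_ms, roi_masks)
        p = out_dir / "roi_stats.csv"
        table.to_csv(p, index=False)
        written["roi_stats"] = p
    return written
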