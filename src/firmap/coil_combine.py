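"""Phase-sensitive multi-coil combination.

Inversion-recovery fitting needs the *signed* recovery curve, so a plain
root-sum-of-squares (which discards polarity) is not enough.  Instead each
coil is first phase-corrected by its background phase map phi_c(j), estimated
once from a composite image of the late (well-recovered, positive-signal)
projections; the signed squared real parts are then summed over coils,

    theta(j, t) = sum_c sign(Re{M_c e^{-i phi_c}}) |Re{M_c e^{-i phi_c}}|^2,

and the combined value is sign(theta) * sqrt(|theta|) — a signed
root-sum-of-squares that preserves the inversion polarity while restoring
the amplitude scale of the underlying signal.
"""

from __future__ import annotations

import numpy as np

from .data_model_io import CoilPhaseMaps, CombinedSeries, GriddedProjections, ModelSeries
from .fourier import ifft2c

__all__ = ["mean_phase_maps", "combine", "composite_kspace"]


def composite_kspace(gridded: GriddedProjections, last_n: int = 200) -> np.ndarray:
    """Superimpose the last ``last_n`` projections into one k-space per coil.

    Values from different projections landing on the same node are averaged;
    nodes covered by none remain zero.  Returns (n_coil, N, N).
    """
    n_proj = gridded.meta.n_proj
    if last_n > n_proj:
        raise ValueError(f"last_n={last_n} exceeds the {n_proj} available projections")
    tail_vals = gridded.values[n_proj - last_n :]
    tail_mask = gridded.mask[n_proj - last_n :]
    count = tail_mask.sum(axis=0)
    total = tail_vals.sum(axis=0)
    covered = count > 0
    comp = np.zeros_like(total)
    comp[:, covered] = total[:, covered] / count[covered]
    return comp


def mean_phase_maps(gridded: GriddedProjections, last_n: int = 200) -> CoilPhaseMaps:
    """Per-coil background phase from a composite of the last projections.

    Late in the recovery the signal is positive everywhere, so the phase of
    the composite coil image is (up to noise) the coil's own phase.
    """
    comp_img = ifft2c(composite_kspace(gridded, last_n))
    return CoilPhaseMaps(phi=np.angle(comp_img))


def combine(
    series: ModelSeries, phi: CoilPhaseMaps, amplitude_root: bool = True
) -> CombinedSeries:
    """Combine a multi-coil complex series into a signed real series.

    With ``amplitude_root`` (default) the result is sign(theta)*sqrt(|theta|),
    keeping the combined value on the signal amplitude scale used by the
    relaxation fit; switching it off returns theta itself (the literal signed
    sum of squares) for sensitivity checks.
    """
    if series.images.shape[1] != phi.phi.shape[0]:
        raise ValueError("coil count of series and phase maps disagree")
    # Re{M e^{-i phi}} = Re(M) cos(phi) + Im(M) sin(phi), in real arithmetic;
    # trig factors follow the series' precision so no large temporary upcasts
    real_dtype = series.images.real.dtype
    cos_phi = np.cos(phi.phi).astype(real_dtype)[None]
    sin_phi = np.sin(phi.phi).astype(real_dtype)[None]
    real = series.images.real * cos_phi + series.images.imag * sin_phi
    theta = np.sum(np.sign(real) * real**2, axis=1)  # (P, N, N)
    if amplitude_root:
        values = np.sign(theta) * np.sqrt(np.abs(theta))
    else:
        values = theta
    return CombinedSeries(values=values)
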