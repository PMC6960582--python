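"""Initial image-series models for the first reconstruction iteration.

Three strategies are supported:

* **OFM** (original first model): each time frame is the zero-filled inverse
  FFT of that projection's own gridded spoke — the rawest possible start,
  needing many iterations.
* **IFM** (interpolated first model): every k-space node that was hit by at
  least one projection is linearly interpolated through time (real and
  imaginary parts separately), filling each frame's k-space before inverse
  transforming.
* **MFM** (mean first model): all projections are averaged node-wise in
  k-space — only projections actually covering a node contribute to its
  mean — and the resulting per-coil image is treated as the steady-state
  amplitude M0* of a simplified recovery M(t) = M0* (1 - 2 exp(-t/T1*))
  with a fixed initial T1* (default 1000 ms).

All builders accept an optional ``eval_times`` axis so that a model built
from one projection subset can be evaluated on the (possibly different)
subset used in the iteration loop.
"""

from __future__ import annotations

import numpy as np

from .data_model_io import GriddedProjections, InversionTimeAxis, ModelSeries
from .fourier import ifft2c

__all__ = ["build_mfm", "build_ifm", "build_ofm"]


def _mean_kspace(gridded: GriddedProjections) -> np.ndarray:
    """Node-wise mean of covered projections, per coil; uncovered nodes stay 0."""
    count = gridded.mask.sum(axis=0)  # (N, N)
    total = gridded.values.sum(axis=0)  # (C, N, N); masked-out values are zero
    covered = count > 0
    mean = np.zeros_like(total)
    mean[:, covered] = total[:, covered] / count[covered]
    return mean


def build_mfm(
    gridded: GriddedProjections,
    times: InversionTimeAxis,
    t1_star_init_ms: float = 1000.0,
    eval_times: InversionTimeAxis | None = None,
) -> ModelSeries:
    """Mean first model: averaged k-space image scaled by a fixed recovery."""
    count = gridded.mask.sum(axis=0)
    if not np.any(count):
        raise ValueError("cannot build MFM: no k-space node is covered by any projection")
    m0_star_img = ifft2c(_mean_kspace(gridded))  # (C, N, N) complex
    t = (eval_times or times).t_ms
    factor = 1.0 - 2.0 * np.exp(-t / t1_star_init_ms)  # (P,)
    images = factor[:, None, None, None] * m0_star_img[None]
    return ModelSeries(images=images)


def build_ifm(
    gridded: GriddedProjections,
    times: InversionTimeAxis,
    eval_times: InversionTimeAxis | None = None,
) -> ModelSeries:
    """Interpolated first model: per-node linear interpolation through time.

    Real and imaginary parts are interpolated separately; outside the sampled
    time range the nearest sample's value is held constant (which also makes
    single-sample nodes constant in time).  Nodes never covered remain zero.
    """
    t_out = (eval_times or times).t_ms
    t_in = times.t_ms
    n_proj, n_coil, n, _ = gridded.values.shape
    n_out = t_out.size

    maskf = gridded.mask.reshape(n_proj, n * n)
    valsf = gridded.values.reshape(n_proj, n_coil, n * n)
    kser = np.zeros((n_out, n_coil, n * n), dtype=np.complex128)

    covered = np.nonzero(maskf.any(axis=0))[0]
    for node in covered:
        hit = maskf[:, node]
        tp = t_in[hit]
        v = valsf[hit, :, node]  # (n_hit, n_coil)
        for c in range(n_coil):
            kser[:, c, node] = np.interp(t_out, tp, v[:, c].real) + 1j * np.interp(
                t_out, tp, v[:, c].imag
            )

    return ModelSeries(images=ifft2c(kser.reshape(n_out, n_coil, n, n)))


def build_ofm(
    gridded: GriddedProjections, eval_times: InversionTimeAxis | None = None
) -> ModelSeries:
    """Original first model: zero-filled inverse FFT of each projection alone."""
    return ModelSeries(images=ifft2c(gridded.values))
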