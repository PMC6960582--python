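"""Data consistency in k-space: reinsertion, circular mask, termination metric.

Each iteration the current image-space model is Fourier transformed, the
measured spokes are written back over the model at their acquired k-space
nodes (the model only ever fills the gaps), and optionally everything outside
the disk actually reached by the radial spokes is zeroed.  The termination
metric is the absolute sum of the complex difference between measured and
model k-space over the sampled nodes, evaluated *before* reinsertion.
"""

from __future__ import annotations

import numpy as np

from .data_model_io import GriddedProjections, ModelSeries
from .fourier import fft2c

__all__ = [
    "model_to_kspace",
    "reinsert",
    "consistency_metric",
    "circular_kspace_mask",
    "sparsity_select",
]


def model_to_kspace(series: ModelSeries) -> np.ndarray:
    """Unitary centered FFT of every (projection, coil) model frame."""
    return fft2c(series.images)


def circular_kspace_mask(n: int, radius: float) -> np.ndarray:
    """Boolean (N, N) disk of given radius in grid units around DC."""
    c = n // 2
    y, x = np.mgrid[0:n, 0:n]
    return (y - c) ** 2 + (x - c) ** 2 <= radius**2


def reinsert(
    model_k: np.ndarray,
    gridded: GriddedProjections,
    circular_mask: bool = True,
    radius: float | None = None,
    sample_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Replace model k-space by the measured values at sampled nodes.

    ``sample_mask`` optionally restricts which sampled nodes are reinserted
    (used by the sparsity-selection option); it defaults to the gridded
    sampling mask.  If ``circular_mask`` is set, nodes farther than
    ``radius`` (default n_read/2, the largest disk the spokes reach) from DC
    are zeroed after reinsertion, so measured samples inside the disk are
    never altered.
    """
    mask = gridded.mask if sample_mask is None else sample_mask
    out = np.where(mask[:, None], gridded.values, model_k)
    if circular_mask:
        n = gridded.meta.matrix
        r = gridded.meta.n_read / 2 if radius is None else radius
        out = np.where(circular_kspace_mask(n, r)[None, None], out, 0.0)
    return out


def consistency_metric(model_k: np.ndarray, gridded: GriddedProjections) -> float:
    """Absolute sum of (measured - model) over all sampled k-space nodes."""
    mask = np.broadcast_to(gridded.mask[:, None], model_k.shape)
    return float(np.sum(np.abs(gridded.values[mask] - model_k[mask])))


def sparsity_select(
    gridded: GriddedProjections,
    reference_k: np.ndarray,
    fraction: float = 0.05,
) -> np.ndarray:
    """Per-projection mask keeping only 'strong' sampled nodes.

    A sampled node survives when its measured magnitude exceeds ``fraction``
    of the magnitude of a reference composite k-space at that node.  This is
    a declared interpretation of sparsity-conditioned reinsertion, off by
    default in the reconstruction loop.
    """
    ref_mag = np.abs(reference_k).max(axis=0)  # (N, N) over coils
    strong = np.abs(gridded.values).max(axis=1) > fraction * ref_mag[None]
    return gridded.mask & strong
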