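"""Golden-ratio radial trajectories and nearest-neighbour gridding.

Spoke angles follow the golden-angle ordering: successive projections are
rotated by 180/phi ~ 111.246 degrees (phi the golden ratio), which keeps the
angular coverage of any contiguous subset of spokes near-uniform.  Spokes are
deposited onto the Cartesian grid by snapping each readout point to its
nearest grid node; samples colliding on one node are averaged.  The gridding
backend is deliberately pluggable so that a coil-calibrated operator (e.g.
GRAPPA operator gridding) can be swapped in later.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = ["SpokeGeometry", "golden_angle_sequence", "spoke_coords", "grid_spoke"]

log = logging.getLogger(__name__)

GOLDEN_RATIO = (1.0 + np.sqrt(5.0)) / 2.0
GOLDEN_ANGLE_DEG = 180.0 / GOLDEN_RATIO


@dataclass(frozen=True)
class SpokeGeometry:
    """Continuous (ky, kx) coordinates of one radial spoke.

    Coordinates are in grid units, centered on DC: readout index r maps to
    radius rho = r - n_read/2 along the spoke direction, so the spoke covers
    both signs of rho and index n_read/2 hits the DC sample exactly.
    """

    angle_deg: float
    coords: np.ndarray  # (n_read, 2) as (ky, kx)

    @property
    def n_read(self) -> int:
        return self.coords.shape[0]


def golden_angle_sequence(n_proj: int) -> np.ndarray:
    """Return the first ``n_proj`` golden-angle spoke angles in [0, 180).

    angle_p = (p * 180/phi) mod 180 for 0-based p; the half-circle range
    suffices because each spoke covers both signs of the readout radius.
    """
    if n_proj < 1:
        raise ValueError("n_proj must be >= 1")
    p = np.arange(n_proj, dtype=np.float64)
    return (p * GOLDEN_ANGLE_DEG) % 180.0


def spoke_coords(angle_deg: float, n_read: int) -> SpokeGeometry:
    """Continuous k-space coordinates of a spoke at ``angle_deg``."""
    if n_read % 2:
        raise ValueError("n_read must be even")
    theta = np.deg2rad(angle_deg)
    rho = np.arange(n_read, dtype=np.float64) - n_read / 2
    coords = np.stack([rho * np.sin(theta), rho * np.cos(theta)], axis=1)
    return SpokeGeometry(angle_deg=float(angle_deg), coords=coords)


def snap_to_grid(geom: SpokeGeometry, grid_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Nearest integer grid node (iy, ix) for each readout point.

    DC maps to index (grid_size//2, grid_size//2).  Returns index arrays and
    a validity mask for points that land inside the grid; out-of-grid points
    are clipped from deposition with a logged warning.
    """
    center = grid_size // 2
    iy = np.rint(geom.coords[:, 0]).astype(np.intp) + center
    ix = np.rint(geom.coords[:, 1]).astype(np.intp) + center
    inside = (iy >= 0) & (iy < grid_size) & (ix >= 0) & (ix < grid_size)
    if not np.all(inside):
        log.debug(
            "spoke at %.3f deg: %d readout points fall outside the %dx%d grid and are clipped",
            geom.angle_deg,
            int(np.sum(~inside)),
            grid_size,
            grid_size,
        )
    return np.stack([iy, ix], axis=1), inside


def grid_spoke(
    values: np.ndarray, geom: SpokeGeometry, grid_size: int
) -> tuple[np.ndarray, np.ndarray]:
    """Deposit one spoke onto an (N, N) Cartesian plane.

    ``values`` may be (n_read,) for a single coil or (n_coil, n_read).
    Each sample goes to its nearest grid node; samples colliding on a node
    are averaged (deterministically, independent of sample order).  Returns
    ``(plane, mask)`` with plane shaped like values but with the readout axis
    replaced by (N, N), and mask (N, N) true at touched nodes.
    """
    values = np.asarray(values, dtype=np.complex128)
    single = values.ndim == 1
    if single:
        values = values[None]
    if values.shape[-1] != geom.n_read:
        raise ValueError("values length must equal the spoke's n_read")

    idx, inside = snap_to_grid(geom, grid_size)
    iy, ix = idx[inside, 0], idx[inside, 1]
    flat = iy * grid_size + ix

    n_coil = values.shape[0]
    acc = np.zeros((n_coil, grid_size * grid_size), dtype=np.complex128)
    count = np.zeros(grid_size * grid_size, dtype=np.int64)
    np.add.at(count, flat, 1)
    for c in range(n_coil):
        np.add.at(acc[c], flat, values[c, inside])
    touched = count > 0
    acc[:, touched] /= count[touched]

    plane = acc.reshape(n_coil, grid_size, grid_size)
    mask = touched.reshape(grid_size, grid_size)
    if single:
        plane = plane[0]
    return plane, mask
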