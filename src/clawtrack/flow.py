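"""Dense optical flow, grid downsampling, and magnitude thresholding.

The per-pixel displacement field between consecutive frames is estimated with
a coarse-to-fine pyramidal dense-flow routine. The field is then reduced to a
uniform grid of cells by averaging the vectors inside each cell, and cells
whose mean speed falls below a user-set cutoff are zeroed, leaving a sparse
set of motion vectors that is robust to background noise. Crabs barely
translate while waving, so essentially all retained motion is claw motion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.registration import optical_flow_ilk

__all__ = [
    "FlowParams",
    "FlowField",
    "GridFlowField",
    "estimate_dense_flow",
    "downsample_flow",
    "threshold_flow",
]


@dataclass(frozen=True)
class FlowParams:
    """Dense-flow estimator settings.

    ``window`` is the side of the local neighborhood each displacement is
    fit over (the backend uses radius ``window // 2``); ``iterations`` the
    number of warp/refine passes; ``levels`` the requested pyramid depth.
    The backend builds its pyramid from the image size, so ``levels`` acts
    as an upper bound rather than an exact count.
    """

    levels: int = 3
    window: int = 15
    iterations: int = 3

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError(f"levels must be >= 1, got {self.levels}")
        if self.window < 3:
            raise ValueError(f"window must be >= 3, got {self.window}")
        if self.iterations < 1:
            raise ValueError(f"iterations must be >= 1, got {self.iterations}")


@dataclass
class FlowField:
    """Per-pixel displacement (px per frame interval), same shape as the frames.

    ``u`` is horizontal (x, columns), ``v`` vertical (y, rows); positive ``v``
    points down, consistent with the top-left image origin.
    """

    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        self.v = np.asarray(self.v, dtype=np.float64)
        if self.u.shape != self.v.shape or self.u.ndim != 2:
            raise ValueError(f"u and v must be equal-shape 2-D arrays, got {self.u.shape} / {self.v.shape}")
        if not (np.isfinite(self.u).all() and np.isfinite(self.v).all()):
            raise ValueError("flow field contains non-finite values")

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


@dataclass
class GridFlowField:
    """Cell-averaged flow on a uniform grid.

    ``cell_x``/``cell_y`` hold the pixel coordinates of each cell's center
    (mean coordinate of the pixels it covers, so partial edge cells have
    their true center). Arrays are 2-D, indexed ``[row, col]`` of the grid.
    """

    cell_size: int
    cell_x: np.ndarray
    cell_y: np.ndarray
    cell_u: np.ndarray
    cell_v: np.ndarray

    @property
    def cell_speed(self) -> np.ndarray:
        return np.hypot(self.cell_u, self.cell_v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.cell_u.shape


def estimate_dense_flow(
    frame_a: np.ndarray, frame_b: np.ndarray, params: FlowParams | None = None
) -> FlowField:
    """Estimate the per-pixel displacement field from ``frame_a`` to ``frame_b``.

    Uses an iterative Lucas–Kanade estimator on a multilevel pyramid, so both
    large and sub-pixel displacements are recovered. Constant (textureless)
    frame pairs return an exact zero field: with no gradient there is no
    evidence of motion.
    """
    params = params or FlowParams()
    a = np.asarray(frame_a, dtype=np.float32)
    b = np.asarray(frame_b, dtype=np.float32)
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    if a.ndim != 2:
        raise ValueError(f"frames must be 2-D grayscale, got shape {a.shape}")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        zero = np.zeros(a.shape)
        return FlowField(u=zero, v=zero.copy())
    vu = optical_flow_ilk(
        a,
        b,
        radius=max(1, params.window // 2),
        num_warp=params.iterations,
        dtype=np.float32,
    )
    v, u = vu
    return FlowField(u=u, v=v)


def _block_reduce_mean(arr: np.ndarray, cell: int) -> np.ndarray:
    """Mean over cell×cell blocks; partial edge blocks average their own pixels."""
    h, w = arr.shape
    row_edges = np.arange(0, h, cell)
    col_edges = np.arange(0, w, cell)
    sums = np.add.reduceat(np.add.reduceat(arr, row_edges, axis=0), col_edges, axis=1)
    rc = np.minimum(row_edges + cell, h) - row_edges
    cc = np.minimum(col_edges + cell, w) - col_edges
    counts = np.outer(rc, cc)
    return sums / counts


def downsample_flow(flow: FlowField, cell_size: int) -> GridFlowField:
    """Average the dense field over a uniform grid of ``cell_size`` px cells.

    Each cell's vector is the arithmetic mean of the per-pixel vectors it
    covers; edge cells not fully inside the frame average only the pixels
    actually present. When cells tile the frame exactly, the area-weighted
    grid mean equals the dense-field mean.
    """
    if cell_size < 1:
        raise ValueError(f"cell_size must be >= 1, got {cell_size}")
    h, w = flow.u.shape
    if cell_size > max(h, w):
        warnings.warn(
            f"cell_size {cell_size} exceeds frame size {w}x{h}; the grid is a single cell",
            stacklevel=2,
        )
    cell_u = _block_reduce_mean(flow.u, cell_size)
    cell_v = _block_reduce_mean(flow.v, cell_size)
    # Cell centers = mean coordinate of covered pixels.
    row_edges = np.arange(0, h, cell_size)
    col_edges = np.arange(0, w, cell_size)
    yc = (row_edges + np.minimum(row_edges + cell_size, h) - 1) / 2.0
    xc = (col_edges + np.minimum(col_edges + cell_size, w) - 1) / 2.0
    cell_x, cell_y = np.meshgrid(xc, yc)
    return GridFlowField(
        cell_size=cell_size, cell_x=cell_x, cell_y=cell_y, cell_u=cell_u, cell_v=cell_v
    )


def threshold_flow(grid: GridFlowField, cutoff: float) -> GridFlowField:
    """Zero every cell whose speed is below ``cutoff`` (px per frame).

    Cells with ``speed < cutoff`` get both components set to exactly zero;
    all others pass through unchanged, so the operation is idempotent and
    never increases any cell's speed.
    """
    if cutoff < 0:
        raise ValueError(f"cutoff must be >= 0, got {cutoff}")
    keep = grid.cell_speed >= cutoff
    return GridFlowField(
        cell_size=grid.cell_size,
        cell_x=grid.cell_x,
        cell_y=grid.cell_y,
        cell_u=np.where(keep, grid.cell_u, 0.0),
        cell_v=np.where(keep, grid.cell_v, 0.0),
    )
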