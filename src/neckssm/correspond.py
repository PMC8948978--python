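"""Point correspondence across patients.

Two steps make the 10 x 36 contour grids comparable point-to-point:

1. longitudinal rearrangement — each of the 36 angular columns is treated as
   its own 3D polyline and its 10 points are re-placed at equal arc-length
   spacing by linear interpolation, which prevents adjacent contour rings
   from crossing;
2. translation to the LRA baseline — every grid is shifted so the CLL point
   at the lowest-renal-artery projection sits at the origin. Translation
   only: no rotation and no scaling, so deflection modes keep their
   anatomical orientation.

Aligned grids are flattened to shape vectors (ring-major, then ray, then
x/y/z: 10 x 36 x 3 = 1080 values) and stacked into a cohort matrix for PCA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionMismatchError, ZeroLengthColumnError
from .parametrize import ContourGrid

__all__ = [
    "rearrange_longitudinal",
    "align_to_baseline",
    "flatten",
    "unflatten",
    "ShapeCohort",
    "process_grid",
]


def _equalize_column(col: np.ndarray, tol: float = 1e-13, max_iter: int = 200) -> np.ndarray:
    """Re-place a column polyline's points at equal spacing.

    One pass interpolates linearly along the current polyline at equal
    cumulative-arc positions; because the new points cut polyline corners,
    a single pass leaves slightly unequal chord distances, so the pass is
    iterated to its fixed point (points with exactly equal consecutive
    distances, which is also what makes the operation idempotent). Smooth
    anatomical columns converge in a handful of passes with negligible
    displacement beyond the first.
    """
    n = len(col)
    cur = col
    for _ in range(max_iter):
        seg = np.linalg.norm(np.diff(cur, axis=0), axis=1)
        total = float(seg.sum())
        if total <= 0.0:
            raise ZeroLengthColumnError("column has zero length (all points coincide)")
        if seg.size and np.ptp(seg) <= tol * total:
            break
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        target = np.linspace(0.0, total, n)
        nxt = np.column_stack([np.interp(target, cum, cur[:, k]) for k in range(3)])
        nxt[0], nxt[-1] = col[0], col[-1]
        cur = nxt
    return cur


def rearrange_longitudinal(grid: ContourGrid) -> ContourGrid:
    """Re-place each angular column's points at equal spacing along the
    column, by linear interpolation on the column polyline.

    Column endpoints (ring 0 and the last ring) are unchanged; afterwards
    the consecutive inter-point distances within each column are equal,
    which prevents adjacent contour rings from crossing. Idempotent.
    """
    pts = grid.points.copy()
    for j in range(grid.n_rays):
        try:
            pts[:, j, :] = _equalize_column(grid.points[:, j, :])
        except ZeroLengthColumnError:
            raise ZeroLengthColumnError(
                f"angular column {j} has zero length (all points coincide)"
            ) from None
    return ContourGrid(pts, grid.arc_positions, grid.angles_deg, grid.baseline_point)


def align_to_baseline(grid: ContourGrid, baseline_point=None) -> ContourGrid:
    """Translate the grid so the LRA baseline point moves to the origin."""
    if baseline_point is None:
        baseline_point = grid.baseline_point
    if baseline_point is None:
        raise ValueError("no baseline point available for alignment")
    b = np.asarray(baseline_point, dtype=float).reshape(3)
    new_base = None if grid.baseline_point is None else grid.baseline_point - b
    return ContourGrid(grid.points - b, grid.arc_positions, grid.angles_deg, new_base)


def flatten(grid: ContourGrid) -> np.ndarray:
    """Grid -> shape vector, ring-major then ray then coordinate."""
    return grid.points.reshape(-1).copy()


def unflatten(
    vector,
    n_rings: int = 10,
    n_rays: int = 36,
    arc_positions=None,
    angles_deg=None,
) -> ContourGrid:
    """Shape vector -> grid. Exact inverse of :func:`flatten`."""
    v = np.asarray(vector, dtype=float).reshape(-1)
    expected = 3 * n_rings * n_rays
    if v.size != expected:
        raise DimensionMismatchError(
            f"shape vector has length {v.size}, expected {expected} "
            f"({n_rings} rings x {n_rays} rays x 3)"
        )
    if arc_positions is None:
        arc_positions = np.arange(n_rings, dtype=float)
    if angles_deg is None:
        angles_deg = np.arange(n_rays) * (360.0 / n_rays)
    return ContourGrid(v.reshape(n_rings, n_rays, 3), arc_positions, angles_deg)


def process_grid(grid: ContourGrid) -> np.ndarray:
    """Rearrange, align to the LRA baseline, and flatten one grid."""
    return flatten(align_to_baseline(rearrange_longitudinal(grid)))


@dataclass
class ShapeCohort:
    """Cohort of corresponded, aligned shape vectors (one row per patient)."""

    ids: list[str]
    matrix: np.ndarray
    n_rings: int = 10
    n_rays: int = 36

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.ids = [str(i) for i in self.ids]
        if self.matrix.ndim != 2:
            raise DimensionMismatchError("cohort matrix must be 2-D")
        if len(self.ids) != self.matrix.shape[0]:
            raise DimensionMismatchError("id count does not match matrix rows")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicated patient id in cohort")
        if self.matrix.shape[0] < 3:
            raise ValueError("cohort needs at least 3 shapes")
        if self.matrix.shape[1] != 3 * self.n_rings * self.n_rays:
            raise DimensionMismatchError(
                f"vector length {self.matrix.shape[1]} does not match "
                f"{self.n_rings} x {self.n_rays} x 3"
            )
        if not np.isfinite(self.matrix).all():
            raise ValueError("non-finite values in cohort matrix")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def column_labels(self) -> list[str]:
        step = 360.0 / self.n_rays
        return [
            f"r{i}_a{int(round(j * step))}_{c}"
            for i in range(self.n_rings)
            for j in range(self.n_rays)
            for c in "xyz"
        ]


def cohort_from_grids(grids, ids=None, preprocessed: bool = False) -> ShapeCohort:
    """Build a cohort from contour grids (rearranged + aligned unless told
    they already are)."""
    grids = list(grids)
    if ids is None:
        ids = [f"P{i:03d}" for i in range(len(grids))]
    rows = [
        flatten(g) if preprocessed else process_grid(g)
        for g in grids
    ]
    g0 = grids[0]
    return ShapeCohort(list(ids), np.vstack(rows), g0.n_rings, g0.n_rays)
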