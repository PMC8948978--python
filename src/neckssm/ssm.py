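"""PCA statistical shape model: fit, project, reconstruct, mode meshes.

The model is a point-distribution model: the cohort matrix is centered on
the arithmetic mean shape and decomposed by singular value decomposition.
Component variances are the squared singular values divided by (n - 1)
(sample-variance convention, consistent with the n - 1 component count).
Eigenvector signs are fixed so the largest-magnitude entry of each column
is positive, making the decomposition reproducible across linear-algebra
backends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .correspond import ShapeCohort, unflatten
from .errors import DimensionMismatchError
from .geometry import LumenMesh
from .parametrize import ContourGrid

__all__ = [
    "SSMModel",
    "ModeMesh",
    "fit_ssm",
    "explained_variance",
    "project",
    "reconstruct",
    "mode_mesh",
    "grid_to_tube_mesh",
    "score_bounds",
    "sd_coverage",
]

#: components with variance below this fraction of the largest are discarded
_RANK_TOL = 1e-10
#: absolute variance floor (mm^2): sub-nanometre spread is numerical noise
_VAR_FLOOR = 1e-18


@dataclass
class SSMModel:
    """Mean shape + orthonormal variation modes of a corresponded cohort.

    eigenvalues are per-component variances in mm^2, sorted descending;
    ``scores[i, j]`` is training shape i's coefficient on component j, so
    ``mean + scores @ eigenvectors.T`` reproduces the training matrix.
    """

    mean: np.ndarray              # (D,)
    eigenvectors: np.ndarray      # (D, m), orthonormal columns
    eigenvalues: np.ndarray       # (m,)
    scores: np.ndarray            # (n, m)
    n_train: int
    n_rings: int = 10
    n_rays: int = 36
    ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float).reshape(-1)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float).reshape(-1)
        self.scores = np.asarray(self.scores, dtype=float)
        D = self.mean.size
        if self.eigenvectors.ndim != 2 or self.eigenvectors.shape[0] != D:
            raise DimensionMismatchError("eigenvector matrix does not match mean length")
        m = self.eigenvectors.shape[1]
        if self.eigenvalues.size != m:
            raise DimensionMismatchError("eigenvalue count does not match eigenvectors")
        if self.scores.size and self.scores.shape != (self.n_train, m):
            raise DimensionMismatchError("scores shape does not match (n_train, m)")
        if m and np.any(np.diff(self.eigenvalues) > 0):
            raise ValueError("eigenvalues must be sorted descending")
        if np.any(self.eigenvalues < 0):
            raise ValueError("negative eigenvalue")
        if D != 3 * self.n_rings * self.n_rays:
            raise DimensionMismatchError("mean length does not match grid dimensions")

    @property
    def n_components(self) -> int:
        return self.eigenvectors.shape[1]


def fit_ssm(cohort: ShapeCohort) -> SSMModel:
    """Fit the shape model by SVD of the centered cohort matrix."""
    X = cohort.matrix
    mean = X.mean(axis=0)
    Xc = X - mean
    # economy SVD: Xc = U S Vt, variances = S^2 / (n-1)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = S**2 / (cohort.n - 1)
    if var.size and var[0] > _VAR_FLOOR:
        keep = var > _RANK_TOL * var[0]
    else:
        keep = np.zeros_like(var, dtype=bool)
    U, S, Vt, var = U[:, keep], S[keep], Vt[keep], var[keep]
    vecs = Vt.T                                  # (D, m)
    scores = U * S                               # (n, m) = Xc @ vecs
    # sign convention: largest-magnitude entry of each column positive
    if vecs.size:
        idx = np.argmax(np.abs(vecs), axis=0)
        flip = np.sign(vecs[idx, np.arange(vecs.shape[1])])
        flip[flip == 0] = 1.0
        vecs = vecs * flip
        scores = scores * flip
    return SSMModel(
        mean=mean,
        eigenvectors=vecs,
        eigenvalues=var,
        scores=scores,
        n_train=cohort.n,
        n_rings=cohort.n_rings,
        n_rays=cohort.n_rays,
        ids=list(cohort.ids),
    )


def explained_variance(model: SSMModel):
    """Per-component variance fractions and their cumulative sum."""
    total = float(model.eigenvalues.sum())
    if total <= 0:
        raise ValueError("model has zero total variance")
    frac = model.eigenvalues / total
    return frac, np.cumsum(frac)


def project(model: SSMModel, shape, k: int | None = None) -> np.ndarray:
    """Scores of a shape on the first k components: (shape - mean) . V_k."""
    shape = np.asarray(shape, dtype=float).reshape(-1)
    if shape.size != model.mean.size:
        raise DimensionMismatchError(
            f"shape vector length {shape.size} != model dimension {model.mean.size}"
        )
    if k is None:
        k = model.n_components
    if not 0 <= k <= model.n_components:
        raise ValueError(f"k={k} out of range [0, {model.n_components}]")
    return (shape - model.mean) @ model.eigenvectors[:, :k]


def reconstruct(model: SSMModel, scores) -> np.ndarray:
    """Shape vector mean + sum_i score_i * eigenvector_i."""
    scores = np.asarray(scores, dtype=float).reshape(-1)
    if scores.size > model.n_components:
        raise DimensionMismatchError(
            f"{scores.size} scores but model has {model.n_components} components"
        )
    return model.mean + model.eigenvectors[:, : scores.size] @ scores


def grid_to_tube_mesh(grid: ContourGrid) -> LumenMesh:
    """Triangulate a contour grid as an open tube.

    Each quad between adjacent rings (cyclic in the ray index) is split into
    two triangles along a fixed diagonal; ends are left open, giving
    2 * (rings - 1) * rays triangles.
    """
    R, K = grid.n_rings, grid.n_rays
    verts = grid.points.reshape(-1, 3)
    faces = []
    for i in range(R - 1):
        for j in range(K):
            jn = (j + 1) % K
            a, b = i * K + j, i * K + jn
            c, d = (i + 1) * K + jn, (i + 1) * K + j
            faces.append((a, b, c))
            faces.append((a, c, d))
    return LumenMesh(verts, np.asarray(faces, dtype=np.int64))


@dataclass
class ModeMesh:
    """Surface of one variation mode at mean + s * sqrt(eigenvalue) * mode."""

    mesh: LumenMesh
    pc_index: int
    sd_multiplier: float
    normal_scores: bool            #: Shapiro–Wilk p > 0.05 on training scores
    shapiro_p: float
    score_range_sd: tuple          #: empirical (min, max) score in SD units
    recommended_s: tuple           #: +/-3 clipped to the empirical range


def score_bounds(model: SSMModel, pc_index: int, s_max: float = 3.0) -> tuple:
    """SD-multiplier bounds supported by the training scores.

    When the empirical score range of a component does not reach +/- s_max
    standard deviations (e.g. a skewed neck-length mode), the bound is the
    observed extreme score divided by sqrt(eigenvalue).
    """
    sd = float(np.sqrt(model.eigenvalues[pc_index]))
    lo = float(model.scores[:, pc_index].min() / sd)
    hi = float(model.scores[:, pc_index].max() / sd)
    return (max(-s_max, lo), min(s_max, hi))


def mode_mesh(model: SSMModel, pc_index: int, s: float) -> ModeMesh:
    """Mesh of the mean shape displaced s standard deviations along one PC.

    The training score distribution of the component is tested for
    normality (Shapiro–Wilk, alpha 0.05); non-normal components get their
    recommended SD range clipped to the empirical score range, mirroring
    visualization at -1 SD rather than -3 SD for a skewed length mode.
    """
    if not 0 <= pc_index < model.n_components:
        raise ValueError(f"pc_index {pc_index} out of range")
    vec = model.mean + s * np.sqrt(model.eigenvalues[pc_index]) * model.eigenvectors[:, pc_index]
    grid = unflatten(vec, model.n_rings, model.n_rays)
    mesh = grid_to_tube_mesh(grid)
    _warn_if_self_intersecting(grid, pc_index, s)
    scores = model.scores[:, pc_index]
    if scores.size >= 3 and np.ptp(scores) > 0:
        sw_p = float(stats.shapiro(scores).pvalue)
    else:
        sw_p = 1.0
    rng_sd = score_bounds(model, pc_index)
    sd = float(np.sqrt(model.eigenvalues[pc_index]))
    return ModeMesh(
        mesh=mesh,
        pc_index=pc_index,
        sd_multiplier=float(s),
        normal_scores=sw_p > 0.05,
        shapiro_p=sw_p,
        score_range_sd=(float(scores.min() / sd), float(scores.max() / sd)),
        recommended_s=rng_sd,
    )


def _warn_if_self_intersecting(grid: ContourGrid, pc_index: int, s: float) -> None:
    """Cheap validity check: ring centroids must stay ordered and rings must
    not collapse. Emits a warning only — the mesh is still returned."""
    centroids = grid.points.mean(axis=1)
    steps = np.linalg.norm(np.diff(centroids, axis=0), axis=1)
    radii = np.linalg.norm(grid.points - centroids[:, None, :], axis=2)
    if np.any(steps <= 0) or np.any(radii <= 0):
        warnings.warn(
            f"mode {pc_index} at s={s:+.1f} produces a degenerate or "
            "self-intersecting tube",
            stacklevel=2,
        )


def sd_coverage(s: float) -> float:
    """Fraction of a normal distribution within +/- s standard deviations."""
    return float(special.erf(abs(s) / np.sqrt(2.0)))
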