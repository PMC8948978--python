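"""Shape-model quality metrics: compactness, generalization, specificity.

* compactness — cumulative explained-variance fraction vs number of PCs;
* generalization — leave-one-out cross-validation: the model is refitted
  without each shape, the left-out shape is projected onto the first k PCs
  and reconstructed, and the per-point RMSE (mm) is recorded;
* specificity — random shapes are sampled from the model (component i
  ~ Normal(0, eigenvalue_i), i <= k), reconstructed, and compared with
  their nearest training shape by RMSE.

Means are reported with 95% confidence intervals from the normal
approximation (mean +/- 1.96 SE).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .correspond import ShapeCohort
from .errors import DimensionMismatchError
from .ssm import SSMModel, explained_variance, fit_ssm, project, reconstruct

__all__ = [
    "rmse",
    "compactness",
    "generalization_loo",
    "specificity",
    "evaluate_all",
    "EvalReport",
    "MetricSummary",
]


def rmse(a, b) -> float:
    """Root-mean-square 3D point-to-point distance between two shapes (mm).

    The mean runs over the corresponded contour points (each an (x, y, z)
    triple), not over the 3 x n_points scalar coordinates.
    """
    a = np.asarray(a, dtype=float).reshape(-1)
    b = np.asarray(b, dtype=float).reshape(-1)
    if a.size != b.size:
        raise DimensionMismatchError(f"shape lengths differ: {a.size} vs {b.size}")
    if a.size % 3:
        raise DimensionMismatchError("shape vector length is not a multiple of 3")
    d2 = np.sum((a.reshape(-1, 3) - b.reshape(-1, 3)) ** 2, axis=1)
    return float(np.sqrt(d2.mean()))


def compactness(model: SSMModel) -> np.ndarray:
    """Cumulative explained-variance fraction at each PC count 1..m.

    A degenerate model with no retained components (zero shape variance)
    yields an empty curve.
    """
    if model.n_components == 0:
        return np.empty(0)
    _, cum = explained_variance(model)
    return cum


def _mean_ci(values: np.ndarray) -> tuple[float, float, float]:
    values = np.asarray(values, dtype=float)
    m = float(values.mean())
    if values.size > 1:
        se = float(values.std(ddof=1) / np.sqrt(values.size))
    else:
        se = 0.0
    return m, m - 1.96 * se, m + 1.96 * se


@dataclass
class MetricSummary:
    """Per-k summary of an error metric: mean, 95% CI, raw values."""

    k: int
    mean: float
    ci_low: float
    ci_high: float
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not (self.ci_low <= self.mean <= self.ci_high):
            raise ValueError("confidence interval does not bracket the mean")


def generalization_loo(cohort: ShapeCohort, k_values) -> dict[int, MetricSummary]:
    """Leave-one-out generalization RMSE for each requested PC count.

    Deterministic: one model refit per left-out shape, shared across all k.
    """
    k_values = sorted(int(k) for k in k_values)
    if cohort.n < 4:
        raise ValueError("leave-one-out needs n >= 4")
    if max(k_values) > cohort.n - 2:
        raise ValueError(
            f"k={max(k_values)} exceeds the n-2={cohort.n - 2} components "
            "available in each fold"
        )
    errors = {k: np.empty(cohort.n) for k in k_values}
    for i in range(cohort.n):
        rest = np.delete(cohort.matrix, i, axis=0)
        sub = ShapeCohort(
            [pid for j, pid in enumerate(cohort.ids) if j != i],
            rest, cohort.n_rings, cohort.n_rays,
        )
        model = fit_ssm(sub)
        left_out = cohort.matrix[i]
        for k in k_values:
            # a fold may retain fewer components than requested (e.g. a
            # degenerate cohort); projection uses what the fold provides
            kk = min(k, model.n_components)
            rec = reconstruct(model, project(model, left_out, kk))
            errors[k][i] = rmse(left_out, rec)
    return {k: MetricSummary(k, *_mean_ci(errors[k]), values=errors[k])
            for k in k_values}


def specificity(
    model: SSMModel,
    cohort: ShapeCohort,
    k: int,
    n_samples: int = 1000,
    seed: int = 0,
) -> MetricSummary:
    """Mean RMSE from random model samples to their nearest training shape.

    Sampling is restricted to the first k components: score vector drawn as
    ``rng.standard_normal((n_samples, k)) * sqrt(eigenvalues[:k])`` from
    ``numpy.random.default_rng(seed)``. Deterministic given the seed.
    """
    if not 0 <= k <= model.n_components:
        raise ValueError(f"k={k} out of range [0, {model.n_components}]")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal((n_samples, k)) * np.sqrt(model.eigenvalues[:k])
    samples = model.mean[None, :] + draws @ model.eigenvectors[:, :k].T
    n_pts = samples.shape[1] // 3
    train = cohort.matrix.reshape(cohort.n, n_pts, 3)
    vals = np.empty(n_samples)
    for s in range(n_samples):
        d2 = ((samples[s].reshape(1, n_pts, 3) - train) ** 2).sum(axis=2)
        vals[s] = np.sqrt(d2.mean(axis=1).min())
    return MetricSummary(k, *_mean_ci(vals), values=vals)


@dataclass
class EvalReport:
    """Combined evaluation report of one fitted model."""

    compactness: np.ndarray
    generalization: dict[int, MetricSummary]
    specificity: dict[int, MetricSummary]
    n_shapes: int
    n_samples: int
    seed: int

    def __post_init__(self):
        self.compactness = np.asarray(self.compactness, dtype=float)
        if np.any(np.diff(self.compactness) < -1e-12):
            raise ValueError("compactness curve must be non-decreasing")

    def to_dict(self) -> dict:
        def summ(s: MetricSummary) -> dict:
            return {
                "k": s.k,
                "mean_mm": s.mean,
                "ci95_low_mm": s.ci_low,
                "ci95_high_mm": s.ci_high,
                "n": int(s.values.size),
            }

        return {
            "n_shapes": self.n_shapes,
            "n_samples": self.n_samples,
            "seed": self.seed,
            "compactness": self.compactness.tolist(),
            "generalization": [summ(self.generalization[k])
                               for k in sorted(self.generalization)],
            "specificity": [summ(self.specificity[k])
                            for k in sorted(self.specificity)],
        }


def evaluate_all(
    cohort: ShapeCohort,
    k_values=(5, 9),
    n_samples: int = 1000,
    seed: int = 0,
) -> EvalReport:
    """Compactness + LOO generalization + specificity in one report."""
    model = fit_ssm(cohort)
    k_values = sorted(int(k) for k in k_values)
    gen = generalization_loo(cohort, k_values)
    spec = {
        k: specificity(model, cohort, min(k, model.n_components),
                       n_samples=n_samples, seed=seed)
        for k in k_values
    }
    return EvalReport(
        compactness=compactness(model),
        generalization=gen,
        specificity=spec,
        n_shapes=cohort.n,
        n_samples=n_samples,
        seed=seed,
    )
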