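"""Independent brute-force oracles, deliberately naive.

Each reimplements an operation from first principles (scalar loops, explicit
covariance matrices) so the fast implementations can be checked against a
second, independent route.
"""

import numpy as np

# same tolerances as the implementation so boundary hits agree exactly
PARALLEL_EPS = 1e-12
BARY_EPS = 1e-9
T_MIN = 1e-9


def _dot3(a, b):
    return (a[0] * b[0] + a[1] * b[1]) + a[2] * b[2]


def brute_force_ray_hit(origin, direction, vertices, faces):
    """Nearest positive ray-triangle hit, one triangle at a time."""
    best_t, best_tri = np.inf, -1
    for f, (i0, i1, i2) in enumerate(faces):
        v0, v1, v2 = vertices[i0], vertices[i1], vertices[i2]
        e1, e2 = v1 - v0, v2 - v0
        pvec = np.cross(direction, e2)
        det = _dot3(pvec, e1)
        scale = np.linalg.norm(e1) * np.linalg.norm(e2)
        if abs(det) <= PARALLEL_EPS * scale:
            continue
        tvec = origin - v0
        u = _dot3(pvec, tvec) / det
        qvec = np.cross(tvec, e1)
        v = _dot3(direction, qvec) / det
        t = _dot3(e2, qvec) / det
        if u >= -BARY_EPS and v >= -BARY_EPS and u + v <= 1.0 + BARY_EPS and t > T_MIN:
            if t < best_t:
                best_t, best_tri = t, f
    return best_t, best_tri


def pca_via_covariance(X):
    """PCA through the explicit sample covariance matrix (eigendecomposition).

    Returns mean, eigenvalues (descending, tiny ones dropped) and
    eigenvectors as columns.
    """
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    C = np.cov(X - mean, rowvar=False, ddof=1)
    vals, vecs = np.linalg.eigh(np.atleast_2d(C))
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals = np.clip(vals, 0.0, None)
    keep = vals > 1e-10 * vals[0] if vals.size and vals[0] > 0 else np.zeros_like(vals, bool)
    return mean, vals[keep], vecs[:, keep]


def rmse_points(a, b):
    d = np.asarray(a, float).reshape(-1, 3) - np.asarray(b, float).reshape(-1, 3)
    return float(np.sqrt((d**2).sum(axis=1).mean()))


def loo_generalization_bruteforce(X, k):
    """Hand-rolled leave-one-out loop using covariance-matrix PCA."""
    X = np.asarray(X, dtype=float)
    out = []
    for i in range(len(X)):
        rest = np.delete(X, i, axis=0)
        mean, vals, vecs = pca_via_covariance(rest)
        kk = min(k, vecs.shape[1])
        scores = (X[i] - mean) @ vecs[:, :kk]
        rec = mean + vecs[:, :kk] @ scores
        out.append(rmse_points(X[i], rec))
    return np.asarray(out)


def specificity_bruteforce(mean, eigenvalues, eigenvectors, train, k, n_samples, seed):
    """Hand-rolled specificity loop sharing the documented seed stream."""
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal((n_samples, k)) * np.sqrt(eigenvalues[:k])
    vals = []
    for s in range(n_samples):
        sample = mean + eigenvectors[:, :k] @ draws[s]
        vals.append(min(rmse_points(sample, row) for row in train))
    return np.asarray(vals)
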