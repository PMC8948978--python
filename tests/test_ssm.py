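import numpy as np
import pytest

from neckssm import (
    explained_variance,
    fit_ssm,
    generate_cohort,
    mode_mesh,
    parametrize,
    project,
    reconstruct,
    sd_coverage,
)
from neckssm.correspond import ShapeCohort, process_grid
from neckssm.ssm import SSMModel, score_bounds
from neckssm.synthetic import _shape_functional
from neckssm.parametrize import ParametrizationConfig

from conftest import small_cohort_spec
from oracles import pca_via_covariance


def random_cohort(n=8, n_rings=5, n_rays=12, seed=0, scale=1.0):
    rng = np.random.default_rng(seed)
    return ShapeCohort(
        [f"P{i}" for i in range(n)],
        rng.normal(scale=scale, size=(n, 3 * n_rings * n_rays)),
        n_rings, n_rays,
    )


class TestFitSSM:
    def test_matches_covariance_eigendecomposition(self):
        cohort = random_cohort(n=9, seed=4)
        model = fit_ssm(cohort)
        mean_o, vals_o, vecs_o = pca_via_covariance(cohort.matrix)
        np.testing.assert_allclose(model.mean, mean_o, rtol=1e-12)
        np.testing.assert_allclose(model.eigenvalues, vals_o, rtol=1e-8)
        # eigenvectors agree up to sign for a non-degenerate spectrum
        dots = np.abs(np.einsum("ij,ij->j", model.eigenvectors, vecs_o))
        np.testing.assert_allclose(dots, 1.0, atol=1e-8)

    def test_n_minus_one_components(self):
        model = fit_ssm(random_cohort(n=7))
        assert model.n_components == 6

    def test_identical_shapes_zero_components(self):
        row = np.linspace(0, 1, 180)
        cohort = ShapeCohort(["a", "b", "c"], np.tile(row, (3, 1)), 5, 12)
        model = fit_ssm(cohort)
        assert model.n_components == 0
        np.testing.assert_allclose(model.mean, row, atol=1e-12)

    def test_training_reconstruction_with_full_basis(self):
        cohort = random_cohort(n=6, scale=5.0)
        model = fit_ssm(cohort)
        rec = model.mean + model.scores @ model.eigenvectors.T
        np.testing.assert_allclose(rec, cohort.matrix, atol=1e-6)

    def test_eigenvalue_sum_conserves_total_variance(self):
        cohort = random_cohort(n=10, seed=2)
        model = fit_ssm(cohort)
        Xc = cohort.matrix - cohort.matrix.mean(axis=0)
        total = (Xc**2).sum() / (cohort.n - 1)
        np.testing.assert_allclose(model.eigenvalues.sum(), total, rtol=1e-8)

    def test_order_invariance(self):
        cohort = random_cohort(n=8, seed=5)
        perm = np.random.default_rng(0).permutation(cohort.n)
        shuffled = ShapeCohort([cohort.ids[i] for i in perm],
                               cohort.matrix[perm], cohort.n_rings, cohort.n_rays)
        m1, m2 = fit_ssm(cohort), fit_ssm(shuffled)
        np.testing.assert_allclose(m2.eigenvalues, m1.eigenvalues, rtol=1e-9)
        np.testing.assert_allclose(m2.eigenvectors, m1.eigenvectors, atol=1e-8)

    def test_orthonormal_columns(self):
        model = fit_ssm(random_cohort(n=9, seed=7))
        gram = model.eigenvectors.T @ model.eigenvectors
        np.testing.assert_allclose(gram, np.eye(model.n_components), atol=1e-9)

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            ShapeCohort(["a", "b"], np.zeros((2, 1080)))


class TestExplainedVariance:
    def test_fractions(self):
        model = fit_ssm(random_cohort(n=5, seed=1))
        frac, cum = explained_variance(model)
        np.testing.assert_allclose(frac.sum(), 1.0, rtol=1e-12)
        assert np.all(np.diff(cum) >= -1e-15)
        np.testing.assert_allclose(cum[-1], 1.0, rtol=1e-12)

    def test_simple_arithmetic(self):
        model = fit_ssm(random_cohort(n=5, seed=1))
        fake = SSMModel(
            mean=model.mean,
            eigenvectors=model.eigenvectors[:, :2],
            eigenvalues=np.array([3.0, 1.0]),
            scores=model.scores[:, :2],
            n_train=model.n_train,
            n_rings=model.n_rings,
            n_rays=model.n_rays,
        )
        frac, _ = explained_variance(fake)
        np.testing.assert_allclose(frac, [0.75, 0.25])


class TestProjectReconstruct:
    def test_mean_projects_to_zero(self):
        model = fit_ssm(random_cohort())
        np.testing.assert_allclose(project(model, model.mean), 0.0, atol=1e-9)

    def test_eigen_direction_score(self):
        model = fit_ssm(random_cohort(seed=3))
        lam = model.eigenvalues[0]
        shape = model.mean + 2 * np.sqrt(lam) * model.eigenvectors[:, 0]
        scores = project(model, shape)
        np.testing.assert_allclose(scores[0], 2 * np.sqrt(lam), rtol=1e-9)
        np.testing.assert_allclose(scores[1:], 0.0, atol=1e-9)

    def test_projector_identity_on_training(self):
        cohort = random_cohort(n=6, scale=3.0)
        model = fit_ssm(cohort)
        for x in cohort.matrix:
            rec = reconstruct(model, project(model, x))
            assert np.max(np.abs(rec - x)) < 1e-6

    def test_reconstruct_affine(self):
        model = fit_ssm(random_cohort())
        rng = np.random.default_rng(0)
        a = rng.normal(size=model.n_components)
        b = rng.normal(size=model.n_components)
        mid = reconstruct(model, (a + b) / 2)
        np.testing.assert_allclose(
            mid, (reconstruct(model, a) + reconstruct(model, b)) / 2, rtol=1e-10
        )

    def test_k_out_of_range(self):
        model = fit_ssm(random_cohort())
        with pytest.raises(ValueError):
            project(model, model.mean, k=model.n_components + 1)


class TestParameterRecovery:
    def test_single_mode_pc1_correlates_with_true_draws(self):
        spec = small_cohort_spec(
            n=60, seed=17,
            mode_variances=(4.0, 0.0, 0.0, 0.0, 0.0),
            noise_variance_fraction=0.02,
        )
        necks, truth = generate_cohort(spec)
        rows = [process_grid(parametrize(nk.mesh, nk.cll, nk.landmarks)) for nk in necks]
        model = fit_ssm(ShapeCohort([f"P{i}" for i in range(60)], np.vstack(rows)))
        r = np.corrcoef(model.scores[:, 0], truth["mode_scores"][:, 0])[0, 1]
        assert abs(r) > 0.99


class TestModeMesh:
    def test_zero_sd_is_mean_shape(self, small_cohort):
        cohort, _ = small_cohort
        model = fit_ssm(cohort)
        mm = mode_mesh(model, 0, 0.0)
        np.testing.assert_allclose(mm.mesh.vertices.reshape(-1), model.mean, atol=1e-12)

    def test_open_tube_triangulation(self, small_cohort):
        cohort, _ = small_cohort
        model = fit_ssm(cohort)
        mm = mode_mesh(model, 0, 3.0)
        assert mm.mesh.n_vertices == 360
        assert mm.mesh.n_faces == 2 * 9 * 36
        assert np.all(mm.mesh.triangle_areas() > 0)

    def test_single_mode_plus_minus_differ_along_generative_mode(self):
        spec = small_cohort_spec(
            n=30, seed=23,
            mode_variances=(4.0, 0.0, 0.0, 0.0, 0.0),
            noise_variance_fraction=0.01,
        )
        necks, _ = generate_cohort(spec)
        rows = [process_grid(parametrize(nk.mesh, nk.cll, nk.landmarks)) for nk in necks]
        model = fit_ssm(ShapeCohort([f"P{i}" for i in range(30)], np.vstack(rows)))
        hi = mode_mesh(model, 0, 3.0).mesh.vertices.reshape(-1)
        lo = mode_mesh(model, 0, -3.0).mesh.vertices.reshape(-1)
        diff = hi - lo
        # finite-difference direction of the true length mode
        import dataclasses

        cfg = ParametrizationConfig()
        p = spec.mean_params
        d = (_shape_functional(dataclasses.replace(p, length=p.length + 1), cfg)
             - _shape_functional(dataclasses.replace(p, length=p.length - 1), cfg))
        cos = abs(diff @ d) / (np.linalg.norm(diff) * np.linalg.norm(d))
        assert cos > 0.99

    def test_score_bounds_definition(self, small_cohort):
        cohort, _ = small_cohort
        model = fit_ssm(cohort)
        sd = np.sqrt(model.eigenvalues[0])
        lo, hi = score_bounds(model, 0)
        assert lo == pytest.approx(max(-3.0, model.scores[:, 0].min() / sd))
        assert hi == pytest.approx(min(3.0, model.scores[:, 0].max() / sd))

    def test_flags_non_normal_scores(self):
        # heavy right-skew along one direction -> Shapiro-Wilk rejects
        rng = np.random.default_rng(0)
        n, D = 40, 180
        direction = np.zeros(D)
        direction[0] = 1.0
        skew = rng.exponential(scale=10.0, size=n)
        X = skew[:, None] * direction[None, :] + 0.01 * rng.normal(size=(n, D))
        model = fit_ssm(ShapeCohort([f"P{i}" for i in range(n)], X, 5, 12))
        mm = mode_mesh(model, 0, 1.0)
        assert not mm.normal_scores
        assert mm.recommended_s[0] > -3.0  # skewed mode: lower bound flagged


class TestCoverage:
    def test_three_sd_coverage_closed_form(self):
        assert sd_coverage(3.0) == pytest.approx(0.9973002039367398, abs=1e-12)
        assert sd_coverage(1.0) == pytest.approx(0.6826894921370859, abs=1e-12)
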