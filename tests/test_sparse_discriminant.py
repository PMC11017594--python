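import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from omicselect.errors import (
    DegenerateFeatureError,
    DegenerateLabelsError,
    ValueDomainError,
)
from omicselect.io_tables import FeatureTable
from omicselect.preprocess import standardize_fit
from omicselect.sparse_discriminant import (
    DiscriminantInputs,
    build_inputs,
    classify,
    correlated_expansion,
    fit_sparse_lda,
    kkt_residual,
    lambda_path_loocv,
    quadratic_objective,
    select_model,
)


def random_spd_inputs(rng, p=6, n=30):
    """Well-conditioned random (W, d) pair for solver tests."""
    B = rng.standard_normal((n, p))
    W = B.T @ B / n + 0.2 * np.eye(p)
    d = rng.standard_normal(p)
    return DiscriminantInputs(
        W=W, d=d, mean1=np.zeros(p), mean2=d.copy(), n1=5, n2=5, gamma=0.0
    )


class TestBuildInputs:
    def test_identical_group_means_give_zero_d(self, rng):
        X = np.vstack([rng.standard_normal((4, 3))] * 2)
        y = np.array([0] * 4 + [1] * 4)
        inp = build_inputs(X, y)
        np.testing.assert_allclose(inp.d, 0.0, atol=1e-15)

    def test_hand_computed_p1(self):
        # p=1, groups (0,0) and (1,1): zero within-group variance
        X = np.array([[0.0], [0.0], [1.0], [1.0]])
        y = np.array([0, 0, 1, 1])
        inp = build_inputs(X, y)
        assert inp.d[0] == pytest.approx(0.5)
        assert inp.W[0, 0] == pytest.approx(inp.gamma)
        assert inp.gamma > 0

    def test_label_swap_flips_d_keeps_W(self, rng):
        X = rng.standard_normal((10, 4))
        y = np.array([0] * 5 + [1] * 5)
        a = build_inputs(X, y)
        b = build_inputs(X, 1 - y)
        np.testing.assert_allclose(a.d, -b.d, atol=1e-14)
        np.testing.assert_allclose(a.W, b.W, atol=1e-14)

    def test_small_class_rejected(self, rng):
        X = rng.standard_normal((4, 2))
        with pytest.raises(DegenerateLabelsError):
            build_inputs(X, np.array([0, 1, 1, 1]))


class TestFitSparseLda:
    def test_empty_selection_at_lambda_max(self, rng):
        inp = random_spd_inputs(rng)
        fit = fit_sparse_lda(inp, inp.lambda_max * 1.0001)
        assert not fit.selected and not np.any(fit.v)

    def test_orthonormal_closed_form(self):
        inp = DiscriminantInputs(
            W=np.eye(2), d=np.array([0.8, 0.1]), mean1=np.zeros(2),
            mean2=np.ones(2), n1=5, n2=5, gamma=0.0,
        )
        fit = fit_sparse_lda(inp, 0.5)
        np.testing.assert_allclose(fit.v, [0.3, 0.0], atol=1e-12)

    def test_kkt_on_random_instances(self, rng):
        for _ in range(30):
            inp = random_spd_inputs(rng, p=int(rng.integers(2, 10)))
            lam = float(rng.uniform(0.05, 1.2)) * inp.lambda_max
            fit = fit_sparse_lda(inp, lam)
            assert kkt_residual(inp.W, inp.d, lam, fit.v) <= 1e-6

    def test_matches_generic_qp_oracle(self, rng):
        for _ in range(5):
            inp = random_spd_inputs(rng, p=5)
            lam = 0.3 * inp.lambda_max
            fit = fit_sparse_lda(inp, lam)

            def obj(v):
                return quadratic_objective(inp.W, inp.d, lam, v)

            res = minimize(obj, np.zeros(5), method="Powell",
                           options={"maxiter": 100000, "xtol": 1e-12,
                                    "ftol": 1e-14})
            assert obj(fit.v) <= res.fun + 1e-10
            np.testing.assert_allclose(fit.v, res.x, atol=1e-5)

    def test_homogeneity_in_d_and_lambda(self, rng):
        inp = random_spd_inputs(rng)
        lam = 0.4 * inp.lambda_max
        f1 = fit_sparse_lda(inp, lam)
        scaled = DiscriminantInputs(
            W=inp.W, d=3.0 * inp.d, mean1=inp.mean1, mean2=inp.mean2,
            n1=inp.n1, n2=inp.n2, gamma=0.0,
        )
        f2 = fit_sparse_lda(scaled, 3.0 * lam)
        np.testing.assert_allclose(f2.v, 3.0 * f1.v, atol=1e-8)

    def test_selection_size_monotone_on_orthonormal_design(self, rng):
        # with W = I the solution is coordinatewise soft-thresholding,
        # so the active set can only grow as lambda decreases
        d = rng.standard_normal(12)
        inp = DiscriminantInputs(
            W=np.eye(12), d=d, mean1=np.zeros(12), mean2=d.copy(),
            n1=5, n2=5, gamma=0.0,
        )
        sizes = [
            len(fit_sparse_lda(inp, lam).selected)
            for lam in np.geomspace(inp.lambda_max, 1e-3 * inp.lambda_max, 15)
        ]
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))

    def test_factored_and_dense_kernels_agree(self, rng):
        X = rng.standard_normal((14, 25))
        y = np.array([0] * 7 + [1] * 7)
        inp = build_inputs(standardize_fit(X)[0], y)
        from dataclasses import replace

        lam = 0.5 * inp.lambda_max
        f_fact = fit_sparse_lda(inp, lam)
        f_dense = fit_sparse_lda(replace(inp, A=None), lam)
        np.testing.assert_allclose(f_fact.v, f_dense.v, atol=1e-9)


class TestClassify:
    def test_zero_training_error_on_separable(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((16, 5))
            y = np.array([0] * 8 + [1] * 8)
            X[:, 0] += y * 6.0  # 3-sd separated after standardization
            Xs = standardize_fit(X)[0]
            inp = build_inputs(Xs, y)
            fit = fit_sparse_lda(inp, 0.3 * inp.lambda_max)
            np.testing.assert_array_equal(classify(fit, Xs), y)

    def test_zero_v_predicts_majority_with_tie_rule(self, rng):
        X = rng.standard_normal((10, 3))
        y = np.array([0] * 5 + [1] * 5)
        inp = build_inputs(X, y)
        fit = fit_sparse_lda(inp, 2 * inp.lambda_max)
        assert (classify(fit, X) == 0).all()

    def test_group_mean_assigned_to_its_group(self, rng):
        X = rng.standard_normal((12, 4))
        y = np.array([0] * 6 + [1] * 6)
        X[:, 1] += y * 4.0
        Xs = standardize_fit(X)[0]
        inp = build_inputs(Xs, y)
        fit = fit_sparse_lda(inp, 0.2 * inp.lambda_max)
        preds = classify(fit, np.vstack([inp.mean1, inp.mean2]))
        assert preds.tolist() == [0, 1]


class TestLambdaPathLoocv:
    def test_separable_reaches_zero_mcr(self, rng):
        n = 18
        y = np.array([0] * 9 + [1] * 9)
        X = rng.standard_normal((n, 12))
        X[:, 0] = y * 8.0 + rng.standard_normal(n) * 0.1
        path = lambda_path_loocv(X, y, grid_size=20)
        assert path.loo_mcr.min() == 0.0

    def test_grid_size_one_is_empty_model_at_lambda_max(self, labeled_matrix):
        X, y = labeled_matrix
        path = lambda_path_loocv(X, y, grid_size=1)
        assert len(path.lambda_grid) == 1
        assert path.sizes[0] == 0
        # the full-data fit predicts the training majority everywhere
        fit = path.fits[0]
        from omicselect.sparse_discriminant import classify

        assert (classify(fit, X) == fit.majority_class).all()

    def test_top_of_grid_has_empty_selection(self, labeled_matrix):
        X, y = labeled_matrix
        path = lambda_path_loocv(X, y, grid_size=8)
        assert path.sizes[0] == 0

    def test_small_n_rejected(self, rng):
        X = rng.standard_normal((4, 3))
        with pytest.raises(ValueDomainError):
            lambda_path_loocv(X, np.array([0, 0, 1, 1]))


class TestSelectModel:
    def _path(self, miscounts, sizes, labeled_matrix):
        X, y = labeled_matrix
        path = lambda_path_loocv(X, y, grid_size=len(miscounts))
        path.loo_miscount = np.asarray(miscounts)
        path.loo_mcr = path.loo_miscount / path.n
        path.sizes = np.asarray(sizes)
        return path

    def test_sparsest_tie_rule(self, labeled_matrix):
        path = self._path([8, 4, 4, 6], [0, 2, 5, 9], labeled_matrix)
        fit = select_model(path, "min_mcr_sparsest")
        assert fit.lam == path.lambda_grid[1]

    def test_min_mcr_takes_richest_minimizer(self, labeled_matrix):
        path = self._path([8, 4, 4, 6], [0, 2, 5, 9], labeled_matrix)
        fit = select_model(path, "min_mcr")
        assert fit.lam == path.lambda_grid[2]

    def test_fixed_size_prefers_larger_lambda(self, labeled_matrix):
        path = self._path([8, 4, 4, 6], [0, 3, 3, 9], labeled_matrix)
        fit = select_model(path, "fixed_size", k=3)
        assert fit.lam == path.lambda_grid[1]

    def test_fixed_size_requires_k(self, labeled_matrix):
        path = self._path([1, 2], [0, 1], labeled_matrix)
        with pytest.raises(ValueDomainError):
            select_model(path, "fixed_size")


class TestCorrelatedExpansion:
    def _table(self, X):
        return FeatureTable(
            pd.DataFrame(X, index=[f"s{i}" for i in range(X.shape[0])],
                         columns=[f"f{j}" for j in range(X.shape[1])])
        )

    def test_duplicate_column_included(self, rng):
        X = rng.standard_normal((10, 3))
        X[:, 2] = X[:, 0]
        out = correlated_expansion(self._table(X), ["f0"], 0.95)
        assert "f2" in out and out["f2"][1] == pytest.approx(1.0)

    def test_independent_noise_excluded(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((18, 5))
            out = correlated_expansion(self._table(X), ["f0"], 0.95)
            hits += len(out)
        assert hits == 0

    def test_unattainable_threshold_empty(self, rng):
        X = rng.standard_normal((10, 4))
        X[:, 1] = X[:, 0]
        assert correlated_expansion(self._table(X), ["f0"], 1.01) == {}

    def test_zero_variance_anchor_raises(self, rng):
        X = rng.standard_normal((8, 2))
        X[:, 0] = 1.0
        with pytest.raises(DegenerateFeatureError):
            correlated_expansion(self._table(X), ["f0"], 0.9)

    def test_anti_correlated_included_by_magnitude(self, rng):
        X = rng.standard_normal((10, 2))
        X[:, 1] = -X[:, 0]
        out = correlated_expansion(self._table(X), ["f0"], 0.95)
        assert out["f1"][1] == pytest.approx(-1.0)
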