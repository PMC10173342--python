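"""Non-negative PARAFAC core: NNLS, ALS fitting, diagnostics, matching."""

import numpy as np
import pytest
import scipy.optimize
from hypothesis import given, settings
from hypothesis import strategies as st

from eemviva.parafac import (
    ParafacModel,
    canonicalize,
    corcondia,
    explained_variance,
    fit_parafac,
    local_maxima,
    match_components,
    nnls_solve,
    tucker_congruence,
)

from conftest import exact_tensor, random_nonneg_factors


def nnls_objective(design, target, beta):
    return float(((design @ beta - target) ** 2).sum())


def grid_search_nnls(design, target, upper=2.0):
    """Coarse-to-fine dense grid search over the non-negative orthant."""
    n = design.shape[1]
    center = np.full(n, upper / 2)
    half = upper / 2
    best = center
    for res in (0.05, 0.002, 1e-4):
        axes = [np.clip(np.arange(c - half, c + half + res / 2, res), 0, None)
                for c in best]
        grids = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([g.ravel() for g in grids], axis=1)
        obj = ((pts @ design.T - target) ** 2).sum(axis=1)
        best = pts[np.argmin(obj)]
        half = 2 * res
    return best


class TestNNLS:
    def test_unconstrained_optimum_passes_through(self):
        np.testing.assert_allclose(nnls_solve(np.eye(2), np.array([1.0, 2.0])), [1, 2])

    def test_active_constraint_projection(self):
        np.testing.assert_allclose(nnls_solve(np.eye(2), np.array([-1.0, 2.0])), [0, 2])

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(42)
        design = rng.normal(size=(4, 3))
        target = rng.normal(size=4)
        beta = nnls_solve(design, target)
        beta_grid = grid_search_nnls(design, target)
        assert nnls_objective(design, target, beta) <= (
            nnls_objective(design, target, beta_grid) + 1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_scipy_active_set(self, seed):
        rng = np.random.default_rng(seed)
        design = rng.normal(size=(8, 4))
        target = rng.normal(size=8)
        ours = nnls_solve(design, target)
        ref, _ = scipy.optimize.nnls(design, target)
        np.testing.assert_allclose(ours, ref, atol=1e-9)

    def test_multiple_targets_columnwise(self):
        rng = np.random.default_rng(7)
        design = rng.normal(size=(6, 3))
        targets = rng.normal(size=(6, 5))
        out = nnls_solve(design, targets)
        assert out.shape == (3, 5)
        for c in range(5):
            ref, _ = scipy.optimize.nnls(design, targets[:, c])
            np.testing.assert_allclose(out[:, c], ref, atol=1e-9)

    def test_rank_deficient_rejected_without_ridge(self):
        design = np.ones((4, 2))
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            nnls_solve(design, np.ones(4))
        out = nnls_solve(design, np.ones(4), ridge=1e-8)
        assert (out >= 0).all()

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_nonnegative_and_no_worse_than_clipping(self, seed):
        rng = np.random.default_rng(seed)
        design = rng.normal(size=(6, 3))
        target = rng.normal(size=6)
        beta = nnls_solve(design, target)
        assert (beta >= 0).all()
        clipped = np.clip(np.linalg.lstsq(design, target, rcond=None)[0], 0, None)
        assert nnls_objective(design, target, beta) <= (
            nnls_objective(design, target, clipped) + 1e-10)


class TestFitParafac:
    def test_exact_rank2_recovery(self):
        A, B, C = random_nonneg_factors(8, 7, 6, 2, seed=0)
        X = exact_tensor(A, B, C)
        model, diag = fit_parafac(X, 2, n_starts=3, seed=1)
        assert diag.explained_variance_pct >= 99.9999
        truth = ParafacModel(F=2, scores=A, em_loadings=B, ex_loadings=C)
        _, cong = match_components(truth, model, mode="both")
        assert cong.min() >= 0.999

    def test_exact_rank1_recovery(self):
        A, B, C = random_nonneg_factors(5, 6, 4, 1, seed=2)
        X = exact_tensor(A, B, C)
        model, diag = fit_parafac(X, 1, n_starts=2, seed=3)
        assert tucker_congruence(model.em_loadings[:, 0], B[:, 0]) >= 0.999999
        assert tucker_congruence(model.ex_loadings[:, 0], C[:, 0]) >= 0.999999

    @pytest.mark.parametrize("F", [2, 3, 4])
    def test_exact_recovery_across_ranks(self, F):
        A, B, C = random_nonneg_factors(F + 4, F + 3, F + 2, F, seed=F)
        X = exact_tensor(A, B, C)
        model, _ = fit_parafac(X, F, n_starts=4, seed=F + 10)
        truth = ParafacModel(F=F, scores=A, em_loadings=B, ex_loadings=C)
        _, cong = match_components(truth, model, mode="both")
        assert cong.min() >= 0.999

    def test_sse_trace_monotone(self):
        A, B, C = random_nonneg_factors(10, 8, 6, 3, seed=5)
        X = exact_tensor(A, B, C) + 0.01 * np.random.default_rng(5).random((10, 8, 6))
        _, diag = fit_parafac(X, 3, n_starts=3, seed=6)
        trace = diag.sse_trace
        assert np.all(np.diff(trace) <= 1e-9 * trace[0])

    def test_deterministic_given_seed(self):
        A, B, C = random_nonneg_factors(7, 6, 5, 2, seed=8)
        X = exact_tensor(A, B, C) + 0.01 * np.random.default_rng(8).random((7, 6, 5))
        m1, _ = fit_parafac(X, 2, n_starts=3, seed=9)
        m2, _ = fit_parafac(X, 2, n_starts=3, seed=9)
        np.testing.assert_array_equal(m1.scores, m2.scores)
        np.testing.assert_array_equal(m1.em_loadings, m2.em_loadings)
        np.testing.assert_array_equal(m1.ex_loadings, m2.ex_loadings)

    def test_all_factors_nonnegative(self):
        rng = np.random.default_rng(12)
        X = rng.random((9, 7, 5))
        model, _ = fit_parafac(X, 3, n_starts=2, seed=13)
        assert model.scores.min() >= 0
        assert model.em_loadings.min() >= 0
        assert model.ex_loadings.min() >= 0

    def test_canonical_form(self):
        rng = np.random.default_rng(14)
        X = rng.random((9, 7, 5))
        model, _ = fit_parafac(X, 3, n_starts=2, seed=15)
        np.testing.assert_allclose(np.linalg.norm(model.em_loadings, axis=0), 1.0)
        np.testing.assert_allclose(np.linalg.norm(model.ex_loadings, axis=0), 1.0)
        energy = (model.scores ** 2).sum(axis=0)
        assert np.all(np.diff(energy) <= 1e-9)

    def test_nonfinite_input_rejected(self):
        X = np.full((4, 3, 2), np.nan)
        with pytest.raises(ValueError, match="finite|preprocess"):
            fit_parafac(X, 1)

    def test_invalid_F_rejected(self):
        with pytest.raises(ValueError):
            fit_parafac(np.ones((4, 3, 2)), 0)


class TestExplainedVariance:
    def test_zero_residual_is_100(self):
        A, B, C = random_nonneg_factors(5, 4, 3, 2, seed=20)
        X = exact_tensor(A, B, C)
        model = ParafacModel(F=2, scores=A, em_loadings=B, ex_loadings=C)
        assert explained_variance(model, X) == pytest.approx(100.0)

    def test_zero_model_on_nonzero_data_is_0(self):
        model = ParafacModel(F=1, scores=np.zeros((5, 1)),
                             em_loadings=np.zeros((4, 1)), ex_loadings=np.zeros((3, 1)))
        X = np.ones((5, 4, 3))
        assert explained_variance(model, X) == pytest.approx(0.0)

    def test_simple_ratio(self):
        # residual SS 1 on data SS 100 -> 99.0
        X = np.zeros((1, 1, 100))
        X[0, 0, :] = 1.0
        model = ParafacModel(F=1, scores=np.ones((1, 1)),
                             em_loadings=np.ones((1, 1)),
                             ex_loadings=np.concatenate([np.ones(99), [0.0]])[:, None])
        assert explained_variance(model, X) == pytest.approx(99.0)

    def test_all_zero_cube_rejected(self):
        model = ParafacModel(F=1, scores=np.ones((2, 1)),
                             em_loadings=np.ones((2, 1)), ex_loadings=np.ones((2, 1)))
        with pytest.raises(ValueError, match="zero"):
            explained_variance(model, np.zeros((2, 2, 2)))


def brute_force_core(A, B, C, X):
    """Least-squares Tucker core via the explicit Khatri-Rao normal equations."""
    F = A.shape[1]
    cols = []
    for f in range(F):
        for g in range(F):
            for h in range(F):
                cols.append(np.einsum("i,j,k->ijk", A[:, f], B[:, g], C[:, h]).ravel())
    design = np.stack(cols, axis=1)
    gvec, *_ = np.linalg.lstsq(design, X.ravel(), rcond=None)
    return gvec.reshape(F, F, F)


class TestCorcondia:
    def test_exact_rank2_core_is_superidentity(self):
        A, B, C = random_nonneg_factors(6, 5, 4, 2, seed=30)
        X = exact_tensor(A, B, C)
        model, diag = fit_parafac(X, 2, n_starts=3, seed=31)
        assert diag.core_consistency_pct == pytest.approx(100.0, abs=1e-6)

    def test_one_component_canonical_model_is_100(self):
        rng = np.random.default_rng(32)
        X = rng.random((6, 5, 4))
        model, diag = fit_parafac(X, 1, n_starts=2, seed=33)
        assert diag.core_consistency_pct == pytest.approx(100.0, abs=1e-8)

    def test_overfactored_matches_brute_force_core(self):
        A, B, C = random_nonneg_factors(6, 5, 4, 1, seed=34)
        X = exact_tensor(A, B, C)
        model, _ = fit_parafac(X, 2, n_starts=4, seed=35)
        G = brute_force_core(model.scores, model.em_loadings, model.ex_loadings, X)
        F = 2
        T = np.zeros((F, F, F))
        T[np.arange(F), np.arange(F), np.arange(F)] = 1.0
        expected = 100.0 * (1.0 - ((G - T) ** 2).sum() / (T ** 2).sum())
        assert corcondia(model, X) == pytest.approx(expected, abs=1e-8)


class TestMatchComponents:
    def test_self_match_is_identity(self):
        A, B, C = random_nonneg_factors(6, 5, 4, 3, seed=40)
        m = ParafacModel(F=3, scores=A, em_loadings=B, ex_loadings=C)
        perm, cong = match_components(m, m, mode="both")
        np.testing.assert_array_equal(perm, [0, 1, 2])
        np.testing.assert_allclose(cong, 1.0)

    def test_column_swap_recovered(self):
        A, B, C = random_nonneg_factors(6, 5, 4, 3, seed=41)
        m = ParafacModel(F=3, scores=A, em_loadings=B, ex_loadings=C)
        order = [2, 0, 1]
        m2 = ParafacModel(F=3, scores=A[:, order], em_loadings=B[:, order],
                          ex_loadings=C[:, order])
        perm, cong = match_components(m, m2, mode="both")
        np.testing.assert_array_equal(perm, [1, 2, 0])
        np.testing.assert_allclose(cong, 1.0)

    def test_independent_refits_agree(self):
        A, B, C = random_nonneg_factors(8, 7, 6, 3, seed=42)
        X = exact_tensor(A, B, C)
        m1, _ = fit_parafac(X, 3, n_starts=3, seed=43)
        m2, _ = fit_parafac(X, 3, n_starts=3, seed=44)
        _, cong = match_components(m1, m2, mode="both")
        assert cong.min() >= 0.999

    def test_mismatched_F_rejected(self):
        A, B, C = random_nonneg_factors(5, 4, 3, 2, seed=45)
        m2 = ParafacModel(F=2, scores=A, em_loadings=B, ex_loadings=C)
        A1, B1, C1 = random_nonneg_factors(5, 4, 3, 1, seed=46)
        m1 = ParafacModel(F=1, scores=A1, em_loadings=B1, ex_loadings=C1)
        with pytest.raises(ValueError):
            match_components(m1, m2)


class TestUtilities:
    def test_local_maxima_with_height_filter(self):
        x = np.arange(10)
        y = np.array([0, 1, 0, 0.05, 0, 5, 0, 3, 0, 0.0])
        assert local_maxima(y, x) == [1, 3, 5, 7]
        assert local_maxima(y, x, min_rel_height=0.1) == [1, 5, 7]

    def test_canonicalize_preserves_reconstruction(self):
        rng = np.random.default_rng(50)
        A, B, C = rng.random((6, 3)), rng.random((5, 3)), rng.random((4, 3))
        X = exact_tensor(A, B, C)
        A2, B2, C2 = canonicalize(A, B, C)
        np.testing.assert_allclose(exact_tensor(A2, B2, C2), X, atol=1e-12)
        np.testing.assert_allclose(np.linalg.norm(B2, axis=0), 1.0)
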