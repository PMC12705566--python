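"""Non-negative CP fitting, CORCONDIA, split-half analysis and score projection.

The cross-check oracle here is a deliberately independent *unconstrained*
CP-ALS (normal equations via pseudo-inverse, no NNLS, no restarts) — a
different algorithm and code path from the package's solver. On tensors whose
true factors are strictly positive, both must reach the same fit error.
"""

import numpy as np
import pytest

from eemstress.parafac import (
    RankSelection,
    core_consistency,
    decimate_emission,
    fit_parafac,
    match_components,
    project_scores,
    select_rank,
    split_half,
    tucker_congruence,
)


# ---------------------------------------------------------------------------
# independent oracle
# ---------------------------------------------------------------------------


def cp_als_unconstrained(X, F, n_iter=400, seed=0):
    """Plain CP-ALS via pinv of Khatri-Rao products. Returns fit-error fraction."""
    rng = np.random.default_rng(seed)
    n, p, q = X.shape
    A = rng.standard_normal((n, F))
    B = rng.standard_normal((p, F))
    C = rng.standard_normal((q, F))

    def kr(U, V):
        return (U[:, None, :] * V[None, :, :]).reshape(-1, U.shape[1])

    X0 = X.reshape(n, -1)
    X1 = np.moveaxis(X, 1, 0).reshape(p, -1)
    X2 = np.moveaxis(X, 2, 0).reshape(q, -1)
    for _ in range(n_iter):
        A = X0 @ np.linalg.pinv(kr(B, C)).T
        B = X1 @ np.linalg.pinv(kr(A, C)).T
        C = X2 @ np.linalg.pinv(kr(A, B)).T
    resid = X0 - A @ kr(B, C).T
    return float((resid**2).sum() / (X**2).sum())


@pytest.fixture(scope="module")
def rank1(fixtures):
    return fixtures["rank1_tensor"], fixtures["rank1_factors"]


@pytest.fixture(scope="module")
def three(fixtures):
    return fixtures["three_component_tensor"], fixtures["three_component_factors"]


class TestFit:
    def test_exact_rank_one(self, rank1):
        X, (a, b, c) = rank1
        m = fit_parafac(X, 1, n_restarts=3, seed=0)
        assert m.fit_error < 1e-6
        assert tucker_congruence(m.ex_loadings[:, 0], b) > 0.9999
        assert tucker_congruence(m.em_loadings[:, 0], c) > 0.9999
        assert tucker_congruence(m.sample_scores[:, 0], a) > 0.9999

    def test_three_component_recovery(self, three):
        X, (A, B, C) = three
        m = fit_parafac(X, 3, seed=0)
        assert m.fit_error < 1e-6
        truth = np.vstack([B / np.linalg.norm(B, axis=0), C / np.linalg.norm(C, axis=0)])
        fitted = np.vstack([m.ex_loadings, m.em_loadings])
        _, congs = match_components(truth, fitted)
        assert min(congs) >= 0.99

    def test_deterministic_given_seed(self, three):
        X, _ = three
        m1 = fit_parafac(X, 2, n_restarts=2, max_iter=50, seed=42)
        m2 = fit_parafac(X, 2, n_restarts=2, max_iter=50, seed=42)
        np.testing.assert_array_equal(m1.sample_scores, m2.sample_scores)
        np.testing.assert_array_equal(m1.em_loadings, m2.em_loadings)
        assert m1.fit_error == m2.fit_error

    def test_fit_error_monotone_over_iterations(self, three, rng):
        X, _ = three
        noisy = X + rng.normal(0, 0.05 * X.mean(), X.shape)
        m = fit_parafac(noisy, 3, n_restarts=2, seed=1)
        h = np.asarray(m.fit_error_history)
        assert np.all(np.diff(h) <= 1e-10)

    def test_loadings_unit_norm_and_reconstruction(self, three):
        X, _ = three
        m = fit_parafac(X, 3, seed=0)
        np.testing.assert_allclose(np.linalg.norm(m.ex_loadings, axis=0), 1.0, rtol=1e-9)
        np.testing.assert_allclose(np.linalg.norm(m.em_loadings, axis=0), 1.0, rtol=1e-9)
        np.testing.assert_allclose(m.reconstruct(), X, atol=1e-5 * X.max())

    def test_input_validation(self, three):
        X, _ = three
        with pytest.raises(ValueError, match="dimension"):
            fit_parafac(X, 50)
        bad = X.copy()
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit_parafac(bad, 2)

    def test_matches_unconstrained_oracle_on_noisy_tensor(self, rng):
        """Fit error within 1e-3 of an independent CP-ALS at the same rank."""
        F = 3
        A = rng.uniform(0.5, 2.0, (20, F))
        B = rng.uniform(0.5, 2.0, (10, F))
        C = rng.uniform(0.5, 2.0, (15, F))
        X = np.einsum("if,jf,kf->ijk", A, B, C)
        X += rng.normal(0, 0.02 * X.mean(), X.shape)
        X = np.clip(X, 0, None)
        ours = fit_parafac(X, F, seed=0).fit_error
        oracle = cp_als_unconstrained(X, F, seed=0)
        assert ours == pytest.approx(oracle, abs=1e-3)


class TestCoreConsistency:
    def test_correct_rank_near_100(self, three):
        X, _ = three
        m = fit_parafac(X, 3, seed=0)
        assert core_consistency(m, X) > 99

    def test_rank_one_exactly_100(self, rank1):
        X, _ = rank1
        m = fit_parafac(X, 1, n_restarts=2, seed=0)
        assert core_consistency(m, X) == 100.0

    def test_overfactoring_collapses(self, three, rng):
        X, _ = three
        noisy = X + np.abs(rng.normal(0, 0.01 * X.mean(), X.shape))
        m6 = fit_parafac(noisy, 6, seed=0)
        assert core_consistency(m6, noisy) < 50

    def test_degenerate_loadings_flagged_not_raised(self, three):
        X, _ = three
        m = fit_parafac(X, 3, seed=0)
        m.ex_loadings[:, 1] = m.ex_loadings[:, 0]  # force rank deficiency
        with pytest.warns(RuntimeWarning, match="degenerate"):
            assert np.isnan(core_consistency(m, X))


class TestSplitHalf:
    def test_noiseless_three_component_above_99(self, three):
        X, _ = three
        assert split_half(X, 3, seed=0) > 99

    def test_deterministic(self, three):
        X, _ = three
        assert split_half(X, 2, seed=5) == split_half(X, 2, seed=5)

    def test_needs_four_samples(self, three):
        X, _ = three
        with pytest.raises(ValueError, match="4 samples"):
            split_half(X[:3], 2)


class TestSelectRank:
    def test_rank_one_tensor_chooses_one(self, rank1):
        X, _ = rank1
        sel = select_rank(X, range(1, 4), seed=0)
        assert isinstance(sel, RankSelection)
        assert sel.chosen == 1
        assert len(sel.diagnostics) == 3
        assert set(sel.diagnostics.columns) >= {
            "n_components",
            "fit_error",
            "core_consistency",
            "split_half_similarity",
        }

    def test_empty_admissible_set_warns_and_returns_smallest(self, rng):
        X = np.abs(rng.standard_normal((12, 6, 7)))  # unstructured noise
        with pytest.warns(RuntimeWarning, match="no candidate"):
            sel = select_rank(X, [4, 5], split_half_min=99.99, seed=0)
        assert sel.chosen == 4 and sel.warning


class TestProjectScores:
    def test_training_samples_reproject_to_their_scores(self, three):
        X, _ = three
        m = fit_parafac(X, 3, seed=0)
        sc = project_scores(m, X)
        scale = np.abs(m.sample_scores).max()
        assert np.abs(sc - m.sample_scores).max() / scale < 0.01

    def test_zero_and_linearity(self, three):
        X, _ = three
        m = fit_parafac(X, 3, seed=0)
        np.testing.assert_allclose(project_scores(m, np.zeros_like(X[:1])), 0.0, atol=1e-12)
        s1 = project_scores(m, X[:4])
        s2 = project_scores(m, 2.0 * X[:4])
        np.testing.assert_allclose(s2, 2.0 * s1, rtol=1e-6)

    def test_grid_mismatch_rejected(self, three):
        X, _ = three
        m = fit_parafac(X, 2, n_restarts=2, max_iter=50, seed=0)
        with pytest.raises(ValueError, match="grid"):
            project_scores(m, np.zeros((2, 4, 4)))


def test_decimate_emission(three):
    X, _ = three
    assert decimate_emission(X, 4).shape == (20, 10, 4)
    with pytest.raises(ValueError):
        decimate_emission(X, 0)
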