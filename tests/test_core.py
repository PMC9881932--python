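import numpy as np
import pytest

from paca.cca import sample_space_cca
from paca.core import (
    classify_scenario,
    fit_paca,
    pc_variance_pair,
    permutation_null_variance,
    select_k,
)
from paca.datamodel import AnalysisConfig, DataMatrix, ValidationError
from paca.evaluation import abs_corr
from paca.io import standardize
from paca.simulate import SimParams, simulate

from conftest import random_pair


def _dm(values, role="target", prefix="s"):
    m, n = values.shape
    return DataMatrix(values,
                      np.array([f"f{i}" for i in range(m)], dtype=object),
                      np.array([f"{prefix}{i}" for i in range(n)], dtype=object),
                      role)


class TestPCVariancePair:
    def test_rank_one_construction(self):
        rng = np.random.default_rng(0)
        w = rng.standard_normal(40)
        w /= np.linalg.norm(w)
        s = rng.standard_normal(12)
        s -= s.mean()
        x = _dm(3.0 * np.outer(w, s))
        y = _dm(np.zeros((40, 8)), "background", "k")
        pv = pc_variance_pair(x, y)
        assert pv.var_x == pytest.approx(9.0 * np.var(s, ddof=1), rel=1e-10)
        assert pv.var_y == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_inputs_give_equal_variances(self):
        X, _ = random_pair(m=30, n1=6, n0=6, seed=1)
        y = _dm(X.values.copy(), "background", "k")
        pv = pc_variance_pair(X, y)
        assert pv.var_x == pytest.approx(pv.var_y, abs=1e-10)

    def test_var_x_matches_top_covariance_eigenvalue(self):
        rng = np.random.default_rng(2)
        vals = rng.standard_normal((100, 20))
        vals -= vals.mean(axis=1, keepdims=True)
        x = _dm(vals)
        y = _dm(rng.standard_normal((100, 25)), "background", "k")
        pv = pc_variance_pair(x, y)
        top = np.linalg.eigvalsh(vals @ vals.T / (20 - 1)).max()
        assert pv.var_x == pytest.approx(top, abs=1e-8)

    def test_zero_case_residual_flags_degenerate(self):
        x = _dm(np.zeros((10, 4)))
        y = _dm(np.ones((10, 4)) + np.arange(4), "background", "k")
        pv = pc_variance_pair(x, y)
        assert pv.var_x == 0.0 and pv.degenerate


class TestPermutationNull:
    def test_constant_loading_is_permutation_invariant(self):
        M, _ = random_pair(m=20, n1=6, n0=5, seed=3)
        loading = np.full(20, 1 / np.sqrt(20))
        null = permutation_null_variance(loading, M, 20, seed=0)
        observed = np.var(loading @ M.values, ddof=1)
        np.testing.assert_allclose(null, observed, rtol=1e-12)

    def test_fixed_seed_reproduces_null(self):
        M, _ = random_pair(m=30, n1=8, n0=5, seed=4)
        loading = np.random.default_rng(1).standard_normal(30)
        a = permutation_null_variance(loading, M, 50, seed=9)
        b = permutation_null_variance(loading, M, 50, seed=9)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("seed", range(20))
    def test_aligned_loading_beats_null_on_rank_one_structure(self, seed):
        rng = np.random.default_rng(seed)
        w = np.zeros(60)
        w[:5] = 1 / np.sqrt(5)  # sparse, so permutations destroy alignment
        s = rng.standard_normal(15)
        M = _dm(5.0 * np.outer(w, s) + 0.1 * rng.standard_normal((60, 15)))
        observed = np.var(w @ M.values, ddof=1)
        null = permutation_null_variance(w, M, 100, seed=seed)
        assert observed > null.max()


class TestClassifyScenario:
    null = np.linspace(0.5, 1.0, 100)

    def test_case_only_significance_is_scenario_i(self):
        assert classify_scenario(5.0, 0.7, self.null, self.null, 0.05, 10.0) == "i"

    def test_both_significant_low_ratio_is_scenario_ii(self):
        assert classify_scenario(5.0, 4.0, self.null, self.null, 0.05, 10.0) == "ii"

    def test_high_ratio_upgrades_to_ratio_pass(self):
        assert classify_scenario(40.0, 2.0, self.null, self.null, 0.05, 10.0) == "ii-ratio-pass"

    def test_zero_control_variance_counts_as_infinite_ratio(self):
        null_y = np.zeros(100)
        # var_y = 0 cannot be "significant" against a zero null
        assert classify_scenario(5.0, 0.0, self.null, null_y, 0.05, 10.0) == "i"

    def test_neither_significant_is_scenario_iii(self):
        assert classify_scenario(0.6, 0.6, self.null, self.null, 0.05, 10.0) == "iii"

    def test_control_only_significance_is_scenario_iv(self):
        assert classify_scenario(0.6, 5.0, self.null, self.null, 0.05, 10.0) == "iv"


class TestSelectK:
    def test_null_data_does_not_trip_assumption_violation(self):
        for seed in (0, 1, 2):
            X, Y, _ = simulate(SimParams(
                m=200, n1=80, n0=80, k0=20, signal_strength=0.0, seed=seed))
            Xc, Yc = standardize(X, "center"), standardize(Y, "center")
            cs = sample_space_cca(Xc, Yc)
            ks = select_k(Xc, Yc, cs, AnalysisConfig(seed=seed))
            assert ks.terminated_by != "scenario_iv"
            assert 0 <= ks.k_selected <= cs.R

    def test_weak_sparse_selection_tracks_true_dimension(self):
        # With a weak subtype axis most shared axes must come out: the mean
        # selected dimension should be at least half the simulated one.
        ks_vals = []
        for seed in range(5):
            X, Y, _ = simulate(SimParams(
                m=200, n1=100, n0=100, k0=40, signal_strength=1.5,
                sparsity=0.1, seed=100 + seed))
            fit = fit_paca(X, Y, AnalysisConfig(seed=seed))
            ks_vals.append(fit.k_selected)
        assert 20 <= np.mean(ks_vals) <= 100

    def test_trace_length_bounded_by_binary_search_depth(self):
        X, Y, _ = simulate(SimParams(m=200, n1=60, n0=60, k0=10,
                                     signal_strength=2.5, sparsity=1.0, seed=5))
        fit = fit_paca(X, Y, AnalysisConfig(seed=1))
        assert len(fit.k_selection.trace) <= int(np.ceil(np.log2(60))) + 2


class TestFitPaca:
    def test_strong_dense_signal_recovers_subtypes(self):
        X, Y, truth = simulate(SimParams(signal_strength=4.0, sparsity=1.0,
                                         prop=0.5, seed=3))
        fit = fit_paca(X, Y, AnalysisConfig(seed=1))
        assert abs_corr(fit.scores[:, 0], truth.subtype_labels) > 0.9

    def test_no_shared_structure_selects_zero_and_keeps_centered_cases(self):
        X, Y, _ = simulate(SimParams(m=200, n1=80, n0=80, k0=0,
                                     signal_strength=3.0, sparsity=1.0, seed=2))
        fit = fit_paca(X, Y, AnalysisConfig(seed=1))
        assert fit.k_selected == 0
        centered = X.values - X.values.mean(axis=1, keepdims=True)
        np.testing.assert_allclose(fit.x_residual.values, centered, atol=1e-10)

    def test_residual_orthogonal_to_selected_basis(self):
        X, Y, _ = simulate(SimParams(m=200, n1=60, n0=60, k0=15,
                                     signal_strength=2.5, sparsity=0.5, seed=7))
        fit = fit_paca(X, Y, AnalysisConfig(seed=2))
        assert fit.k_selected > 0
        assert np.abs(fit.shared_basis.T @ fit.x_residual.values).max() < 1e-8

    def test_scores_invariant_to_control_sample_order(self):
        X, Y, _ = simulate(SimParams(m=200, n1=60, n0=60, k0=10,
                                     signal_strength=2.5, sparsity=1.0, seed=9))
        cfg = AnalysisConfig(seed=4)
        fit1 = fit_paca(X, Y, cfg, n_components=2)
        perm = np.random.default_rng(0).permutation(Y.n_samples)
        fit2 = fit_paca(X, Y.subset_samples(perm), cfg, n_components=2)
        assert fit1.k_selected == fit2.k_selected
        for j in range(2):
            d = min(np.abs(fit1.scores[:, j] - fit2.scores[:, j]).max(),
                    np.abs(fit1.scores[:, j] + fit2.scores[:, j]).max())
            assert d < 1e-6

    def test_explained_variance_nonincreasing_loadings_orthonormal(self):
        X, Y, _ = simulate(SimParams(m=150, n1=50, n0=50, k0=10,
                                     signal_strength=2.5, sparsity=1.0, seed=11))
        fit = fit_paca(X, Y, AnalysisConfig(seed=0), n_components=5)
        assert np.all(np.diff(fit.explained_variance) <= 1e-10)
        np.testing.assert_allclose(fit.loadings.T @ fit.loadings, np.eye(5), atol=1e-8)

    def test_wide_data_directed_to_rpaca(self):
        X, Y = random_pair(m=10, n1=20, n0=20, seed=0)
        with pytest.raises(ValidationError, match="rpaca"):
            fit_paca(X, Y)

    def test_deterministic_given_seed(self):
        X, Y, _ = simulate(SimParams(m=150, n1=50, n0=50, k0=10,
                                     signal_strength=2.0, sparsity=0.5, seed=13))
        cfg = AnalysisConfig(seed=8)
        f1 = fit_paca(X, Y, cfg)
        f2 = fit_paca(X, Y, cfg)
        np.testing.assert_array_equal(f1.scores, f2.scores)
        assert f1.k_selected == f2.k_selected
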