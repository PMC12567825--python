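import dataclasses

import numpy as np
import pandas as pd
import pytest

from soilrisk.io import MetalParams
from soilrisk._defaults import METALS
from soilrisk.pmf import (PMFModel, align_factors, build_uncertainty,
                          factor_contributions, fit_pmf,
                          residual_diagnostics, select_n_factors,
                          snr_classes)
from soilrisk.synth import default_spec, generate_cohort, recovery_spec

from conftest import make_samples


class TestUncertainty:
    def test_below_mdl_uses_five_sixths(self, params):
        st = make_samples({"Cd": [0.005, 0.01, 1.0]})
        u = build_uncertainty(st, params)
        assert u["Cd"].iloc[0] == pytest.approx(5 / 6 * 0.01)
        assert u["Cd"].iloc[1] == pytest.approx(5 / 6 * 0.01)  # c == MDL

    def test_above_mdl_quadrature_formula(self, params):
        st = make_samples({"Cr": [10.0, 20.0]})
        u = build_uncertainty(st, params, rsd={m: 0.1 for m in METALS})
        # sqrt((0.1*10)^2 + (0.5*4)^2) = sqrt(1+4)
        assert u["Cr"].iloc[0] == pytest.approx(np.sqrt(5.0))

    def test_zero_rsd_limit_is_half_mdl(self, params):
        st = make_samples({"Cr": [10.0, 20.0]})
        u = build_uncertainty(st, params, rsd={m: 0.0 for m in METALS})
        assert u["Cr"].iloc[0] == pytest.approx(0.5 * 4.0)

    def test_missing_rsd_is_config_error(self, params):
        from soilrisk.io import ConfigError
        st = make_samples({"Cr": [10.0, 20.0]})
        with pytest.raises(ConfigError):
            build_uncertainty(st, params, rsd={"Cr": 0.1})

    def test_snr_classes(self):
        conc = pd.DataFrame({"a": [10.0, 10.0], "b": [1.0, 1.0],
                             "c": [0.1, 0.1]})
        unc = pd.DataFrame({"a": [1.0, 1.0], "b": [0.6, 0.6],
                            "c": [0.5, 0.5]})
        cls = snr_classes(conc, unc)
        assert cls["a"] == "strong"   # S/N = 9
        assert cls["b"] == "weak"     # S/N = (1-0.6)/0.6 = 0.67
        assert cls["c"] == "bad"      # below detection: S/N = 0


class TestSolver:
    def test_rank_one_matrix_perfectly_reconstructed(self):
        rng = np.random.default_rng(0)
        g = rng.uniform(1, 2, 30)[:, None]
        f = rng.uniform(1, 5, 6)[None, :]
        X = g @ f
        sol = fit_pmf(X, np.full_like(X, 0.5), 1, restarts=2, seed=0)
        assert sol.q_true < 1e-10
        assert (sol.G >= 0).all() and (sol.F >= 0).all()

    def test_objective_monotone_non_increasing(self):
        st, _ = generate_cohort(default_spec(seed=2, n_samples=60))
        X = st.concentrations()
        U = build_uncertainty(st, MetalParams.defaults())
        sol = PMFModel(X, U, 3, restarts=2, seed=0, max_iter=50).fit()
        diffs = np.diff(sol.q_history)
        assert (diffs <= 1e-9 * np.abs(sol.q_history[:-1]) + 1e-12).all()

    def test_scaling_uncertainty_scales_objective(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(1, 10, (25, 6))
        U = np.full_like(X, 1.0)
        a = fit_pmf(X, U, 2, restarts=3, seed=5)
        b = fit_pmf(X, 2 * U, 2, restarts=3, seed=5)
        # same optimum, objective divided by 4
        assert b.q_true == pytest.approx(a.q_true / 4.0, rel=1e-6)
        np.testing.assert_allclose(b.G @ b.F, a.G @ a.F, rtol=1e-5)

    def test_profiles_unit_row_sum_and_reconstruction_unchanged(self):
        st, _ = generate_cohort(default_spec(seed=3, n_samples=50))
        X = st.concentrations()
        U = build_uncertainty(st, MetalParams.defaults())
        sol = PMFModel(X, U, 3, restarts=2, seed=0, max_iter=100).fit()
        np.testing.assert_allclose(sol.F.sum(axis=1), 1.0, atol=1e-10)
        # E is exactly X - G @ F by construction
        np.testing.assert_allclose(sol.E, X.to_numpy() - sol.G @ sol.F,
                                   atol=1e-12)

    def test_row_permutation_invariance_after_alignment(self):
        st, _ = generate_cohort(default_spec(seed=4, n_samples=40))
        X = st.concentrations()
        U = build_uncertainty(st, MetalParams.defaults())
        a = PMFModel(X, U, 2, restarts=3, seed=0, max_iter=200).fit()
        perm_rows = np.random.default_rng(0).permutation(len(X))
        b = PMFModel(X.iloc[perm_rows], U.iloc[perm_rows], 2, restarts=3,
                     seed=0, max_iter=200).fit()
        perm, cos = align_factors(b.F, a.F, b.G, a.G)
        assert (cos > 0.999).all()

    def test_invalid_inputs_rejected(self):
        X = np.ones((5, 4))
        with pytest.raises(ValueError):
            PMFModel(X, -np.ones_like(X), 2)
        with pytest.raises(ValueError):
            PMFModel(X, np.ones_like(X), 0)


class TestContributions:
    def test_single_factor_is_100_percent(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(1, 5, 12)[:, None] @ rng.uniform(1, 3, 5)[None, :]
        sol = fit_pmf(X, np.full_like(X, 0.3), 1, restarts=2, seed=0)
        per_metal, overall = factor_contributions(sol)
        np.testing.assert_allclose(per_metal.to_numpy(), 100.0, atol=1e-8)
        assert overall.iloc[0] == pytest.approx(100.0)

    def test_two_identical_factors_split_evenly(self):
        sol = fit_pmf(np.ones((10, 4)) * 2.0, np.full((10, 4), 0.2), 2,
                      restarts=2, seed=1)
        # force exactly symmetric factors, then check the formula
        sol.G = np.ones((10, 2))
        sol.F = np.full((2, 4), 1.0)
        per_metal, overall = factor_contributions(sol)
        np.testing.assert_allclose(per_metal.to_numpy(), 50.0)
        np.testing.assert_allclose(overall.to_numpy(), 50.0)

    def test_shares_sum_to_100(self):
        st, _ = generate_cohort(default_spec(seed=5, n_samples=60))
        X = st.concentrations()
        U = build_uncertainty(st, MetalParams.defaults())
        sol = PMFModel(X, U, 3, restarts=2, seed=0, max_iter=200).fit()
        per_metal, overall = factor_contributions(sol)
        np.testing.assert_allclose(per_metal.sum(axis=0), 100.0, atol=1e-8)
        assert overall.sum() == pytest.approx(100.0, abs=1e-8)


class TestModelSelection:
    def test_single_candidate_range(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(1, 10, (30, 6))
        p, table = select_n_factors(X, np.full_like(X, 0.5), scan=(2, 2),
                                    restarts=2, seed=0)
        assert p == 2
        assert len(table) == 1

    def test_noise_free_rank4_scan_chooses_four(self):
        spec = recovery_spec(seed=1, n_samples=120)
        st, _ = generate_cohort(spec)
        X = st.concentrations()
        U = build_uncertainty(st, MetalParams.defaults())
        p, table = select_n_factors(X, U, scan=(3, 5), restarts=3, seed=0,
                                    max_iter=1500)
        assert list(table.index) == [3, 4, 5]
        # Q collapses at the true rank
        assert table.loc[4, "q_true"] < 1e-3 * table.loc[3, "q_true"]
        assert p == 4


class TestResidualDiagnostics:
    def test_gaussian_residuals_look_normal(self):
        spec = dataclasses.replace(default_spec(seed=6, n_samples=150),
                                   noise_cv=np.full(8, 0.05))
        st, _ = generate_cohort(spec)
        X = st.concentrations()
        U = build_uncertainty(st, MetalParams.defaults())
        sol = PMFModel(X, U, 4, restarts=3, seed=0, max_iter=300).fit()
        diag = residual_diagnostics(sol)
        assert (diag["shapiro_w"] > 0.9).mean() >= 0.75

    def test_injected_outliers_flagged(self):
        rng = np.random.default_rng(4)
        g = rng.uniform(1, 2, (80, 2))
        f = rng.uniform(1, 5, (2, 5))
        X = g @ f * (1 + 0.02 * rng.standard_normal((80, 5)))
        X[:10, 0] *= 8.0                     # heavy outliers in species 0
        sol = fit_pmf(X, 0.05 * X, 2, restarts=2, seed=0)
        diag = residual_diagnostics(sol)
        assert diag.iloc[0]["flagged"]

    def test_too_few_samples_skipped(self):
        X = np.ones((2, 4)) + np.arange(8).reshape(2, 4) * 0.1
        sol = fit_pmf(X, np.full_like(X, 0.2), 1, restarts=1, seed=0)
        diag = residual_diagnostics(sol)
        assert diag["shapiro_w"].isna().all()
        assert not diag["flagged"].any()
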