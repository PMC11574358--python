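"""Tests for the time-energy-budget regression and AICc pooling machinery."""

import numpy as np
import pytest

from kittiwake_energetics import calibration as cal
from kittiwake_energetics import synthetic
from kittiwake_energetics.states import BEHAVIOURS


def make_dataset(seed=0, noise=0.05, n=50, true_mr=None, with_vedba=False,
                 **kwargs):
    c = synthetic.simulate_calibration_cohort(n_birds=n, noise_frac=noise,
                                              seed=seed, true_mr=true_mr,
                                              **kwargs)
    tw = c.activity_vedba * c.budgets if with_vedba else None
    ds = cal.CalibrationDataset(dee_std=c.dee_std, budgets=c.budgets,
                                activity_vedba=tw, stage=c.stages)
    return ds, c


WELL_SEPARATED_MR = {"colony": 0.5, "rest_land": 1.1, "swimming": 1.8,
                     "flapping": 3.9, "gliding": 2.7}


class TestAicc:
    def test_formula(self):
        assert cal.aicc(0.0, 1, 100) == pytest.approx(2 + 4 / 98)

    def test_large_n_limit_is_aic(self):
        assert cal.aicc(-10.0, 3, 10**7) == pytest.approx(20 + 6, rel=1e-6)

    def test_monotone_in_k_at_fixed_loglik(self):
        vals = [cal.aicc(-50.0, k, 50) for k in range(1, 8)]
        assert np.all(np.diff(vals) > 0)

    def test_undefined_when_n_too_small(self):
        with pytest.raises(ValueError):
            cal.aicc(0.0, 10, 11)


class TestVif:
    def test_orthogonal_design_is_unity(self):
        X = np.kron(np.eye(3), np.ones(10)).T
        assert np.allclose(cal.vif(X), 1.0)

    def test_duplicated_column_is_infinite(self, rng):
        x = rng.normal(size=30)
        X = np.column_stack([x, x, rng.normal(size=30)])
        v = cal.vif(X)
        assert np.isinf(v[0]) and np.isinf(v[1])

    def test_matches_direct_r2_regression_oracle(self):
        """Budget design VIFs equal 1/(1-R2_j) with R2_j computed by an
        independent uncentred OLS (statsmodels)."""
        import statsmodels.api as sm
        _, c = make_dataset(seed=5)
        X = c.budgets
        ours = cal.vif(X)
        for j in range(X.shape[1]):
            r2 = sm.OLS(X[:, j], np.delete(X, j, axis=1)).fit().rsquared
            assert ours[j] == pytest.approx(1.0 / (1.0 - r2), rel=1e-6)


class TestBudgetModel:
    def test_exact_recovery_at_zero_noise(self):
        ds, c = make_dataset(noise=0.0)
        fit = cal.fit_budget_model(ds)
        assert np.allclose(fit.coefficients, c.true_coefficients, atol=1e-8)
        assert fit.terms == BEHAVIOURS

    def test_identical_budgets_are_rank_deficient(self):
        budgets = np.tile(np.array([0.5, 0.1, 0.15, 0.2, 0.05]), (20, 1))
        ds = cal.CalibrationDataset(dee_std=np.full(20, 600.0), budgets=budgets)
        with pytest.raises(np.linalg.LinAlgError):
            cal.fit_budget_model(ds)

    def test_pooled_grouping_sums_columns(self):
        ds, c = make_dataset(noise=0.0)
        fit = cal.fit_budget_model(ds, [("colony", "gliding"), ("rest_land",),
                                        ("swimming",), ("flapping",)])
        assert "colony+gliding" in fit.terms
        # colony and gliding share the true coefficient, so pooling is exact
        assert fit.coefficient("colony+gliding") == pytest.approx(
            c.true_coefficients[0], abs=1e-8)

    def test_needs_more_birds_than_terms(self):
        ds, _ = make_dataset(n=6)
        with pytest.raises(ValueError):
            cal.fit_budget_model(ds)

    def test_coverage_of_two_se_intervals(self):
        """Recovered MRs fall within 2 s.e. of truth at ~95% rate."""
        hits = total = 0
        for seed in range(60):
            ds, c = make_dataset(seed=seed)
            fit = cal.fit_budget_model(ds)
            for j in range(5):
                total += 1
                hits += abs(fit.coefficients[j] - c.true_coefficients[j]) \
                    <= 2 * fit.std_errors[j]
        assert hits / total >= 0.90

    def test_rmse_decreases_with_sample_size(self):
        rmses = []
        for n in (25, 50, 100, 200):
            errs = []
            for seed in range(15):
                ds, c = make_dataset(seed=seed, n=n)
                fit = cal.fit_budget_model(ds)
                errs.append(np.mean((fit.coefficients - c.true_coefficients) ** 2))
            rmses.append(np.sqrt(np.mean(errs)))
        assert np.all(np.diff(rmses) < 0)


class TestDbaModel:
    def test_high_r2_when_dee_is_linear_in_vedba(self, rng):
        _, c = make_dataset(seed=1, with_vedba=True)
        tw = c.activity_vedba * c.budgets
        dee = 150.0 + 900.0 * tw.sum(axis=1) * (1 + rng.normal(0, 0.01, 50))
        ds = cal.CalibrationDataset(dee_std=dee, budgets=c.budgets,
                                    activity_vedba=tw)
        assert cal.fit_dba_model(ds).r_squared >= 0.99

    def test_teb_generated_data_prefers_teb_model(self):
        ds, _ = make_dataset(seed=2, with_vedba=True)
        assert cal.fit_budget_model(ds).aicc < cal.fit_dba_model(ds).aicc

    def test_bird_order_permutation_invariance(self, rng):
        ds, c = make_dataset(seed=3, with_vedba=True)
        perm = rng.permutation(ds.n)
        ds2 = cal.CalibrationDataset(dee_std=ds.dee_std[perm],
                                     budgets=ds.budgets[perm],
                                     activity_vedba=ds.activity_vedba[perm])
        f1, f2 = cal.fit_dba_model(ds), cal.fit_dba_model(ds2)
        assert np.allclose(f1.coefficients, f2.coefficients)
        assert f1.aicc == pytest.approx(f2.aicc)

    def test_mostly_missing_behaviour_dropped(self):
        ds, c = make_dataset(seed=4, with_vedba=True)
        tw = ds.activity_vedba.copy()
        tw[:40, 4] = np.nan
        ds2 = cal.CalibrationDataset(dee_std=ds.dee_std, budgets=ds.budgets,
                                     activity_vedba=tw)
        fit = cal.fit_dba_model(ds2)
        assert "vedba_gliding" not in fit.terms


class TestPoolingSearch:
    def test_no_merge_when_costs_well_separated(self):
        ds, _ = make_dataset(seed=3, noise=0.005, true_mr=WELL_SEPARATED_MR)
        res = cal.pooling_search(ds)
        assert len(res.selected.grouping) == 5

    def test_colony_gliding_truth_is_pooled(self):
        ds, _ = make_dataset(seed=0)
        res = cal.pooling_search(ds)
        assert any({"colony", "gliding"} <= set(g)
                   for g in res.selected.grouping)

    def test_selected_aicc_close_to_greedy_optimum(self):
        for seed in (0, 1):
            ds, _ = make_dataset(seed=seed)
            res = cal.pooling_search(ds)
            full = cal.fit_budget_model(ds)
            assert res.selected.aicc <= full.aicc + 2.0

    def test_search_invariant_to_behaviour_relabelling(self):
        """Permuting the budget columns (with matching truth) selects the
        equivalent partition."""
        ds, _ = make_dataset(seed=6)
        res1 = cal.pooling_search(ds)
        sel1 = {frozenset(g) for g in res1.selected.grouping}
        perm = [4, 2, 0, 1, 3]  # new column order over BEHAVIOURS
        names = [BEHAVIOURS[i] for i in perm]
        ds2 = cal.CalibrationDataset(dee_std=ds.dee_std,
                                     budgets=ds.budgets[:, perm])
        # rename: column j of ds2 carries behaviour names[j]; map the
        # selected partition back through the inverse permutation
        res2 = cal.pooling_search(ds2)
        remap = {BEHAVIOURS[j]: names[j] for j in range(5)}
        sel2 = {frozenset(remap[b] for b in g) for g in res2.selected.grouping}
        assert sel1 == sel2

    def test_greedy_never_beats_exhaustive(self):
        for seed in (0, 5, 9):
            ds, _ = make_dataset(seed=seed)
            greedy = cal.pooling_search(ds)
            exhaustive = cal.exhaustive_pooling_search(ds)
            assert greedy.ranked[0].aicc >= exhaustive.ranked[0].aicc - 1e-9

    def test_partition_count_is_bell_5(self):
        assert sum(1 for _ in cal.all_partitions()) == 52

    def test_stage_not_selected_when_truth_has_no_stage_effect(self):
        ds, _ = make_dataset(seed=7)
        res = cal.pooling_search(ds, stage_candidate=True)
        assert not any(t.startswith("stage[") for t in res.selected.terms)


class TestCoefficientReport:
    def test_bmr_multiple_anchor(self):
        fit = cal.ModelFit(terms=("flapping",), coefficients=np.array([301.536]),
                           std_errors=np.array([1.0]), log_likelihood=0.0,
                           aicc=0.0, vifs=np.array([1.0]), r_squared=1.0,
                           n=10, k=2)
        rep = cal.coefficients_report(fit)
        # 3.49 W = 301.536 kJ/day, so this coefficient is exactly 1 x BMR
        assert rep["mr_x_bmr"][0] == pytest.approx(1.0)
        assert rep["mr_kj_g_day"][0] == pytest.approx(301.536 / 450.0)

    def test_zero_coefficient_zero_everywhere(self):
        fit = cal.ModelFit(terms=("gliding",), coefficients=np.array([0.0]),
                           std_errors=np.array([1.0]), log_likelihood=0.0,
                           aicc=0.0, vifs=np.array([1.0]), r_squared=1.0,
                           n=10, k=2)
        rep = cal.coefficients_report(fit)
        assert rep[["mr_kj_day", "mr_kj_g_day", "mr_x_bmr"]].to_numpy().sum() == 0

    def test_bmr_ratio_equals_raw_ratio(self):
        ds, _ = make_dataset(seed=0, noise=0.0)
        fit = cal.fit_budget_model(ds)
        rep = cal.coefficients_report(fit)
        raw = rep["mr_kj_day"].to_numpy()
        bmr = rep["mr_x_bmr"].to_numpy()
        assert raw[3] / raw[4] == pytest.approx(bmr[3] / bmr[4])
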