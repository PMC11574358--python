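"""Unit and property tests for the two-sample DLW computation chain."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from kittiwake_energetics import dlw
from kittiwake_energetics.synthetic import simulate_isotopes


class TestTurnover:
    def test_exponential_decay_rate(self):
        # excess 1000 ppm decaying to 1000/e over 10 h has k = 0.1 / h
        k = dlw.turnover_rate(0.0, 1000.0, 1000.0 / math.e, 10.0)
        assert k == pytest.approx(0.1, rel=1e-9)

    def test_no_decay_gives_zero(self):
        assert dlw.turnover_rate(0.0, 1000.0, 1000.0, 10.0) == 0.0

    def test_halving_time_doubles_rate(self):
        k1 = dlw.turnover_rate(50.0, 900.0, 300.0, 10.0)
        k2 = dlw.turnover_rate(50.0, 900.0, 300.0, 5.0)
        assert k2 == pytest.approx(2 * k1)

    def test_exhausted_enrichment_signals_exclusion(self):
        with pytest.raises(dlw.DlwExclusion):
            dlw.turnover_rate(100.0, 900.0, 99.0, 10.0)

    def test_rising_enrichment_is_an_error(self):
        with pytest.raises(ValueError):
            dlw.turnover_rate(0.0, 500.0, 600.0, 10.0)


class TestDilutionSpace:
    def test_direct_substitution(self):
        assert dlw.dilution_space(1.0, 100_000.0, 1_000.0, 0.0) == pytest.approx(99.0)

    def test_midpoint_enrichment_gives_dose(self):
        # initial exactly halfway between injectate and background
        assert dlw.dilution_space(0.03, 10_000.0, 5_050.0, 100.0) == pytest.approx(0.03)

    def test_linear_in_dose(self):
        n1 = dlw.dilution_space(1.0, 50_000.0, 800.0, 150.0)
        n2 = dlw.dilution_space(2.0, 50_000.0, 800.0, 150.0)
        assert n2 == pytest.approx(2 * n1)

    def test_no_enrichment_is_an_error(self):
        with pytest.raises(ValueError):
            dlw.dilution_space(1.0, 50_000.0, 100.0, 150.0)


class TestPoolAndCo2:
    def test_pool_size_mass_scaling(self):
        assert dlw.pool_size(18.0, 450.0, 400.0) == pytest.approx(17.0)

    def test_pool_size_no_mass_change(self):
        assert dlw.pool_size(18.0, 450.0, 450.0) == pytest.approx(18.0)

    def test_pool_between_initial_and_final(self):
        n = dlw.pool_size(18.0, 450.0, 500.0)
        assert 18.0 <= n <= 20.0

    def test_co2_hand_computed(self):
        # rCO2 = (N/2.078)(k_o - k_d) - 0.0062 k_d N, both terms by hand
        expected = 17.5 / 2.078 * 0.002 - 0.0062 * 0.008 * 17.5
        assert dlw.co2_production(17.5, 0.010, 0.008) == pytest.approx(expected, rel=1e-12)

    def test_zero_turnover_zero_co2(self):
        assert dlw.co2_production(17.5, 0.0, 0.0) == 0.0

    def test_linear_in_pool(self):
        r1 = dlw.co2_production(10.0, 0.02, 0.01)
        r2 = dlw.co2_production(20.0, 0.02, 0.01)
        assert r2 == pytest.approx(2 * r1)

    def test_dee_from_1000ml_per_h(self):
        # 1000 ml/h x 27.63 J/ml x 24 h / 1000 = 663.12 kJ/day
        assert dlw.dee_from_co2(1000.0 / 22_400.0) == pytest.approx(663.12)

    def test_dee_monotone_in_k_o(self):
        dees = [dlw.dee_from_co2(dlw.co2_production(17.5, ko, 0.008))
                for ko in np.linspace(0.009, 0.03, 10)]
        assert np.all(np.diff(dees) > 0)


class TestStandardise:
    def test_reference_mass_identity(self):
        assert dlw.standardize_dee(612.0, 450.0, 450.0) == pytest.approx(612.0)

    def test_mean_mass_scaling(self):
        assert dlw.standardize_dee(600.0, 520.0, 480.0) == pytest.approx(540.0)

    def test_exponent_zero_is_identity(self):
        assert dlw.standardize_dee(600.0, 520.0, 480.0, exponent=0.0) == 600.0


class TestProcessBird:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        dee=st.floats(300.0, 1500.0),
        mass=st.floats(350.0, 550.0),
        loss=st.floats(-20.0, 40.0),
        t_final=st.floats(30.0, 120.0),
        k_d=st.floats(0.005, 0.03),
    )
    def test_roundtrip_recovers_true_dee(self, dee, mass, loss, t_final, k_d):
        """Zero-noise isotopes invert the full chain to 1e-6 relative."""
        samples = simulate_isotopes(dee, mass, mass - loss, t_final_h=t_final,
                                    k_d_per_h=k_d)
        result = dlw.process_dlw_bird(samples)
        # long, energetic deployments can wash the 18O excess below the 2%
        # exclusion threshold; the round trip applies to included birds
        assume(not result.excluded)
        assert result.dee_kj_day == pytest.approx(dee, rel=1e-6)

    def test_roundtrip_unbiased_under_multiplicative_noise(self):
        errors = []
        for seed in range(1000):
            s = simulate_isotopes(700.0, 460.0, 450.0, t_final_h=59.0,
                                  noise=0.002, seed=seed)
            r = dlw.process_dlw_bird(s)
            if not r.excluded:
                errors.append(r.dee_kj_day / 700.0 - 1.0)
        assert abs(np.mean(errors)) < 0.01

    def test_exclusion_rule_is_step_at_2_percent(self):
        def bird(final_excess_frac):
            s = simulate_isotopes(700.0, 460.0, 450.0, t_final_h=59.0)
            bg = s.o18.background
            o18 = dlw.IsotopeSamples(bg, s.o18.initial, bg + final_excess_frac * bg)
            return dlw.IsotopeSampleSet(**{**s.__dict__, "o18": o18})

        assert dlw.process_dlw_bird(bird(0.019)).excluded
        assert not dlw.process_dlw_bird(bird(0.021)).excluded

    def test_flagged_bird_excluded_with_reason(self):
        s = simulate_isotopes(700.0, 460.0, 450.0, t_final_h=59.0)
        s = dlw.IsotopeSampleSet(**{**s.__dict__, "include": False,
                                    "exclude_reason": "misidentified female"})
        r = dlw.process_dlw_bird(s)
        assert r.excluded and r.reason == "misidentified female"


def _cohort_frame(n_total=54, n_exhausted=1, n_missing_final=1, n_females=2):
    rows = []
    for i in range(n_total):
        bird = f"b{i:02d}"
        s = simulate_isotopes(650.0 + 5 * i, 460.0, 450.0, t_final_h=59.0,
                              bird_id=bird)
        if i < n_exhausted:  # final 18O collapsed to within 2% of background
            bg = s.o18.background
            s = dlw.IsotopeSampleSet(**{**s.__dict__, "o18": dlw.IsotopeSamples(
                bg, s.o18.initial, bg + 0.01 * bg)})
        include = not (n_exhausted <= i < n_exhausted + n_females)
        for stype, t_h, d2, o18 in (
                ("background", 0.0, s.d2.background, s.o18.background),
                ("initial", s.t_initial_h, s.d2.initial, s.o18.initial),
                ("final", s.t_final_h, s.d2.final, s.o18.final)):
            if stype == "final" and n_exhausted + n_females <= i < n_exhausted + n_females + n_missing_final:
                continue
            rows.append({"bird_id": bird, "sample_type": stype, "time_h": t_h,
                         "d2_ppm": d2, "o18_ppm": o18, "dose_mol": s.dose_mol,
                         "inj_d2_ppm": s.inj_d2_ppm, "inj_o18_ppm": s.inj_o18_ppm,
                         "mass_deploy_g": s.mass_deploy_g,
                         "mass_retrieve_g": s.mass_retrieve_g,
                         "include": include,
                         "exclude_reason": None if include else "misidentified female"})
    return pd.DataFrame(rows)


class TestCohort:
    def test_exclusion_cascade_counts(self):
        assert dlw.exclusion_cascade(dlw.DEPLOYMENT_CASCADE) == 80
        assert dlw.exclusion_cascade(dlw.DLW_CASCADE) == 50

    def test_cohort_of_54_keeps_50(self):
        """One exhausted bird, one missing final sample and two flagged
        females leave 50 of 54 recaptured birds included."""
        results = dlw.process_isotope_table(_cohort_frame())
        assert len(results) == 54
        assert int((~results["excluded"]).sum()) == 50
        reasons = results.loc[results["excluded"], "reason"].tolist()
        assert any("background" in r for r in reasons)
        assert any("missing" in r for r in reasons)
        assert sum("female" in r for r in reasons) == 2

    def test_missing_sample_row_raises_in_strict_reader(self):
        frame = _cohort_frame(n_total=3, n_exhausted=0, n_missing_final=1,
                              n_females=0)
        with pytest.raises(ValueError, match="final"):
            dlw.samples_from_frame(frame)
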