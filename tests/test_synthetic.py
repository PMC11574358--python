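"""Tests for the synthetic deployment and isotope generators."""

import math

import numpy as np
import pytest

from kittiwake_energetics import signals, synthetic
from kittiwake_energetics.states import BEHAVIOURS, BEHAVIOUR_INDEX


class TestStateSequence:
    def test_transition_matrix_is_stochastic_with_exact_stationary(self):
        cfg = synthetic.SimulationConfig()
        pi = cfg.budget_vector
        dwell = np.array([cfg.state_dwell_hours[b] * 360 for b in BEHAVIOURS])
        P = synthetic.transition_matrix(pi, dwell)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(pi @ P, pi, atol=1e-10)

    def test_invalid_transition_matrix_rejected(self):
        P = np.full((5, 5), 0.3)
        with pytest.raises(ValueError):
            synthetic.sample_markov_chain(P, np.full(5, 0.2), 10,
                                          np.random.default_rng(0))

    def test_degenerate_budget_yields_all_colony(self):
        targets = {b: 0.0 for b in BEHAVIOURS}
        targets["colony"] = 1.0
        cfg = synthetic.SimulationConfig(budget_targets=targets,
                                         deployment_hours=1.0)
        states = synthetic.simulate_state_sequence(cfg, seed=0)
        assert np.all(states == BEHAVIOUR_INDEX["colony"])

    def test_incubation_flapping_share_at_1e6_bins(self):
        """Empirical flapping share converges to the 22% incubation target."""
        cfg = synthetic.SimulationConfig(deployment_hours=1e6 / 360.0)
        states = synthetic.simulate_state_sequence(cfg, seed=3)
        freqs = np.bincount(states, minlength=5) / len(states)
        assert freqs[BEHAVIOUR_INDEX["flapping"]] == pytest.approx(0.22, abs=0.01)
        assert np.abs(freqs - cfg.budget_vector).max() < 0.01

    def test_two_state_symmetric_chain_law_of_large_numbers(self):
        P = np.array([[0.9, 0.1], [0.1, 0.9]])
        states = synthetic.sample_markov_chain(P, np.array([0.5, 0.5]), 100_000,
                                               np.random.default_rng(7))
        assert np.mean(states == 0) == pytest.approx(0.5, abs=0.01)

    def test_dwell_times_roughly_geometric_with_configured_mean(self):
        cfg = synthetic.SimulationConfig(deployment_hours=2000.0)
        states = synthetic.simulate_state_sequence(cfg, seed=9)
        flap = BEHAVIOUR_INDEX["flapping"]
        runs = []
        count = 0
        for s in states:
            if s == flap:
                count += 1
            elif count:
                runs.append(count)
                count = 0
        expected = cfg.state_dwell_hours["flapping"] * 360
        assert np.mean(runs) == pytest.approx(expected, rel=0.15)


class TestSignals:
    def test_empty_state_sequence_rejected(self):
        cfg = synthetic.SimulationConfig()
        with pytest.raises(ValueError):
            synthetic.simulate_signals(np.array([], dtype=int), cfg)

    def test_all_colony_gps_within_radius(self):
        cfg = synthetic.SimulationConfig(deployment_hours=0.5)
        states = np.full(180, BEHAVIOUR_INDEX["colony"])
        dep = synthetic.simulate_signals(states, cfg, seed=2)
        d = signals.haversine_m(dep.gps["lat"].to_numpy(), dep.gps["lon"].to_numpy(),
                                *cfg.colony_latlon)
        assert np.all(d <= cfg.colony_radius_m)

    def test_flapping_bins_carry_wingbeat_tone(self, short_deployment):
        cfg, states, dep = short_deployment
        az = dep.accel["az"].to_numpy()
        flap_bins = np.flatnonzero(states == BEHAVIOUR_INDEX["flapping"])[:20]
        for b in flap_bins:
            seg = az[b * 250:(b + 1) * 250]
            f = signals.estimate_wbf(seg)
            assert f == pytest.approx(cfg.wbf_flap_hz, abs=0.2 + 3 * cfg.wbf_flap_sd_hz)

    def test_gliding_vedba_below_flapping_first_percentile(self, short_deployment):
        cfg, states, dep = short_deployment
        trace = signals.AccelTrace(t=dep.accel["t"].to_numpy(),
                                   ax=dep.accel["ax"].to_numpy(),
                                   ay=dep.accel["ay"].to_numpy(),
                                   az=dep.accel["az"].to_numpy())
        v = signals.compute_vedba(trace)
        per_bin = v[:len(states) * 250].reshape(len(states), 250).mean(axis=1)
        flap = per_bin[states == BEHAVIOUR_INDEX["flapping"]]
        glide = per_bin[states == BEHAVIOUR_INDEX["gliding"]]
        assert glide.size and flap.size
        assert np.all(glide < np.percentile(flap, 1))

    def test_accel_length_matches_duration(self, short_deployment):
        cfg, states, dep = short_deployment
        assert len(dep.accel) == len(states) * 250
        assert dep.true_budget == pytest.approx(
            np.bincount(states, minlength=5) / len(states))

    def test_gps_fix_spacing(self, short_deployment):
        cfg, _, dep = short_deployment
        dt = np.diff(dep.gps["t"].to_numpy())
        assert np.all(np.abs(dt - cfg.gps_interval_s) <= 1.0)


class TestIsotopeGenerator:
    def test_log_excess_falls_linearly_with_slope_minus_k(self):
        k = 0.015
        excesses = []
        for t_final in (20.0, 40.0):
            s = synthetic.simulate_isotopes(700.0, 460.0, 450.0,
                                            t_final_h=t_final, k_d_per_h=k)
            excesses.append(math.log(s.d2.final - s.d2.background))
        slope = (excesses[1] - excesses[0]) / 20.0
        assert slope == pytest.approx(-k, rel=1e-9)

    def test_equal_fluxes_when_co2_vanishes(self):
        # with no water flux and DEE -> 0 both washouts vanish identically
        # (k_o = k_d = 0); the fractionation term otherwise keeps k_o > k_d
        s = synthetic.simulate_isotopes(1e-9, 450.0, 450.0, t_final_h=59.0,
                                        k_d_per_h=0.0)
        ratio_o = (s.o18.final - s.o18.background) / (s.o18.initial - s.o18.background)
        ratio_d = (s.d2.final - s.d2.background) / (s.d2.initial - s.d2.background)
        assert ratio_o == pytest.approx(ratio_d, rel=1e-6)
        assert ratio_o == pytest.approx(1.0, rel=1e-6)

    def test_rejects_nonpositive_dee(self):
        with pytest.raises(ValueError):
            synthetic.simulate_isotopes(-5.0, 450.0, 450.0, t_final_h=59.0)


class TestCohortGeneration:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = synthetic.SimulationConfig(n_birds=2, deployment_hours=0.25, seed=4)
        synthetic.generate_cohort(cfg, tmp_path / "a")
        synthetic.generate_cohort(cfg, tmp_path / "b")
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_refuses_nonempty_directory(self, tmp_path):
        cfg = synthetic.SimulationConfig(n_birds=1, deployment_hours=0.25, seed=4)
        out = tmp_path / "c"
        synthetic.generate_cohort(cfg, out)
        with pytest.raises(FileExistsError):
            synthetic.generate_cohort(cfg, out)
        synthetic.generate_cohort(cfg, out, force=True)

    def test_truth_row_count_matches_cohort(self, small_cohort_dir):
        import pandas as pd
        out, cfg = small_cohort_dir
        truth = pd.read_csv(out / "truth.csv")
        assert len(truth) == cfg.n_birds
        iso = pd.read_csv(out / "isotopes.csv")
        assert iso["bird_id"].nunique() == cfg.n_birds

    def test_empty_cohort_is_valid(self, tmp_path):
        import pandas as pd
        cfg = synthetic.SimulationConfig(n_birds=0, deployment_hours=0.25, seed=4)
        synthetic.generate_cohort(cfg, tmp_path / "empty")
        truth = pd.read_csv(tmp_path / "empty" / "truth.csv")
        assert len(truth) == 0


class TestConfigValidation:
    def test_budgets_must_close(self):
        bad = dict(synthetic.STAGE_BUDGETS["incubation"])
        bad["colony"] += 0.05
        with pytest.raises(ValueError):
            synthetic.SimulationConfig(budget_targets=bad)

    def test_flapping_must_cost_more_than_gliding(self):
        mr = dict(synthetic.DEFAULT_TRUE_MR)
        mr["gliding"] = mr["flapping"] + 1.0
        with pytest.raises(ValueError):
            synthetic.SimulationConfig(true_mr=mr)

    def test_calibration_cohort_budget_closure_and_stages(self):
        c = synthetic.simulate_calibration_cohort(n_birds=50, seed=0,
                                                  stage_counts=(17, 33))
        assert np.allclose(c.budgets.sum(axis=1), 1.0, atol=1e-12)
        assert (c.stages == "pre-laying").sum() == 17
        assert (c.stages == "incubation").sum() == 33
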