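import numpy as np
import pytest

from kittiwake_energetics import synthetic


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory):
    """A tiny on-disk cohort (10 birds, 1 h deployments, noiseless isotopes)."""
    out = tmp_path_factory.mktemp("cohort") / "cohort"
    cfg = synthetic.SimulationConfig(n_birds=10, deployment_hours=1.0, seed=11)
    synthetic.generate_cohort(cfg, out)
    return out, cfg


@pytest.fixture(scope="session")
def short_deployment():
    """One simulated bird at 2 h: states, waveforms and GPS."""
    cfg = synthetic.SimulationConfig(deployment_hours=2.0, seed=5)
    states = synthetic.simulate_state_sequence(cfg, seed=5)
    dep = synthetic.simulate_signals(states, cfg, seed=6)
    return cfg, states, dep


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
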