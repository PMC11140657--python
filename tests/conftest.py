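import numpy as np
import pytest

from sleeptmr import synthgen


@pytest.fixture(scope="session")
def benchmark_session():
    """Standard synthetic detector benchmark: 20 min single-channel record
    with fixed-count spindles and SOs at 10x background gain, fixed seed."""
    cfg = synthgen.SimConfig(
        duration_s=1200.0, channel_labels=("Cz", "M1", "M2"), seed=42
    )
    bg = synthgen.gen_background(cfg)
    rec, gt_sp = synthgen.inject_oscillatory_events(
        bg, "spindle", cfg.spindle, seed=43, channels=["Cz"]
    )
    rec, gt_so = synthgen.inject_oscillatory_events(
        rec, "so", cfg.so, seed=44, channels=["Cz"]
    )
    return cfg, rec, gt_sp, gt_so


@pytest.fixture(scope="session")
def coupled_session():
    """2400 s single-channel record with 200 coupled SO-spindle events,
    preferred phase -30 deg, kappa 5."""
    cfg = synthgen.SimConfig(
        duration_s=2400.0, channel_labels=("Cz", "M1", "M2"), seed=5,
        coupling=synthgen.CouplingSpec(fraction=1.0, mu_deg=-30.0, kappa=5.0),
    )
    bg = synthgen.gen_background(cfg)
    rec, gt = synthgen.inject_coupled_events(
        bg, cfg.coupling, cfg.so, cfg.spindle, seed=6, n_so=200,
        channels=["Cz"],
    )
    return cfg, rec, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
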