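import numpy as np
import pytest

import divekin


@pytest.fixture(scope="session")
def sim_deployment():
    """One deterministic synthetic deployment shared across tests."""
    cfg = divekin.SimConfig(seed=11, n_dives=10)
    return cfg, divekin.simulate_deployment(cfg)


@pytest.fixture(scope="session")
def sim_pipeline(sim_deployment):
    """Full pipeline result on the shared deployment."""
    _, (diary, truth, events) = sim_deployment
    return divekin.run_pipeline(diary, events)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_trapezoid_depth(fs=10.0, surface_s=60.0, ramp_s=30.0, bottom_s=60.0,
                         max_depth=20.0, surface_depth=0.2):
    """Simple trapezoidal dive between long surface stretches."""
    n_surf = int(surface_s * fs)
    n_ramp = int(ramp_s * fs)
    n_bot = int(bottom_s * fs)
    ramp = np.linspace(surface_depth, max_depth, n_ramp)
    depth = np.concatenate([
        np.full(n_surf, surface_depth), ramp, np.full(n_bot, max_depth),
        ramp[::-1], np.full(n_surf, surface_depth),
    ])
    return depth, np.arange(len(depth)) / fs
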