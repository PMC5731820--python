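import numpy as np
import pytest

import tetherkit as tk


@pytest.fixture(scope="session")
def config() -> tk.TetherConfig:
    """Default instrument geometry: 1 um bead, ~6 kbp tether, 120 Hz."""
    return tk.TetherConfig()


@pytest.fixture(scope="session")
def traj_1pn_60s(config) -> tk.Trajectory:
    """Shared 60 s bare-tether window at 1 pN (seed fixed)."""
    return tk.simulate_tether(config, tk.ForceSchedule(((60.0, 1.0),)), seed=101)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_trajectory(z, force=1.0, rate=120.0, x=None, turns=None):
    """Hand-built trajectory from a z series (helper for unit tests)."""
    z = np.asarray(z, dtype=float)
    n = z.size
    f = np.full(n, force) if np.ndim(force) == 0 else np.asarray(force, float)
    return tk.Trajectory(
        np.arange(n) / rate,
        np.zeros(n) if x is None else np.asarray(x, float),
        np.zeros(n),
        z,
        f,
        np.zeros(n) if turns is None else np.asarray(turns, float),
        None,
        rate,
    )
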