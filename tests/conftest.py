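import numpy as np
import pytest

import scleropipe as sp


@pytest.fixture(scope="session")
def small_population():
    """30 dated shells at the default (paper-like) signal/noise levels."""
    cfg = sp.SimulationConfig(n_shells=30, seed=3)
    coll, truth = sp.generate_population(cfg)
    return cfg, coll, truth


@pytest.fixture(scope="session")
def noise_free_population():
    """Constant signal, no noise: widths follow the ontogenetic curve only."""
    cfg = sp.SimulationConfig(n_shells=10, noise_sd=0.0, signal_sd=0.0, seed=2)
    coll, truth = sp.generate_population(cfg)
    return cfg, coll, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def ar1_series(rng, n, phi=0.5, burn=60):
    x = np.empty(n + burn)
    x[0] = rng.standard_normal() / np.sqrt(1 - phi**2)
    e = rng.standard_normal(n + burn)
    for i in range(1, n + burn):
        x[i] = phi * x[i - 1] + e[i]
    return x[burn:]
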