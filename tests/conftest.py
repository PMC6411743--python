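import numpy as np
import pytest

import thermsol as ts


@pytest.fixture(scope="session")
def small_2d_sim():
    """Compact mixed 2D dataset with spiked effects, reused across tests."""
    cfg = ts.SimConfig.tpp2d(
        n_proteins=60,
        noise_cv=0.05,
        seed=42,
        fractions={"null": 0.7, "stabilized": 0.2, "destabilized": 0.1},
    )
    return cfg, ts.simulate_2dtpp(cfg)


@pytest.fixture(scope="session")
def small_spp_sim():
    cfg = ts.SimConfig.spp(
        n_proteins=80,
        noise_cv=0.05,
        seed=17,
        fractions={"null": 0.75, "solubilized": 0.2, "desolubilized": 0.05},
    )
    return cfg, ts.simulate_spp(cfg)


@pytest.fixture(scope="session")
def tr_sim_with_complexes():
    cfg = ts.SimConfig.tpp_tr(
        n_proteins=60,
        noise_cv=0.0,
        seed=7,
        n_complexes=2,
        complex_size=5,
        complex_jitter=0.0,
    )
    return cfg, ts.simulate_tpp_tr(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
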