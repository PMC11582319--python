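import numpy as np
import pytest

from oncvae import ModelConfig, Orion, SimConfig, TrainOpts, simulate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small cohort with replicates, two suppliers and planted signal."""
    cfg = SimConfig(
        n_samples=120, d_onc=80, m_endo=10, n_patients=100,
        signal_features=8, effect_logfc=1.5, seed=7,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def signal_cohort():
    """Mid-sized cohort used for training-dependent checks."""
    cfg = SimConfig(
        n_samples=240, d_onc=300, m_endo=15, n_patients=240,
        signal_features=30, effect_logfc=1.5, seed=21,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_model_config():
    return ModelConfig(
        d=300, m=15, k=8, hidden_onc=64, hidden_lib=32, hidden_dec=64,
        eta=20, seed=0,
    )


@pytest.fixture(scope="session")
def trained_model(signal_cohort, small_model_config):
    """One model trained on the mid-sized cohort; reused across tests."""
    model = Orion(small_model_config)
    history = model.fit(
        signal_cohort.x, signal_cohort.r, signal_cohort.annotations,
        TrainOpts(n_epochs=30, batch_size=64),
    )
    return model, history
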