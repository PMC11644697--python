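import numpy as np
import pytest

import bodsense as bs


@pytest.fixture(scope="session")
def small_scenario():
    """6-day dry→rain scenario split into a 3-day train / 3-day test pair."""
    cfg = bs.ScenarioConfig(seed=5, n_days=6, regime_schedule=[("dry", 3), ("rain", 3)])
    ds = bs.generate(cfg)
    return cfg, ds.slice_rows(0, 288), ds.slice_rows(288, ds.n_samples)


@pytest.fixture(scope="session")
def small_profile(small_scenario):
    _, train_ds, _ = small_scenario
    return bs.compute_mi_profile(train_ds, k=3, threshold_lambda=0.3)


@pytest.fixture(scope="session")
def fast_model_cfg():
    """A deliberately tiny training budget for pipeline plumbing tests."""
    return bs.BiLSTMConfig(lookback=4, hidden_size=4, epochs=8,
                           learning_rate=3e-3, batch_size=32, seed=0)


@pytest.fixture()
def toy_pairs():
    """16 noise-free windows whose target is a linear function of the inputs."""
    rng = np.random.default_rng(42)
    X = rng.normal(size=(16, 3, 1))
    y = 0.5 * X[:, -1, 0] + 0.3 * X[:, 0, 0]
    return X, y
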