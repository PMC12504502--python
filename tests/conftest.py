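import numpy as np
import pytest

from mfel import FixtureSpec, TrainConfig, generate_fixtures


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_samples():
    """Four 32x32 synthetic lesion samples shared across tests."""
    return generate_fixtures(FixtureSpec(n_samples=4, size=32, seed=11))


@pytest.fixture(scope="session")
def overfit_samples():
    """The eight 64x64 samples used by convergence/ablation runs."""
    return generate_fixtures(FixtureSpec(n_samples=8, size=64, seed=7))


def tiny_config(**kw) -> TrainConfig:
    """A desk-scale config: 32x32, narrow channels, short schedule."""
    defaults = dict(
        epochs=3,
        warmup_epochs=1,
        batch_size=2,
        working_size=32,
        stage_channels=(4, 8, 16),
        state_dim=4,
        seed=5,
    )
    defaults.update(kw)
    return TrainConfig(**defaults)


@pytest.fixture
def tiny_cfg():
    return tiny_config()
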