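import numpy as np
import pytest

from nstwindow.config import AnalysisConfig, SimConfig


def make_config(**overrides) -> SimConfig:
    """A small one-year trial config; overridable per test."""
    base = dict(
        rng_seed=123,
        years=("2015",),
        sampling_dpp={"2015": [5, 7, 9, 12, 14, 16, 19, 47, 61]},
        n_blocks=4,
        plants_per_plot_per_date=5,
    )
    base.update(overrides)
    return SimConfig(**base)


def noiseless_config(**overrides) -> SimConfig:
    """Deterministic config: no noise, no block effects, no background."""
    base = dict(noise_cv=0.0, block_sd=0.0, background_conc=0.0,
                incomplete_prob=0.0)
    base.update(overrides)
    return make_config(**base)


@pytest.fixture
def sim_config():
    return make_config()


@pytest.fixture
def analysis_config():
    return AnalysisConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(42)
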