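import numpy as np
import pytest

from melanosim import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def small_config(**overrides) -> SimulationConfig:
    """A fast small-lattice configuration for behavioral tests."""
    defaults = dict(dims=(12, 12, 12), t_end_h=40.0, seed=1,
                    initial_tumor_count=20, initial_tip_count=6)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture
def small_cfg() -> SimulationConfig:
    return small_config()
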