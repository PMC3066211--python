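import numpy as np
import pytest
from hypothesis import settings

from kinscreen import (
    ScreenConfig,
    SimulationConfig,
    score_screen,
    simulate_screen,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


SMALL_SIM = dict(
    n_genes=60,
    n_plates=2,
    fraction_erod_hits=0.05,       # 3 planted pathway genes
    fraction_viability_genes=0.05,  # 3 planted viability genes
)


def small_config(seed: int = 11, **overrides) -> SimulationConfig:
    params = {**SMALL_SIM, **overrides}
    return SimulationConfig(seed=seed, **params)


@pytest.fixture(scope="session")
def small_screen():
    """A compact 2-plate, 60-gene screen with planted effects."""
    return simulate_screen(small_config())


@pytest.fixture(scope="session")
def small_scored(small_screen):
    screen, layout, library, truth = small_screen
    cfg = ScreenConfig(top_k=20)
    return score_screen(screen, layout, library, cfg), truth, cfg


@pytest.fixture(scope="session")
def default_screen():
    """One full-geometry screen (712 genes x 3 siRNA, 3 x 30 plates)."""
    return simulate_screen(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_scored(default_screen):
    screen, layout, library, truth = default_screen
    return score_screen(screen, layout, library), truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
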