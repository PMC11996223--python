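import numpy as np
import pytest

from sgtcca.simulate import SimulationDesign


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_design(case: int = 2, setting: str = "normal", n_samples: int = 80,
                 seed: int = 0, **kw) -> SimulationDesign:
    """A 10x-scaled-down variant of the standard simulation design (100
    features per view, same block layout) for fast pipeline tests."""
    blocks = [(0, 2), (2, 4), (4, 6), (6, 8), (8, 10),
              (10, 16), (16, 22), (22, 28), (28, 34), (34, 100)]
    return SimulationDesign(case=case, setting=setting, n_samples=n_samples,
                            n_features=100, blocks=blocks, seed=seed, **kw)
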