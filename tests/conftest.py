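import numpy as np
import pytest

from levyswarm import Environment, Target


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_env():
    """L=10 lattice with three targets of known weights (0.3, 0.6, 0.9)."""
    return Environment(
        L=10,
        density=0.03,
        gamma_max=0.95,
        seed=0,
        targets=(
            Target(x=2, y=3, gamma=0.3),
            Target(x=7, y=1, gamma=0.6),
            Target(x=5, y=8, gamma=0.9),
        ),
    )
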