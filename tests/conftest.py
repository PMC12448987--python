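import numpy as np
import pytest

from hasites.attention_store import AttentionTensor
from hasites.synthetic import SyntheticSpec, make_attention_tensor


def random_row_stochastic(rng: np.random.Generator, L: int, H: int, n: int) -> np.ndarray:
    v = rng.random((L, H, n, n)) + 1e-3
    return v / v.sum(axis=3, keepdims=True)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_tensor(rng) -> AttentionTensor:
    """A (3, 2, 5, 5) row-stochastic tensor with no particular structure."""
    return AttentionTensor("toy", random_row_stochastic(rng, 3, 2, 5))


@pytest.fixture
def planted_tensor() -> AttentionTensor:
    """Default synthetic tensor: sites (30, 60, 90), convergence layer 10."""
    return make_attention_tensor(SyntheticSpec(seed=7))


@pytest.fixture
def planted_spec() -> SyntheticSpec:
    return SyntheticSpec(seed=7)
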