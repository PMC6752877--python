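import numpy as np
import pytest

from midnet import SimSpec, ThresholdedNetwork


@pytest.fixture
def small_spec() -> SimSpec:
    """A 20-neuron, 2-module culture small enough for fast end-to-end runs."""
    return SimSpec(
        n_neurons=20,
        n_modules=2,
        within_module_share=0.6,
        base_rate=1.0,
        duration_s=30.0,
        noise_sd=0.5,
        seed=7,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def net_from(weights: np.ndarray, **kwargs) -> ThresholdedNetwork:
    """Wrap a symmetric weight matrix as a ThresholdedNetwork for metric tests."""
    return ThresholdedNetwork(weights=np.asarray(weights, float), threshold={"mode": "direct"}, **kwargs)
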