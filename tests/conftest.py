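import numpy as np
import pytest

from tempostp.neuron import KernelParams, NeuronConfig
from tempostp.patterns import SpikePattern, gen_latency_batch


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def kernel():
    return KernelParams.from_tau(0.02)


@pytest.fixture
def neuron_cfg(kernel):
    return NeuronConfig(kernel)


@pytest.fixture
def small_pattern(rng):
    """6 afferents x 4 spikes latency pattern."""
    return SpikePattern(0.5, [np.sort(rng.uniform(0, 0.5, 4)) for _ in range(6)], 4)


@pytest.fixture
def small_batch():
    return gen_latency_batch(10, 2, 0.5, 1.0, seed=11)
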