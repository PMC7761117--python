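import numpy as np
import pytest

from spikeburst import (
    SpikingBurstingModel,
    independent_spike_table,
    validate_dichotomous,
)


@pytest.fixture
def model_n2():
    """2-node model: P=0.4 per node, ps=0.6, eps=0.2."""
    return SpikingBurstingModel(
        spikes=independent_spike_table([0.4, 0.4]),
        dichotomous=validate_dichotomous(0.6, 0.2),
    )


@pytest.fixture
def model_n3():
    """3-node model: equal P=0.3, ps=0.7, eps=0.1."""
    return SpikingBurstingModel(
        spikes=independent_spike_table([0.3, 0.3, 0.3]),
        dichotomous=validate_dichotomous(0.7, 0.1),
    )


@pytest.fixture
def model_n4_unequal():
    """4-node model with unequal per-node rates."""
    return SpikingBurstingModel(
        spikes=independent_spike_table([0.2, 0.35, 0.5, 0.65]),
        dichotomous=validate_dichotomous(0.6, 0.15),
    )


@pytest.fixture
def model_n6():
    """6-node equal-rate model with s1=0.1, ps=0.6, eps=0.1."""
    p = 0.1 ** (1.0 / 6.0)
    return SpikingBurstingModel(
        spikes=independent_spike_table([p] * 6),
        dichotomous=validate_dichotomous(0.6, 0.1),
    )


def brute_force_marginal(probs: np.ndarray, n: int, mask: int) -> np.ndarray:
    """Oracle subsystem marginal by explicit summation over all words."""
    keep = [i for i in range(n) if (mask >> i) & 1]
    out = np.zeros(2 ** len(keep))
    for w in range(2 ** n):
        sub = 0
        for k, i in enumerate(keep):
            sub |= ((w >> i) & 1) << k
        out[sub] += probs[w]
    return out
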