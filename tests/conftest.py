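import numpy as np
import pytest
from hypothesis import settings

from tvinfo.data import BinnedRates, CategoryMap, SpikeTrainSet, StimulusRecord

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_spikes():
    """Two stimuli, three trials each, hand-placed spikes in a 100 ms window."""
    return SpikeTrainSet(
        neuron_id="n1",
        window_ms=100.0,
        stimuli=[
            StimulusRecord("s1", "A", [np.array([5.0, 9.99, 10.0]), np.array([50.0]), np.array([])]),
            StimulusRecord("s2", "B", [np.array([20.0, 80.0]), np.array([]), np.array([99.9])]),
        ],
    )


@pytest.fixture
def four_stim_rates():
    """One informative bin: means (2.0, 0.05, 0.05, 0.05)."""
    return BinnedRates(
        bin_ms=10.0,
        mu=np.array([[2.0], [0.05], [0.05], [0.05]]),
        stimulus_ids=["s1", "s2", "s3", "s4"],
    )


@pytest.fixture
def two_cat_map():
    return CategoryMap({"s1": "A", "s2": "A", "s3": "B", "s4": "B"})


def direct_poisson_entropy(mu, r_max):
    """Independent oracle: explicit -sum p log2 p over y = 0..r_max."""
    from math import exp, factorial, log2

    h = 0.0
    for y in range(r_max + 1):
        p = mu**y * exp(-mu) / factorial(y)
        if p > 0:
            h -= p * log2(p)
    return h


def direct_mixture_entropy(mus, weights, r_max):
    from math import exp, factorial, log2

    h = 0.0
    for y in range(r_max + 1):
        p = sum(w * m**y * exp(-m) / factorial(y) for w, m in zip(weights, mus))
        if p > 0:
            h -= p * log2(p)
    return h
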