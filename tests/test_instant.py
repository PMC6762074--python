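"""Closed-form Poisson entropies and instantaneous information vs oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tvinfo.data import BinnedRates, CategoryMap, Priors
from tvinfo.instant import (
    instantaneous_info,
    mixture_entropy,
    poisson_entropy,
    stimulus_priors,
)

from conftest import direct_mixture_entropy, direct_poisson_entropy


@pytest.mark.parametrize("mu,r_max", [(0.05, 20), (0.5, 20), (1.0, 25), (2.0, 25), (5.0, 40), (8.0, 60)])
def test_closed_form_matches_direct_summation(mu, r_max):
    """The algebraic closed form equals the explicit -sum p log2 p."""
    assert poisson_entropy(mu, r_max) == pytest.approx(direct_poisson_entropy(mu, r_max), abs=1e-10)


def test_example_entropies():
    assert poisson_entropy(0.05) == pytest.approx(0.2895, abs=5e-4)
    assert poisson_entropy(2.0, r_max=25) == pytest.approx(2.4596, abs=5e-4)


def test_truncation_guard_raises():
    with pytest.raises(ValueError, match="r_max"):
        poisson_entropy(8.0, r_max=20)


def test_mixture_degenerates_to_single_poisson():
    mus = [0.7, 0.7, 0.7, 0.7]
    assert mixture_entropy(mus, np.full(4, 0.25)) == pytest.approx(poisson_entropy(0.7), abs=1e-12)


def test_mixture_example_against_oracle():
    w = np.full(4, 0.25)
    mus = [2.0, 0.05, 0.05, 0.05]
    got = mixture_entropy(mus, w)
    assert got == pytest.approx(direct_mixture_entropy(mus, w, 20), abs=1e-10)
    assert got == pytest.approx(1.341, abs=2e-3)


@settings(max_examples=30, deadline=None)
@given(mus=st.lists(st.floats(0.05, 2.0), min_size=2, max_size=6))
def test_mixture_entropy_exceeds_mean_entropy(mus):
    """Jensen: entropy of the mixture >= mean of component entropies."""
    w = np.full(len(mus), 1.0 / len(mus))
    mix = mixture_entropy(mus, w)
    mean = sum(poisson_entropy(m) for m in mus) / len(mus)
    assert mix >= mean - 1e-10


def test_identical_rates_give_zero_info():
    rates = BinnedRates(bin_ms=10.0, mu=np.full((4, 6), 0.3), stimulus_ids=list("abcd"))
    np.testing.assert_allclose(instantaneous_info(rates).info, 0.0, atol=1e-12)


def test_peak_info_for_one_discriminable_stimulus(four_stim_rates):
    """One of four stimuli nearly perfectly discriminable -> about 0.5 bits."""
    got = instantaneous_info(four_stim_rates).info[0]
    # independent oracle: direct summation of both entropy terms
    w = np.full(4, 0.25)
    mus = [2.0, 0.05, 0.05, 0.05]
    oracle = direct_mixture_entropy(mus, w, 20) - sum(
        wi * direct_poisson_entropy(m, 20) for wi, m in zip(w, mus)
    )
    assert got == pytest.approx(oracle, abs=1e-9)
    assert got == pytest.approx(0.5, abs=0.02)


def test_info_bounded_by_log_n(rng):
    mu = rng.uniform(0.05, 2.0, size=(5, 12))
    rates = BinnedRates(bin_ms=10.0, mu=mu, stimulus_ids=[f"s{i}" for i in range(5)])
    info = instantaneous_info(rates).info
    assert np.all(info >= -1e-12)
    assert np.all(info <= np.log2(5) + 1e-12)


def test_category_info_never_exceeds_stimulus_info(rng, two_cat_map):
    """Grouping stimuli into categories cannot add information."""
    mu = rng.uniform(0.05, 1.5, size=(4, 20))
    rates = BinnedRates(bin_ms=10.0, mu=mu, stimulus_ids=["s1", "s2", "s3", "s4"])
    stim = instantaneous_info(rates).info
    cat = instantaneous_info(rates, grouping=two_cat_map).info
    assert np.all(cat <= stim + 1e-9)
    assert np.all(cat >= -1e-12)


def test_unknown_stimulus_in_grouping_raises(four_stim_rates):
    cmap = CategoryMap({"x1": "A", "x2": "B"})
    with pytest.raises(KeyError):
        instantaneous_info(four_stim_rates, grouping=cmap)


class TestPriors:
    def test_balanced_equal_category_coincides_with_uniform(self, two_cat_map):
        p = stimulus_priors(two_cat_map, "equal_category")
        np.testing.assert_allclose(p.p_s, 0.25)

    def test_unbalanced_category_prior(self):
        cmap = CategoryMap({"s1": "A", "s2": "B", "s3": "B", "s4": "B"})
        p = stimulus_priors(cmap, "equal_category")
        np.testing.assert_allclose(p.p_s, [1 / 2, 1 / 6, 1 / 6, 1 / 6])

    @settings(max_examples=25, deadline=None)
    @given(labels=st.lists(st.integers(0, 3), min_size=1, max_size=8))
    def test_priors_sum_to_one(self, labels):
        cmap = CategoryMap({f"s{i}": f"c{c}" for i, c in enumerate(labels)})
        for scheme in ("equal_stimulus", "equal_category"):
            assert stimulus_priors(cmap, scheme).p_s.sum() == pytest.approx(1.0, abs=1e-12)

    def test_invalid_priors_rejected(self):
        with pytest.raises(ValueError):
            Priors(p_s=np.array([0.5, 0.6]))
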