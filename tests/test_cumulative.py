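"""Cumulative-information estimators against enumeration oracles."""

import numpy as np
import pytest

from tvinfo.data import BinnedRates, CategoryMap
from tvinfo.cumulative import (
    MCParams,
    conditional_cum_entropy,
    cumulative_info,
    enumerated_joint_entropy,
    exact_window_info,
    markov_joint_entropy,
    mc_joint_entropy,
)
from tvinfo.instant import instantaneous_info, mixture_entropy, poisson_entropy


def small_rates(mu, r_max=20, tol=1e-12):
    mu = np.asarray(mu, dtype=float)
    ids = [f"s{i}" for i in range(mu.shape[0])]
    return BinnedRates(bin_ms=10.0, mu=mu, stimulus_ids=ids, r_max=r_max, trunc_tol=tol)


FAST_MC = MCParams(chunk=20_000, se_stop=0.01, max_samples=400_000, se_abort=0.6, seed=0)


class TestConditionalEntropy:
    def test_single_bin(self, four_stim_rates):
        got = conditional_cum_entropy(four_stim_rates, t_end=0)
        expected = 0.25 * poisson_entropy(2.0) + 0.75 * poisson_entropy(0.05)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_additivity(self, rng):
        rates = small_rates(rng.uniform(0.05, 2.0, size=(4, 8)))
        for t in range(1, 8):
            inc = conditional_cum_entropy(rates, t_end=t) - conditional_cum_entropy(rates, t_end=t - 1)
            w, = (np.full(4, 0.25),)
            per_bin = sum(0.25 * poisson_entropy(m, 20) for m in rates.mu[:, t])
            assert inc == pytest.approx(per_bin, abs=1e-9)

    def test_identical_constant_stimuli(self):
        rates = small_rates(np.full((4, 10), 0.5))
        got = conditional_cum_entropy(rates, t_end=9)
        assert got == pytest.approx(10 * poisson_entropy(0.5), abs=1e-9)


class TestMonteCarlo:
    def test_single_bin_matches_mixture_entropy(self, four_stim_rates):
        h, se, _, reliable = mc_joint_entropy(four_stim_rates, t_end=0, mc=FAST_MC)
        assert reliable
        target = mixture_entropy([2.0, 0.05, 0.05, 0.05], np.full(4, 0.25))
        assert h == pytest.approx(target, abs=max(3 * se, 1e-3))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_on_small_cases(self, seed):
        """Brute-force oracle: <= 3 bins, truncated support, random rates."""
        r = np.random.default_rng(seed)
        rates = small_rates(r.uniform(0.05, 2.0, size=(4, 3)), r_max=5, tol=1.0)
        exact = enumerated_joint_entropy(rates, t_end=2)
        mc = MCParams(chunk=20_000, se_stop=0.002, max_samples=400_000, se_abort=0.6, seed=seed)
        h, se, _, _ = mc_joint_entropy(rates, t_end=2, mc=mc)
        assert abs(h - exact) < 3 * se + 1e-4

    def test_identical_stimuli_joint_is_sum_of_marginals(self):
        rates = small_rates(np.tile(np.array([0.3, 0.8, 1.5]), (4, 1)))
        h, se, _, _ = mc_joint_entropy(rates, t_end=2, mc=FAST_MC)
        target = sum(poisson_entropy(m) for m in (0.3, 0.8, 1.5))
        assert h == pytest.approx(target, abs=max(3 * se, 1e-3))

    def test_seeded_determinism(self, rng):
        rates = small_rates(rng.uniform(0.05, 1.0, size=(3, 4)))
        a = mc_joint_entropy(rates, t_end=3, mc=FAST_MC)
        b = mc_joint_entropy(rates, t_end=3, mc=FAST_MC)
        assert a == b


class TestCumulativeSeries:
    def test_first_bin_equals_instantaneous(self, rng):
        rates = small_rates(rng.uniform(0.05, 1.5, size=(4, 3)))
        series = cumulative_info(rates, mc=FAST_MC)
        inst = instantaneous_info(rates).info[0]
        assert series.info[0] == pytest.approx(inst, abs=max(3 * series.se[0], 3e-3))

    def test_identical_stimuli_stay_at_zero(self):
        rates = small_rates(np.full((4, 6), 0.4))
        series = cumulative_info(rates, mc=FAST_MC)
        assert np.all(np.abs(series.info) <= 3 * series.se + 1e-3)

    def test_monotone_and_bounded_within_error(self, rng):
        rates = small_rates(rng.uniform(0.05, 1.2, size=(4, 6)))
        series = cumulative_info(rates, mc=FAST_MC)
        tol = 3 * (series.se[1:] + series.se[:-1])
        assert np.all(np.diff(series.info) >= -tol)
        assert np.all(series.info <= np.log2(4) + 3 * series.se)


class TestMarkov:
    def test_full_order_is_exact(self, rng):
        rates = small_rates(rng.uniform(0.05, 2.0, size=(3, 4)), r_max=6, tol=1.0)
        exact = enumerated_joint_entropy(rates, t_end=3)
        assert markov_joint_entropy(rates, t_end=3, order=4) == pytest.approx(exact, abs=1e-9)

    def test_identical_stimuli_any_order(self):
        mus = (0.3, 0.8, 1.5, 0.6)
        rates = small_rates(np.tile(np.array(mus), (4, 1)))
        target = sum(poisson_entropy(m) for m in mus)
        for order in (1, 2, 3):
            got = markov_joint_entropy(rates, t_end=3, order=order)
            assert got == pytest.approx(target, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_low_order_overestimates_entropy(self, seed):
        """Bounded history ignores long-range dependence, inflating entropy."""
        r = np.random.default_rng(seed)
        rates = small_rates(r.uniform(0.05, 2.0, size=(4, 3)), r_max=6, tol=1.0)
        exact = enumerated_joint_entropy(rates, t_end=2)
        assert markov_joint_entropy(rates, t_end=2, order=1) >= exact - 1e-12

    def test_budget_guard(self):
        rates = small_rates(np.full((4, 6), 0.5))
        with pytest.raises(ValueError, match="budget"):
            markov_joint_entropy(rates, t_end=5, order=5, budget=1e4)


class TestExactWindow:
    def test_single_bin_window_is_instantaneous(self, rng):
        rates = small_rates(rng.uniform(0.05, 2.0, size=(4, 6)))
        win = exact_window_info(rates, n_bins=1)
        inst = instantaneous_info(rates)
        np.testing.assert_allclose(win.info, inst.info, atol=1e-10)

    def test_identical_stimuli_zero(self):
        rates = small_rates(np.full((4, 8), 0.5), r_max=8, tol=1.0)
        win = exact_window_info(rates, n_bins=3)
        np.testing.assert_allclose(win.info, 0.0, atol=1e-10)


def test_estimator_ordering_window_mc_markov():
    """On a slowly varying synthetic neuron the three joint-entropy routes
    order as: exact running window <= Monte Carlo <= low-order Markov."""
    t = np.arange(12)
    mu = np.stack([
        0.3 + 0.25 * np.sin(2 * np.pi * (t + 3 * i) / 12.0) for i in range(4)
    ]) + 0.3
    rates = small_rates(mu, r_max=8, tol=1.0)
    mc = MCParams(chunk=50_000, se_stop=0.01, max_samples=2_000_000, se_abort=0.6, seed=5)
    series_mc = cumulative_info(rates, mc=mc)
    series_win = exact_window_info(rates, n_bins=4)

    from tvinfo.instant import condition_tables, entropy_of_pmf

    w, pmf = condition_tables(rates)
    cond = (w @ entropy_of_pmf(pmf)).cumsum()
    markov = np.array([
        markov_joint_entropy(rates, t_end=tt, order=min(4, tt + 1)) - cond[tt]
        for tt in range(12)
    ])
    slack = 3 * series_mc.se + 1e-6
    assert np.all(series_win.info <= series_mc.info + slack)
    assert np.all(series_mc.info <= markov + slack)


def test_mcparams_validation():
    with pytest.raises(ValueError):
        MCParams(se_stop=0.7, se_abort=0.6)
    with pytest.raises(ValueError):
        MCParams(chunk=100, max_samples=50)
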