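"""Poisson GOF, Fano factors, correlations and temporal-resolution checks."""

import numpy as np
import pytest

from tvinfo.data import BinnedCounts, BinnedRates, SpikeTrainSet, StimulusRecord
from tvinfo.diagnostics import (
    coherence_info_fraction,
    coherence_information,
    fano_series,
    noise_correlation,
    poisson_gof,
    power_fraction,
    stimulus_correlation,
)
from tvinfo.io import bin_counts
from tvinfo.rates import RateEnsemble
from tvinfo.simulate import make_model_neuron, sample_spikes


def _poisson_counts(rng, mu, m, n_bins):
    return BinnedCounts(
        bin_ms=10.0,
        counts=[rng.poisson(mu, size=(m, n_bins)) for _ in range(len(np.atleast_1d(mu)) or 1)],
        stimulus_ids=["s1"],
    )


class TestPoissonGOF:
    def test_null_specificity(self, rng):
        """Counts simulated from the fitted means: few BH rejections."""
        fracs = []
        for seed in range(6):
            r = np.random.default_rng(seed)
            mu = r.uniform(0.2, 2.0, size=(3, 12))
            counts = BinnedCounts(10.0, [r.poisson(mu[s], size=(10, 12)) for s in range(3)],
                                  ["a", "b", "c"])
            rates = BinnedRates(10.0, mu, ["a", "b", "c"])
            _, frac = poisson_gof(counts, rates, n_boot=400, seed=seed)
            fracs.append(frac)
        assert np.mean(fracs) <= 0.075  # 1.5x the nominal alpha

    def test_constant_counts_rejected(self):
        """Zero across-trial variance at mean 2 is grossly non-Poisson."""
        counts = BinnedCounts(10.0, [np.full((10, 1), 2)], ["s1"])
        rates = BinnedRates(10.0, np.array([[2.0]]), ["s1"])
        pvals, frac = poisson_gof(counts, rates, n_boot=400, seed=0)
        assert frac == 1.0
        assert pvals[0, 0] < 0.05

    def test_all_zero_cell_excluded(self):
        counts = BinnedCounts(10.0, [np.zeros((10, 2), dtype=int)], ["s1"])
        rates = BinnedRates(10.0, np.full((1, 2), 0.05), ["s1"])
        pvals, frac = poisson_gof(counts, rates, n_boot=100, seed=0)
        assert np.isnan(pvals).all()
        assert np.isnan(frac)


class TestFano:
    def test_hand_computed_cell(self):
        counts = BinnedCounts(10.0, [np.array([[0], [0], [1], [1]])], ["s1"])
        fano_bin, fano_mean = fano_series(counts)
        assert fano_bin[0] == pytest.approx((1 / 3) / 0.5)  # sample variance
        assert fano_mean == pytest.approx(fano_bin[0])

    def test_identical_counts_zero(self):
        counts = BinnedCounts(10.0, [np.full((5, 3), 2)], ["s1"])
        assert fano_series(counts)[1] == pytest.approx(0.0)

    def test_poisson_null_near_one(self, rng):
        counts = BinnedCounts(
            10.0, [rng.poisson(1.0, size=(10, 60)) for _ in range(10)],
            [f"s{i}" for i in range(10)]
        )
        _, fano_mean = fano_series(counts)
        assert abs(fano_mean - 1.0) < 0.1

    def test_fano_converges_with_trials(self, rng):
        devs = []
        for m in (10, 100, 1000):
            counts = BinnedCounts(10.0, [rng.poisson(0.8, size=(m, 40))], ["s1"])
            devs.append(abs(fano_series(counts)[1] - 1.0))
        assert devs[2] < devs[0]


class TestNoiseCorrelation:
    def test_independent_poisson_near_zero(self):
        means = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            counts = BinnedCounts(10.0, [r.poisson(1.0, size=(10, 30)) for _ in range(4)],
                                  list("abcd"))
            means.append(noise_correlation(counts)[0])
        assert abs(np.mean(means)) < 0.02

    def test_shared_gain_positive(self, rng):
        counts = []
        for _ in range(4):
            gain = rng.gamma(4.0, 0.25, size=(10, 1))  # per-trial shared gain
            counts.append(rng.poisson(2.0 * gain, size=(10, 30)))
        mean, values = noise_correlation(BinnedCounts(10.0, counts, list("abcd")))
        assert mean > 0.1
        assert values.size > 0

    def test_single_bin_empty(self, rng):
        counts = BinnedCounts(10.0, [rng.poisson(1.0, size=(5, 1))], ["s1"])
        mean, values = noise_correlation(counts)
        assert values.size == 0 and np.isnan(mean)


class TestStimulusCorrelation:
    def test_persistent_tuning_gives_one(self):
        mu = np.tile(np.array([[0.2], [0.6], [1.1]]), (1, 10))
        assert stimulus_correlation(mu) == pytest.approx(1.0)

    def test_shuffled_rates_near_zero(self, rng):
        mu = rng.uniform(0.1, 2.0, size=(40, 50))
        assert abs(stimulus_correlation(mu)) < 0.1

    def test_alternating_tuning_gives_minus_one(self):
        """Tuning that flips between consecutive bins is anti-persistent."""
        mu = np.empty((4, 10))
        mu[:, ::2] = np.array([[2.0], [0.1], [2.0], [0.1]])
        mu[:, 1::2] = np.array([[0.1], [2.0], [0.1], [2.0]])
        assert stimulus_correlation(mu) == pytest.approx(-1.0)


class TestSpectral:
    def test_closed_form_information_integral(self):
        """gamma2 = 0.5 on 0-50 Hz, 0 above: I = -50*log2(0.5) = 50 bits/s."""
        freqs = np.linspace(0, 500, 501)
        g2 = np.where(freqs <= 50, 0.5, 0.0)
        i_low = coherence_information(g2, freqs, 50.0)
        i_all = coherence_information(g2, freqs, 500.0)
        assert i_low == pytest.approx(50.0, rel=0.02)
        assert i_all == pytest.approx(i_low, rel=0.02)  # fraction 1

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_band_limited_neuron_fraction_near_one(self, seed):
        """5 Hz rate modulation: nearly all coherence info below 50 Hz."""
        t = np.arange(600)
        rate = 0.08 * (1 + np.sin(2 * np.pi * 5e-3 * t))
        spec = make_model_neuron("rate", amplitudes=(0.05, 0.05))
        spec.rates[:] = rate
        spikes = sample_spikes(spec, n_trials=20, seed=seed)
        assert coherence_info_fraction(spikes, seed=0) > 0.95

    def test_zero_rate_neuron_undefined(self):
        spikes = SpikeTrainSet(
            "n", 600.0,
            [StimulusRecord("s1", "A", [np.empty(0)] * 4)],
        )
        assert np.isnan(coherence_info_fraction(spikes))

    def test_power_fraction_constant_rate(self):
        ens = RateEnsemble(fs=1000.0, window_ms=600.0, rate=np.full((1, 600), 0.05),
                           stimulus_ids=["s1"])
        assert power_fraction(ens) == pytest.approx(1.0, abs=1e-9)

    def test_power_fraction_spectral_splits(self):
        t = np.arange(600)
        low = 0.05 * (1 + 0.5 * np.sin(2 * np.pi * 5e-3 * t))
        high = 0.05 * (1 + 0.5 * np.sin(2 * np.pi * 0.1 * t))
        ens_low = RateEnsemble(fs=1000.0, window_ms=600.0, rate=low[None, :], stimulus_ids=["s"])
        ens_high = RateEnsemble(fs=1000.0, window_ms=600.0, rate=high[None, :], stimulus_ids=["s"])
        assert power_fraction(ens_low) > 0.99
        # 100 Hz modulation: only the DC share remains below 50 Hz
        frac_high = power_fraction(ens_high)
        dc_share = 1.0 / (1.0 + 0.5**2 / 2.0)
        assert frac_high < 0.95
        assert frac_high == pytest.approx(dc_share, abs=0.05)
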