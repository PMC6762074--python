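"""Adaptive-KDE rate estimation: fallbacks, integration, recovery."""

import numpy as np
import pytest

from tvinfo.data import SpikeTrainSet, StimulusRecord
from tvinfo.rates import (
    RateEnsemble,
    estimate_rate,
    estimate_rates,
    integrate_to_bins,
    jackknife_rates,
    kde_validation_error,
)
from tvinfo.simulate import make_model_neuron, sample_spikes


def test_zero_spike_fallback():
    """10 silent trials over 600 points -> constant 1/12000 spikes/ms."""
    rate = estimate_rate([np.empty(0)] * 10, window_ms=600.0)
    np.testing.assert_allclose(rate, 1.0 / 12000.0)


def test_one_spike_fallback():
    trials = [np.array([250.0])] + [np.empty(0)] * 9
    rate = estimate_rate(trials, window_ms=600.0)
    np.testing.assert_allclose(rate, 1.0 / 6000.0)


def test_single_trial_rejected():
    with pytest.raises(ValueError):
        estimate_rate([np.array([1.0])])


def test_constant_rate_recovered():
    spec = make_model_neuron("rate", amplitudes=(0.05, 0.05))
    spikes = sample_spikes(spec, n_trials=10, seed=0)
    rate = estimate_rate(spikes.stimuli[0].trials, window_ms=600.0)
    jk = jackknife_rates(spikes.stimuli[0].trials, window_ms=600.0)
    mean_est = rate.mean()
    jk_means = jk.mean(axis=1)
    se = np.sqrt((jk.shape[0] - 1) / jk.shape[0] * ((jk_means - jk_means.mean()) ** 2).sum())
    assert abs(mean_est - 0.05) < max(2 * se, 0.01)


def test_jackknife_count_and_identical_trials():
    trials = [np.array([100.0, 300.0])] * 6
    jk = jackknife_rates(trials, window_ms=600.0)
    assert jk.shape[0] == 6
    full = estimate_rate(trials, window_ms=600.0)
    # delete-one of identical data: replicates are identical, and equal to
    # the full estimate except where the M-dependent positivity floor binds
    assert np.max(np.abs(jk - jk[0])) == 0.0
    above = full > 1.0 / 6000.0
    np.testing.assert_allclose(jk[0][above], full[above], rtol=1e-10)


def test_validation_error_fallback_exact():
    """Silent neuron: KDE falls back to 1/(2 M N) and the error against a
    (near-)zero true rate equals that constant."""
    spec = make_model_neuron("rate", amplitudes=(1e-12, 1e-12))
    err = kde_validation_error(spec, n_trials=10, seed=0)
    assert err == pytest.approx(1.0 / 12000.0, rel=1e-6)


def test_mass_conservation():
    """Integral of the rate times M stays within 5% of the pooled count."""
    spec = make_model_neuron("temporal", amplitudes=0.1)
    spikes = sample_spikes(spec, n_trials=10, seed=2)
    rec = spikes.stimuli[1]
    rate = estimate_rate(rec.trials, window_ms=600.0)
    total = rate.sum() * 10  # spikes/ms * 1 ms samples * M trials
    assert total == pytest.approx(rec.spike_count(), rel=0.05)


class TestIntegrateToBins:
    def test_constant_rate_integration(self):
        ens = RateEnsemble(fs=1000.0, window_ms=600.0, rate=np.full((1, 600), 0.05),
                           stimulus_ids=["s1"])
        mu = integrate_to_bins(ens, bin_ms=10.0).mu
        np.testing.assert_allclose(mu, 0.5)

    def test_fallback_rate_floored(self):
        ens = RateEnsemble(fs=1000.0, window_ms=600.0, rate=np.full((1, 600), 1.0 / 12000.0),
                           stimulus_ids=["s1"])
        mu = integrate_to_bins(ens, bin_ms=10.0).mu
        np.testing.assert_allclose(mu, 0.05)  # raw 1/1200 floored to 1/20

    def test_floor_postcondition(self, rng):
        ens = RateEnsemble(fs=1000.0, window_ms=600.0,
                           rate=rng.uniform(1e-6, 0.2, size=(3, 600)),
                           stimulus_ids=["a", "b", "c"])
        assert integrate_to_bins(ens, bin_ms=10.0).mu.min() >= 0.05


def test_kde_error_small_on_archetypes():
    """Mean |estimated - true| rate below 0.02 spikes/ms at 10 trials."""
    errs = []
    for archetype in ("rate", "onset", "temporal"):
        spec = make_model_neuron(archetype, amplitudes=0.1 if archetype != "rate" else None)
        errs.append(kde_validation_error(spec, n_trials=10, seed=7))
    assert np.mean(errs) < 0.02


def test_kde_error_shrinks_with_trials():
    spec = make_model_neuron("onset", amplitudes=0.1)
    e_small = kde_validation_error(spec, n_trials=5, seed=1)
    e_big = kde_validation_error(spec, n_trials=100, seed=1)
    assert e_big < e_small


def test_estimate_rates_flags_degenerate():
    stimuli = [
        StimulusRecord("s1", "A", [np.array([100.0, 200.0, 300.0])] * 4),
        StimulusRecord("s2", "B", [np.empty(0)] * 4),
    ]
    spikes = SpikeTrainSet("n", 600.0, stimuli)
    ens = estimate_rates(spikes, jackknife=True)
    assert not ens.degenerate[0]
    assert ens.degenerate[1]
    assert len(ens.jackknife) == 2
    assert ens.jackknife[0].shape == (4, 600)
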