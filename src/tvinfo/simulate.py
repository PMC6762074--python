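"""Model neurons with known time-varying rates and a Poisson spike sampler.

Archetypes cover the canonical single-neuron codes used to validate the
information estimators:

* ``rate`` -- four stimuli drive constant rates of distinct amplitude;
* ``onset`` -- identical burst amplitude and duration, distinct latencies;
* ``temporal`` -- identical amplitude, bursts at disjoint times;
* ``invariant`` -- stimuli within a category share an identical rate, rates
  differ strongly across categories (perfect within-category invariance);
* ``interleaved`` -- distinct constant rates whose rank order alternates
  category labels, so categories carry no extra structure.

Rates are sampled at 1 kHz (one value per ms) in spikes/ms.  Spike trains are
drawn as an inhomogeneous Poisson process: the count in each 1 ms sample is
Poisson with mean equal to the rate there, and spikes are jittered uniformly
inside the sample.  This is exact for the piecewise-constant rates used here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import CategoryMap, SpikeTrainSet, StimulusRecord

__all__ = ["ModelNeuronSpec", "make_model_neuron", "sample_spikes"]

ARCHETYPES = ("rate", "onset", "temporal", "invariant", "interleaved", "custom")


@dataclass
class ModelNeuronSpec:
    """Ground-truth rates (spikes/ms at 1 kHz) for a simulated neuron."""

    rates: np.ndarray  # (n_stimuli, window_ms) spikes/ms
    categories: CategoryMap
    archetype: str = "custom"
    stimulus_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rates = np.atleast_2d(np.asarray(self.rates, dtype=float))
        if not np.all(np.isfinite(self.rates)) or np.any(self.rates < 0):
            raise ValueError("rates must be finite and non-negative")
        if not self.stimulus_ids:
            self.stimulus_ids = [f"s{i + 1}" for i in range(self.rates.shape[0])]
        if len(self.stimulus_ids) != self.rates.shape[0]:
            raise ValueError("one stimulus_id per rate curve required")

    @property
    def n_stimuli(self) -> int:
        return int(self.rates.shape[0])

    @property
    def window_ms(self) -> int:
        return int(self.rates.shape[1])

    def binned_means(self, bin_ms: float = 10.0) -> np.ndarray:
        """Integrate the true rates into expected counts per analysis bin."""
        window = self.window_ms
        n_bins = int(round(window / bin_ms))
        if abs(window / bin_ms - n_bins) > 1e-9:
            raise ValueError("bin_ms must divide the window")
        return self.rates.reshape(self.n_stimuli, n_bins, -1).sum(axis=2)


def _burst(window_ms: int, start: float, stop: float, amplitude: float, baseline: float) -> np.ndarray:
    t = np.arange(window_ms)
    rate = np.full(window_ms, baseline, dtype=float)
    rate[(t >= start) & (t < stop)] = amplitude
    return rate


def make_model_neuron(
    archetype: str,
    window_ms: int = 600,
    amplitudes=None,
    latencies=None,
    burst_ms: float = 200.0,
    burst_windows=None,
    baseline: float = 0.005,
    n_stimuli: int = 4,
    n_categories: int = 2,
    category_rates=(0.01, 0.2),
) -> ModelNeuronSpec:
    """Build the ground-truth rates for one of the model-neuron archetypes.

    Amplitudes are in spikes/ms.  Defaults give four stimuli; the
    ``invariant``/``interleaved`` archetypes additionally carry category
    labels (two categories of two stimuli by default).
    """
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}")
    window_ms = int(window_ms)

    if archetype == "rate":
        amps = tuple(amplitudes) if amplitudes is not None else (0.01, 0.03, 0.06, 0.09)
        if any(a <= 0 for a in amps):
            raise ValueError("amplitudes must be positive")
        rates = np.tile(np.asarray(amps, dtype=float)[:, None], (1, window_ms))
        cmap = CategoryMap({f"s{i + 1}": f"s{i + 1}" for i in range(len(amps))})
        return ModelNeuronSpec(rates, cmap, "rate")

    if archetype == "onset":
        # burst amplitude: strong enough that the cumulative information
        # saturates near log2(4) by 600 ms, yet inside the regime where the
        # importance-sampling entropy estimator keeps its weights tame
        amp = float(amplitudes) if np.isscalar(amplitudes) else (amplitudes[0] if amplitudes else 0.065)
        if amp <= 0:
            raise ValueError("amplitude must be positive")
        lats = tuple(latencies) if latencies is not None else (0.0, 100.0, 200.0, 300.0)
        rates = np.stack([_burst(window_ms, l, l + burst_ms, amp, baseline) for l in lats])
        cmap = CategoryMap({f"s{i + 1}": f"s{i + 1}" for i in range(len(lats))})
        return ModelNeuronSpec(rates, cmap, "onset")

    if archetype == "temporal":
        amp = float(amplitudes) if np.isscalar(amplitudes) else (amplitudes[0] if amplitudes else 0.1)
        if amp <= 0:
            raise ValueError("amplitude must be positive")
        wins = burst_windows or [(50, 150), (200, 300), (350, 450), (500, 600)]
        wins = sorted((float(a), float(b)) for a, b in wins)
        for (a0, b0), (a1, _) in zip(wins, wins[1:]):
            if a1 < b0:
                raise ValueError("temporal bursts must not overlap")
        rates = np.stack([_burst(window_ms, a, b, amp, baseline) for a, b in wins])
        cmap = CategoryMap({f"s{i + 1}": f"s{i + 1}" for i in range(len(wins))})
        return ModelNeuronSpec(rates, cmap, "temporal")

    # categorical archetypes: constant rates, explicit category labels
    if archetype == "invariant":
        if n_stimuli % n_categories:
            raise ValueError("n_stimuli must be a multiple of n_categories")
        per = n_stimuli // n_categories
        if amplitudes is not None:
            amps = tuple(amplitudes)
        else:
            amps = tuple(np.repeat(np.asarray(category_rates, dtype=float), per))
        if len(amps) != n_stimuli or any(a <= 0 for a in amps):
            raise ValueError("need one positive amplitude per stimulus")
        rates = np.tile(np.asarray(amps, dtype=float)[:, None], (1, window_ms))
        labels = {f"s{i + 1}": f"c{i // per + 1}" for i in range(n_stimuli)}
        return ModelNeuronSpec(rates, CategoryMap(labels), "invariant")

    # interleaved: rank order of the rates alternates the category labels
    amps = tuple(amplitudes) if amplitudes is not None else (0.01, 0.04, 0.08, 0.12)
    if any(a <= 0 for a in amps):
        raise ValueError("amplitudes must be positive")
    rates = np.tile(np.asarray(amps, dtype=float)[:, None], (1, window_ms))
    order = np.argsort(amps)
    labels = {}
    for rank, i in enumerate(order):
        labels[f"s{i + 1}"] = f"c{rank % n_categories + 1}"
    labels = {f"s{i + 1}": labels[f"s{i + 1}"] for i in range(len(amps))}
    return ModelNeuronSpec(rates, CategoryMap(labels), "interleaved")


def sample_spikes(spec: ModelNeuronSpec, n_trials: int = 10, seed: int = 0) -> SpikeTrainSet:
    """Draw inhomogeneous-Poisson spike trains from a model neuron.

    Each trial is independent; the spike count in any interval is Poisson
    with mean equal to the integrated rate.  Identical ``seed`` gives an
    identical :class:`SpikeTrainSet`.
    """
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    rng = np.random.default_rng(seed)
    stimuli = []
    for i, stim_id in enumerate(spec.stimulus_ids):
        lam = spec.rates[i]  # mean count per 1 ms sample
        trials = []
        for _ in range(n_trials):
            counts = rng.poisson(lam)
            pos = np.flatnonzero(counts)
            if pos.size:
                times = np.repeat(pos.astype(float), counts[pos])
                times += rng.random(times.size)
                times = np.sort(np.minimum(times, spec.window_ms - 1e-9))
            else:
                times = np.empty(0)
            trials.append(times)
        stimuli.append(StimulusRecord(stim_id, spec.categories.mapping[stim_id], trials))
    return SpikeTrainSet(neuron_id=f"model_{spec.archetype}", window_ms=float(spec.window_ms), stimuli=stimuli)
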