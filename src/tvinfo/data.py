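"""Trial-structured spike data and the binned containers derived from it.

Time is measured in milliseconds from stimulus onset.  Analysis bins are
half-open, ``[b*bin_ms, (b+1)*bin_ms)``, so a response window of 600 ms cut
into 10 ms bins yields exactly 60 complete bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusRecord",
    "SpikeTrainSet",
    "BinnedCounts",
    "BinnedRates",
    "CategoryMap",
    "Priors",
    "InfoSeries",
]


@dataclass
class StimulusRecord:
    """Spike trains for repeated presentations of one stimulus.

    Parameters
    ----------
    stimulus_id : str
        Unique label of the stimulus within a neuron.
    category : str
        Category (e.g. call-type) label the stimulus belongs to.
    trials : list of ndarray
        One array of spike times (ms) per presentation.  Jackknife
        resampling requires at least two trials.
    """

    stimulus_id: str
    category: str
    trials: list = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def spike_count(self) -> int:
        return int(sum(len(t) for t in self.trials))


@dataclass
class SpikeTrainSet:
    """All trial-structured spike data recorded from one neuron."""

    neuron_id: str
    window_ms: float = 600.0
    stimuli: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.window_ms <= 0:
            raise ValueError("window_ms must be positive")
        seen = set()
        for rec in self.stimuli:
            if rec.stimulus_id in seen:
                raise ValueError(f"duplicate stimulus_id {rec.stimulus_id!r}")
            seen.add(rec.stimulus_id)
            if rec.n_trials < 2:
                raise ValueError(
                    f"stimulus {rec.stimulus_id!r} has {rec.n_trials} trial(s); "
                    "at least 2 are required for jackknife resampling"
                )
            for j, tr in enumerate(rec.trials):
                tr = np.asarray(tr, dtype=float)
                rec.trials[j] = tr
                if tr.size and (tr.min() < 0 or tr.max() >= self.window_ms):
                    raise ValueError(
                        f"stimulus {rec.stimulus_id!r} trial {j}: spike time outside "
                        f"[0, {self.window_ms}) ms"
                    )

    @property
    def n_stimuli(self) -> int:
        return len(self.stimuli)

    @property
    def stimulus_ids(self) -> list:
        return [r.stimulus_id for r in self.stimuli]

    def category_map(self) -> "CategoryMap":
        return CategoryMap({r.stimulus_id: r.category for r in self.stimuli})


@dataclass
class CategoryMap:
    """Assignment of stimuli to categories.

    Derived quantities follow the equal-category prior: with ``k_i`` stimuli
    in the category of stimulus *i* and ``n_c`` categories, the stimulus
    probability is ``p(s_i) = 1 / (k_i * n_c)``.
    """

    mapping: dict

    def __post_init__(self) -> None:
        if not self.mapping:
            raise ValueError("empty category map")

    @property
    def n_stimuli(self) -> int:
        return len(self.mapping)

    @property
    def categories(self) -> list:
        out = []
        for c in self.mapping.values():
            if c not in out:
                out.append(c)
        return out

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    def sizes(self) -> dict:
        sizes: dict = {}
        for c in self.mapping.values():
            sizes[c] = sizes.get(c, 0) + 1
        return sizes

    def k(self, stimulus_id: str) -> int:
        return self.sizes()[self.mapping[stimulus_id]]

    def members(self, category: str) -> list:
        return [s for s, c in self.mapping.items() if c == category]

    def indices_by_category(self, stimulus_ids: list) -> dict:
        """Map category -> list of positions of its stimuli in *stimulus_ids*."""
        for s in stimulus_ids:
            if s not in self.mapping:
                raise KeyError(f"stimulus {s!r} missing from category map")
        out: dict = {c: [] for c in self.categories}
        for i, s in enumerate(stimulus_ids):
            out[self.mapping[s]].append(i)
        return {c: idx for c, idx in out.items() if idx}


@dataclass
class Priors:
    """Stimulus probabilities p(s_i) used to weight conditional responses."""

    p_s: np.ndarray
    scheme: str = "equal_stimulus"

    def __post_init__(self) -> None:
        self.p_s = np.asarray(self.p_s, dtype=float)
        if np.any(self.p_s <= 0):
            raise ValueError("stimulus priors must be strictly positive")
        if abs(self.p_s.sum() - 1.0) > 1e-12:
            raise ValueError("stimulus priors must sum to 1")


@dataclass
class BinnedCounts:
    """Per stimulus x trial x bin spike counts.

    ``counts`` is a list (one entry per stimulus, trial numbers may differ
    across stimuli) of integer arrays of shape ``(n_trials, n_bins)``.
    """

    bin_ms: float
    counts: list
    stimulus_ids: list

    @property
    def n_bins(self) -> int:
        return self.counts[0].shape[1]

    @property
    def n_stimuli(self) -> int:
        return len(self.counts)


@dataclass
class BinnedRates:
    """Expected spike counts per analysis bin: the Poisson means mu_si(t).

    ``mu`` has shape ``(n_stimuli, n_bins)`` in expected spikes per bin.
    ``jackknife_mu`` optionally holds delete-one replicates, one array of
    shape ``(M_s, n_bins)`` per stimulus.  ``r_max`` truncates all count
    sums; the truncated Poisson mass must be within 1e-12 of unity for
    every (stimulus, bin), which is checked where entropies are computed.
    """

    bin_ms: float
    mu: np.ndarray
    stimulus_ids: list
    jackknife_mu: list | None = None
    r_max: int = 20
    trunc_tol: float = 1e-12  # relax only for deliberately truncated toy models

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        if not np.all(np.isfinite(self.mu)):
            raise ValueError("non-finite Poisson mean")
        if np.any(self.mu <= 0):
            raise ValueError("Poisson means must be positive (apply the rate floor)")

    @property
    def n_bins(self) -> int:
        return int(self.mu.shape[1])

    @property
    def n_stimuli(self) -> int:
        return int(self.mu.shape[0])


@dataclass
class InfoSeries:
    """Information values (bits) per analysis bin, with optional errors.

    ``abort_bin`` marks the first bin at which a Monte Carlo estimate was
    deemed unreliable; values at and after that bin are NaN and must not be
    interpreted.
    """

    bin_ms: float
    info: np.ndarray
    se: np.ndarray | None = None
    kind: str = "instantaneous_stim"
    abort_bin: int | None = None

    def __post_init__(self) -> None:
        self.info = np.asarray(self.info, dtype=float)
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)
            if self.se.shape != self.info.shape:
                raise ValueError("se and info must have the same shape")
            if np.any(self.se[np.isfinite(self.se)] < 0):
                raise ValueError("negative standard error")
        limit = self.abort_bin if self.abort_bin is not None else self.info.size
        if not np.all(np.isfinite(self.info[:limit])):
            raise ValueError("non-finite information before abort_bin")

    @property
    def n_bins(self) -> int:
        return int(self.info.size)

    def times_ms(self) -> np.ndarray:
        """Bin end times, i.e. the elapsed response time each value covers."""
        return self.bin_ms * (1.0 + np.arange(self.n_bins))
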