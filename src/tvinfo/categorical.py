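"""The Categorical Information Index (CII).

The CII places the observed cumulative categorical information (CCI) of a
neuron between three references computed per time bin:

* **floor** (CII = 0): the categorical information obtained when stimuli are
  grouped into categories at random (category sizes preserved);
* **expected** (CII = 1): the categorical information predicted when the
  stimulus information is spread equally over stimuli and the response
  ordering segregates the true categories perfectly;
* **ceiling** (CII = 2): all stimulus information is spent on categories,
  i.e. the stimulus cumulative information capped at ``log2(n_c)``.

The expected reference converts the stimulus information to an equivalent
correct-decoding probability *p* through a symmetric confusion matrix,
groups that matrix by category, and reads the category information off the
grouped matrix.  The index is piecewise linear:

    CII = (CCI - floor) / (expected - floor)        if CCI < expected
    CII = 1 + (CCI - expected) / (ceiling - expected)  otherwise
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .data import BinnedRates, CategoryMap, InfoSeries
from .cumulative import MCParams, cumulative_info

__all__ = [
    "CIISeries",
    "mi_from_p",
    "p_from_mi",
    "expected_category_info",
    "floor_category_info",
    "ceiling_category_info",
    "cii_series",
    "cii_time_average",
    "compute_cii",
]


@dataclass
class CIISeries:
    """Cumulative categorical information with its references and the index.

    ``cii`` is clipped to [0, 2]; ``cii_raw`` keeps the unclipped values.
    Bins with a degenerate reference spread (denominator below 1e-9 bits)
    are NaN.
    """

    bin_ms: float
    cci: np.ndarray
    floor: np.ndarray
    expected: np.ndarray
    ceiling: np.ndarray
    cii: np.ndarray
    cii_raw: np.ndarray

    def times_ms(self) -> np.ndarray:
        return self.bin_ms * (1.0 + np.arange(self.cci.size))

    @property
    def excess_bits(self) -> np.ndarray:
        """Categorical information above the expected reference, in bits
        (the absolute-units companion of the index)."""
        return self.cci - self.expected


def _entropy(p: np.ndarray) -> float:
    p = p[p > 1e-300]
    return float(-(p * np.log2(p)).sum())


def mi_from_p(p: float, n: int) -> float:
    """Mutual information (bits) of a symmetric n-way confusion matrix.

    The joint matrix has ``p/n`` on the diagonal and ``(1-p)/(n(n-1))``
    elsewhere; both marginals are uniform, giving

        mi = log2 n - H2(p) - (1 - p) log2(n - 1).
    """
    if not (1.0 / n - 1e-12 <= p <= 1.0 + 1e-12):
        raise ValueError(f"p={p} outside [1/{n}, 1]")
    p = min(max(p, 1.0 / n), 1.0)
    h2 = 0.0
    if 0.0 < p < 1.0:
        h2 = -p * np.log2(p) - (1.0 - p) * np.log2(1.0 - p)
    tail = 0.0 if p == 1.0 or n == 1 else (1.0 - p) * np.log2(n - 1)
    return float(np.log2(n) - h2 - tail)


def p_from_mi(mi: float, n: int) -> float:
    """Invert :func:`mi_from_p` by root bracketing on [1/n, 1].

    Values outside [0, log2 n] (possible through Monte Carlo noise) are
    clipped with a warning.
    """
    top = np.log2(n)
    if mi < -1e-9 or mi > top + 1e-9:
        warnings.warn(f"mi={mi:.4g} outside [0, log2 {n}]; clipping")
    mi = min(max(mi, 0.0), top)
    if mi <= 0.0:
        return 1.0 / n
    if mi >= top:
        return 1.0
    return float(brentq(lambda p: mi_from_p(p, n) - mi, 1.0 / n, 1.0, xtol=1e-12))


def grouped_confusion_mi(p: float, category_sizes) -> float:
    """Category MI of the symmetric stimulus confusion matrix grouped by category."""
    sizes = np.asarray(category_sizes, dtype=int)
    n = int(sizes.sum())
    joint = np.full((n, n), (1.0 - p) / (n * (n - 1)) if n > 1 else 0.0)
    np.fill_diagonal(joint, p / n)
    edges = np.concatenate([[0], np.cumsum(sizes)])
    nc = sizes.size
    grouped = np.add.reduceat(np.add.reduceat(joint, edges[:-1], axis=0), edges[:-1], axis=1)
    h_row = _entropy(grouped.sum(axis=1))
    h_col = _entropy(grouped.sum(axis=0))
    h_tot = _entropy(grouped.ravel())
    return h_row + h_col - h_tot


def expected_category_info(mi_stim: float, category_sizes) -> float:
    """Expected categorical information given stimulus information (bits).

    Converts ``mi_stim`` to the equivalent correct-decoding probability,
    groups the implied confusion matrix by category, and returns
    ``H_row + H_col - H_tot`` of the grouped joint matrix.
    """
    sizes = np.asarray(category_sizes, dtype=int)
    n = int(sizes.sum())
    p = p_from_mi(mi_stim, n)
    return float(grouped_confusion_mi(p, sizes))


def expected_series(ci_stim: InfoSeries, category_sizes) -> np.ndarray:
    out = np.full(ci_stim.n_bins, np.nan)
    for b in range(ci_stim.n_bins):
        if np.isfinite(ci_stim.info[b]):
            out[b] = expected_category_info(max(ci_stim.info[b], 0.0), category_sizes)
    return out


def _random_grouping(rng, stimulus_ids, sizes) -> CategoryMap:
    perm = rng.permutation(len(stimulus_ids))
    mapping = {}
    start = 0
    for c, size in enumerate(sizes):
        for i in perm[start : start + size]:
            mapping[stimulus_ids[i]] = f"perm{c + 1}"
        start += size
    return CategoryMap({s: mapping[s] for s in stimulus_ids})


def floor_category_info(
    rates: BinnedRates,
    priors=None,
    mc: MCParams | None = None,
    cmap: CategoryMap | None = None,
    n_perm: int = 10,
    seed: int = 0,
    t_max: int | None = None,
) -> np.ndarray:
    """Floor reference: mean categorical cumulative information over random
    stimulus-to-category assignments that preserve the category sizes."""
    if cmap is None:
        raise ValueError("a category map is required (its sizes are preserved)")
    mc = mc or MCParams()
    sizes = list(cmap.sizes().values())
    rng = np.random.default_rng(seed)
    acc = np.zeros(rates.n_bins if t_max is None else t_max + 1)
    count = np.zeros_like(acc)
    for k in range(n_perm):
        grouping = _random_grouping(rng, rates.stimulus_ids, sizes)
        mc_k = MCParams(
            chunk=mc.chunk,
            se_stop=mc.se_stop,
            max_samples=mc.max_samples,
            se_abort=mc.se_abort,
            seed=(mc.seed + 7919 * (k + 1)) & 0x7FFFFFFF,
        )
        series = cumulative_info(rates, priors, grouping, mc_k, t_max=t_max)
        ok = np.isfinite(series.info)
        acc[ok] += series.info[ok]
        count[ok] += 1
    with np.errstate(invalid="ignore"):
        return acc / count


def ceiling_category_info(ci_stim: InfoSeries, n_c: int) -> np.ndarray:
    """Ceiling reference: stimulus cumulative information capped at log2(n_c)."""
    return np.minimum(ci_stim.info, np.log2(n_c))


def cii_series(cci, floor, expected, ceiling, bin_ms: float = 10.0) -> CIISeries:
    """Piecewise Categorical Information Index per bin.

    Degenerate denominators (< 1e-9 bits) give NaN; the index is clipped to
    [0, 2] (raw values are retained in ``cii_raw``).
    """
    cci = np.asarray(cci, dtype=float)
    floor = np.asarray(floor, dtype=float)
    expected = np.asarray(expected, dtype=float)
    ceiling = np.asarray(ceiling, dtype=float)
    raw = np.full(cci.shape, np.nan)
    lower = expected - floor
    upper = ceiling - expected
    # each branch needs its own reference spread to be positive; bins where
    # estimation noise inverts or collapses it have no meaningful index
    below = cci < expected
    ok_lo = below & (lower > 1e-9)
    ok_hi = ~below & (upper > 1e-9)
    inverted = (below & np.isfinite(lower) & (lower < -1e-9)) | (
        ~below & np.isfinite(upper) & (upper < -1e-9)
    )
    if np.any(inverted):
        warnings.warn("reference ordering violated at some bins; index undefined there")
    with np.errstate(invalid="ignore", divide="ignore"):
        raw[ok_lo] = (cci[ok_lo] - floor[ok_lo]) / lower[ok_lo]
        raw[ok_hi] = 1.0 + (cci[ok_hi] - expected[ok_hi]) / upper[ok_hi]
    raw[~np.isfinite(cci) | ~np.isfinite(expected)] = np.nan
    return CIISeries(
        bin_ms=bin_ms,
        cci=cci,
        floor=floor,
        expected=expected,
        ceiling=ceiling,
        cii=np.clip(raw, 0.0, 2.0),
        cii_raw=raw,
    )


def cii_time_average(series: CIISeries, t_start: float = 50.0, t_end: float = 300.0) -> float:
    """Mean of the defined CII values whose bin end times lie in (t_start, t_end]."""
    times = series.times_ms()
    window = (times > t_start) & (times <= t_end)
    vals = series.cii[window]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no defined CII values in the requested window")
    return float(vals.mean())


def compute_cii(
    rates: BinnedRates,
    cmap: CategoryMap,
    mc: MCParams | None = None,
    n_perm: int = 10,
    seed: int = 0,
    t_max: int | None = None,
    ci_stim: InfoSeries | None = None,
    cci: InfoSeries | None = None,
) -> CIISeries:
    """Full CII pipeline from binned Poisson means.

    Computes (or accepts precomputed) stimulus and categorical cumulative
    information, the three references, and the index.
    """
    mc = mc or MCParams()
    if ci_stim is None:
        ci_stim = cumulative_info(rates, None, None, mc, t_max=t_max)
    if cci is None:
        mc_cat = MCParams(mc.chunk, mc.se_stop, mc.max_samples, mc.se_abort, (mc.seed + 104729) & 0x7FFFFFFF)
        cci = cumulative_info(rates, None, cmap, mc_cat, t_max=t_max)
    sizes = list(cmap.sizes().values())
    floor = floor_category_info(rates, None, mc, cmap, n_perm=n_perm, seed=seed, t_max=t_max)
    expected = expected_series(ci_stim, sizes)
    ceiling = ceiling_category_info(ci_stim, cmap.n_categories)
    n = min(len(cci.info), len(floor), len(expected), len(ceiling))
    return cii_series(cci.info[:n], floor[:n], expected[:n], ceiling[:n], bin_ms=rates.bin_ms)
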