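"""Cumulative mutual information over growing sequences of analysis bins.

The cumulative information at bin *t* is

    CI_t = H(Y_t, ..., Y_0) - H(Y_t, ..., Y_0 | S).

Under the Poisson assumption the counts are independent across bins *given*
the stimulus, so the conditional term is the exact running sum of per-bin
conditional entropies.  The unconditional joint distribution is a mixture of
product distributions and is *not* independent across bins; its entropy is
estimated three ways:

* **Monte Carlo importance sampling** (the reference estimator): count
  vectors are drawn from the product of the per-bin marginal mixtures and
  the entropy is the likelihood-ratio-weighted average of ``-log2 p``,
  self-normalised by the mean weight.  Self-normalisation is essential in
  this many-bin regime: the weights have a heavy log-normal tail whose
  scale noise cancels in the ratio but wrecks the unnormalised mean.  The
  ratio's O(1/N) bias is removed by a delete-one-chunk jackknife, which
  also supplies the standard error.  Samples accumulate in chunks with a
  standard-error stopping rule; an estimate whose error stays above
  ``se_abort`` at the sample cap is flagged unreliable and no later bin is
  computed.
* **Markov-chain approximation**: the chain-rule decomposition conditioned
  on a bounded history (order 1-4).  It overestimates the joint entropy and
  therefore upper-bounds the cumulative information.
* **Exact running window**: full enumeration over a fixed number of recent
  bins; exact inside the window, it underestimates the full cumulative
  information.

All probabilities are evaluated in log space; the proposal is truncated at
``r_max`` exactly as the target, so importance weights are always finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .data import BinnedRates, CategoryMap, InfoSeries, Priors
from .instant import condition_tables, entropy_of_pmf

__all__ = [
    "MCParams",
    "conditional_cum_entropy",
    "mc_joint_entropy",
    "cumulative_info",
    "markov_joint_entropy",
    "exact_window_info",
    "enumerated_joint_entropy",
]

_LN2 = np.log(2.0)


@dataclass
class MCParams:
    """Monte Carlo sampling controls.

    chunk : samples drawn between convergence checks (default 100 000).
    se_stop : stop once the standard error falls below this (default 0.2 bits).
    max_samples : hard cap on samples per time point (default 5 000 000).
    se_abort : error above this at the cap flags the estimate unreliable
        (default 0.6 bits) and aborts later time points.
    min_chunks : chunks required before the stopping rule may fire (default
        4); the jackknife error of the ratio is meaningless from fewer.
    seed : base seed; each time point uses an independent stream derived
        from (seed, t_end).
    """

    chunk: int = 100_000
    se_stop: float = 0.2
    max_samples: int = 5_000_000
    se_abort: float = 0.6
    seed: int = 0
    min_chunks: int = 4

    def __post_init__(self) -> None:
        if not (0 < self.se_stop < self.se_abort):
            raise ValueError("require 0 < se_stop < se_abort")
        if self.chunk > self.max_samples:
            raise ValueError("chunk must not exceed max_samples")


def conditional_cum_entropy(
    rates: BinnedRates,
    priors: Priors | None = None,
    t_end: int | None = None,
    grouping: CategoryMap | None = None,
) -> float:
    """Exact conditional joint entropy H(Y_0..Y_t | S) in bits.

    Conditional independence across bins makes this the plain sum of the
    per-bin conditional entropies from bin 0 through ``t_end``.
    """
    w, pmf = condition_tables(rates, priors, grouping)
    if t_end is None:
        t_end = rates.n_bins - 1
    if not (0 <= t_end < rates.n_bins):
        raise ValueError("t_end out of range")
    per_bin = w @ entropy_of_pmf(pmf)  # (n_bins,)
    return float(per_bin[: t_end + 1].sum())


def _log_tables(w: np.ndarray, pmf: np.ndarray):
    logw = np.log(w)
    logpmf = np.log(np.maximum(pmf, 1e-300))
    marg = np.tensordot(w, pmf, axes=1)           # (B, R+1)
    marg = marg / marg.sum(axis=1, keepdims=True)  # renormalise truncation
    return logw, logpmf, marg


def _sample_log_terms(rng, n, logw, logpmf, marg, bins):
    """Draw *n* vectors from the product-of-marginals proposal.

    Returns per-sample (w * (-log2 p), w); the self-normalised ratio of
    their means estimates the joint entropy.
    """
    n_cond = logpmf.shape[0]
    n_bins = bins.size
    cum = np.cumsum(marg[bins], axis=1)
    u = rng.random((n, n_bins))
    y = np.empty((n, n_bins), dtype=np.intp)
    for j, b in enumerate(bins):
        y[:, j] = np.searchsorted(cum[j], u[:, j], side="right")
    np.clip(y, 0, logpmf.shape[2] - 1, out=y)

    logmarg = np.log(marg)
    logq = logmarg[bins[None, :], y].sum(axis=1)   # (n,)
    per_cond = np.empty((n_cond, n))
    for i in range(n_cond):
        per_cond[i] = logpmf[i][bins[None, :], y].sum(axis=1)
    logp = logsumexp(per_cond + logw[:, None], axis=0)  # natural log
    weight = np.exp(logp - logq)
    return weight * (-logp / _LN2), weight


def mc_joint_entropy(
    rates: BinnedRates,
    priors: Priors | None = None,
    t_end: int | None = None,
    mc: MCParams | None = None,
    grouping: CategoryMap | None = None,
):
    """Joint response entropy H(Y_0..Y_t) by Monte Carlo importance sampling.

    The per-chunk means of ``w * (-log2 p)`` and of ``w`` are combined into
    the self-normalised ratio estimate; a delete-one-chunk jackknife removes
    the ratio's O(1/N) bias and provides the standard error.  At least
    ``mc.min_chunks`` chunks are drawn before the stopping rule can fire.

    Returns
    -------
    (entropy_bits, se_bits, n_samples, reliable)
        ``reliable`` is False when the error still exceeds ``se_abort`` at
        the sample cap.
    """
    mc = mc or MCParams()
    w, pmf = condition_tables(rates, priors, grouping)
    if t_end is None:
        t_end = rates.n_bins - 1
    if not (0 <= t_end < rates.n_bins):
        raise ValueError("t_end out of range")
    bins = np.arange(t_end + 1)
    logw, logpmf, marg = _log_tables(w, pmf)
    rng = np.random.default_rng([int(mc.seed) & 0x7FFFFFFF, int(t_end)])

    num, den = [], []
    n_total = 0
    while True:
        n = min(mc.chunk, mc.max_samples - n_total)
        terms, weights = _sample_log_terms(rng, n, logw, logpmf, marg, bins)
        n_total += n
        num.append(terms.mean())
        den.append(weights.mean())
        if len(num) >= 2:
            est, se = _jackknife_ratio(np.asarray(num), np.asarray(den))
            if (se < mc.se_stop and len(num) >= mc.min_chunks) or n_total >= mc.max_samples:
                break
        elif n_total >= mc.max_samples:
            est, se = float(num[0] / den[0]), float("inf")
            break
    reliable = se <= mc.se_abort
    return float(est), float(se), n_total, reliable


def _jackknife_ratio(num: np.ndarray, den: np.ndarray):
    """Delete-one-chunk jackknife of the ratio mean(num)/mean(den)."""
    k = num.size
    theta = num.mean() / den.mean()
    s_num, s_den = num.sum(), den.sum()
    jk = (s_num - num) / (s_den - den)
    est = k * theta - (k - 1) * jk.mean()
    se = np.sqrt((k - 1) / k * ((jk - jk.mean()) ** 2).sum())
    return float(est), float(se)


def cumulative_info(
    rates: BinnedRates,
    priors: Priors | None = None,
    grouping: CategoryMap | None = None,
    mc: MCParams | None = None,
    t_max: int | None = None,
) -> InfoSeries:
    """Cumulative mutual information per bin via the Monte Carlo estimator.

    Once a time point is flagged unreliable (error above ``se_abort`` at the
    sample cap) the series is aborted: later bins are NaN and ``abort_bin``
    records the first unusable bin.
    """
    mc = mc or MCParams()
    n_bins = rates.n_bins if t_max is None else min(rates.n_bins, t_max + 1)
    w, pmf = condition_tables(rates, priors, grouping)
    per_bin_cond = w @ entropy_of_pmf(pmf)
    info = np.full(n_bins, np.nan)
    se = np.full(n_bins, np.nan)
    abort_bin = None
    for t in range(n_bins):
        h, h_se, _, reliable = mc_joint_entropy(rates, priors, t, mc, grouping)
        if not reliable:
            abort_bin = t
            break
        info[t] = h - per_bin_cond[: t + 1].sum()
        se[t] = h_se
    kind = "cumulative_cat" if grouping is not None else "cumulative_stim"
    return InfoSeries(bin_ms=rates.bin_ms, info=info, se=se, kind=kind, abort_bin=abort_bin)


def _enumerated_mixture(w, pmf, bins):
    """Joint mixture pmf over the given bins, shape (R+1,) * len(bins)."""
    n_cond = pmf.shape[0]
    mix = None
    for i in range(n_cond):
        joint = np.array(1.0)
        for b in bins:
            joint = np.multiply.outer(joint, pmf[i, b])
        contrib = w[i] * joint
        mix = contrib if mix is None else mix + contrib
    return mix


def enumerated_joint_entropy(
    rates: BinnedRates,
    priors: Priors | None = None,
    t_end: int | None = None,
    grouping: CategoryMap | None = None,
    budget: float = 2e8,
) -> float:
    """Exact joint response entropy by full enumeration (small cases only)."""
    w, pmf = condition_tables(rates, priors, grouping)
    if t_end is None:
        t_end = rates.n_bins - 1
    bins = np.arange(t_end + 1)
    if (pmf.shape[2]) ** bins.size > budget:
        raise ValueError("enumeration budget exceeded; lower r_max or t_end")
    mix = _enumerated_mixture(w, pmf, bins)
    return float(entropy_of_pmf(mix.ravel()))


def markov_joint_entropy(
    rates: BinnedRates,
    priors: Priors | None = None,
    t_end: int | None = None,
    order: int = 1,
    grouping: CategoryMap | None = None,
    budget: float = 2e8,
) -> float:
    """Joint response entropy under a bounded-history Markov approximation.

    Decomposes ``H(Y_0..Y_t)`` as ``H(Y_0..Y_m) + sum_b H(Y_b | Y_{b-m}..Y_{b-1})``
    with history length ``m = order``; each term is evaluated exactly from
    the enumerated mixture over ``order + 1`` consecutive bins.  Because the
    true dependence extends beyond the history, the result is an upper bound
    on the joint entropy (equality at full order).
    """
    w, pmf = condition_tables(rates, priors, grouping)
    if t_end is None:
        t_end = rates.n_bins - 1
    if not (1 <= order <= t_end + 1):
        raise ValueError("order must be in 1..t_end+1")
    r1 = pmf.shape[2]
    if r1 ** (order + 1) > budget:
        raise ValueError(
            f"enumeration of ({r1})^{order + 1} outcomes exceeds budget; "
            "lower r_max or the order"
        )
    m = min(order, t_end)
    lead = _enumerated_mixture(w, pmf, np.arange(m + 1))
    total = float(entropy_of_pmf(lead.ravel()))
    for b in range(m + 1, t_end + 1):
        window = np.arange(b - order, b + 1)
        joint = _enumerated_mixture(w, pmf, window)
        hist = joint.sum(axis=-1)
        # H(Y_b | history) = H(window joint) - H(history joint)
        total += float(entropy_of_pmf(joint.ravel()) - entropy_of_pmf(hist.ravel()))
    return total


def exact_window_info(
    rates: BinnedRates,
    priors: Priors | None = None,
    grouping: CategoryMap | None = None,
    n_bins: int = 4,
    budget: float = 2e8,
) -> InfoSeries:
    """Exact mutual information in a running window of ``n_bins`` bins.

    At bin *t* the information is computed by full enumeration over bins
    ``t - n_bins + 1 .. t`` (fewer at the start).  With ``n_bins = 1`` this
    reduces to the instantaneous information.  It lower-bounds the full
    cumulative information, which also integrates across windows.
    """
    w, pmf = condition_tables(rates, priors, grouping)
    r1 = pmf.shape[2]
    if r1 ** n_bins > budget:
        raise ValueError("enumeration budget exceeded; lower r_max or n_bins")
    per_bin_cond = w @ entropy_of_pmf(pmf)
    out = np.empty(rates.n_bins)
    for t in range(rates.n_bins):
        lo = max(0, t - n_bins + 1)
        window = np.arange(lo, t + 1)
        mix = _enumerated_mixture(w, pmf, window)
        h_resp = float(entropy_of_pmf(mix.ravel()))
        out[t] = h_resp - per_bin_cond[lo : t + 1].sum()
    kind = "cumulative_cat" if grouping is not None else "cumulative_stim"
    return InfoSeries(bin_ms=rates.bin_ms, info=out, kind=kind)
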