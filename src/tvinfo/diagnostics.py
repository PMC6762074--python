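"""Checks of the modelling assumptions behind the information estimates.

Four families of diagnostics:

* a per-(stimulus, bin) likelihood bootstrap test of the Poisson count
  assumption, corrected for multiplicity by Benjamini-Hochberg FDR;
* Fano factors (across-trial variance/mean of counts) which equal 1 for
  Poisson counts;
* noise correlations (correlation of count residuals across consecutive
  bins, same stimulus) and stimulus correlations (correlation of the
  trial-averaged response across consecutive bins), probing the
  conditional-independence assumption;
* temporal-resolution checks: the fraction of spike-train coherence
  information below the analysis cut-off frequency, and the cumulative
  power fraction of the estimated rates below that frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats
from statsmodels.stats.multitest import multipletests

from .data import BinnedCounts, BinnedRates, SpikeTrainSet
from .rates import RateEnsemble

__all__ = [
    "DiagnosticsReport",
    "poisson_gof",
    "fano_series",
    "noise_correlation",
    "stimulus_correlation",
    "coherence_info_fraction",
    "power_fraction",
    "coherence_information",
]


@dataclass
class DiagnosticsReport:
    gof_rejected_fraction: float
    fano_mean: float
    fano_per_bin: np.ndarray
    noise_corr_mean: float
    noise_corr_values: np.ndarray
    stim_corr_mean: float
    coherence_fraction: float
    power_fraction: float


def _delete_one_ll(counts_row: np.ndarray, floor: float) -> float:
    m = counts_row.size
    total = counts_row.sum()
    mu = (total - counts_row) / (m - 1)
    mu = np.maximum(mu, floor)
    return float(stats.poisson.logpmf(counts_row, mu).sum())


def poisson_gof(
    counts: BinnedCounts,
    mu: BinnedRates,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
):
    """Likelihood bootstrap test of Poisson counts, per (stimulus, bin) cell.

    The observed statistic is the log likelihood of the M trial counts under
    per-trial delete-one Poisson means; the null distribution draws
    ``n_boot`` sets of M counts from a Poisson with the KDE-estimated bin
    mean and recomputes the same statistic.  Two-tailed p-values (doubling
    convention, (r+1)/(n+1) continuity correction) are corrected across all
    cells of the neuron by Benjamini-Hochberg.

    Cells with all-zero observed counts have no defined statistic and are
    excluded from the rejected fraction.

    Returns
    -------
    pvals : ndarray (n_stimuli, n_bins), NaN for excluded cells
    rejected_fraction : float
    """
    rng = np.random.default_rng(seed)
    n_s, n_bins = mu.n_stimuli, counts.n_bins
    pvals = np.full((n_s, n_bins), np.nan)
    for s in range(n_s):
        c = counts.counts[s]  # (M, n_bins)
        m = c.shape[0]
        floor = 0.5 / (m - 1)  # zero-count delete-one means are floored
        for b in range(n_bins):
            row = c[:, b]
            if row.sum() == 0:
                continue
            ll_obs = _delete_one_ll(row, floor)
            draws = rng.poisson(mu.mu[s, b], size=(n_boot, m))
            totals = draws.sum(axis=1, keepdims=True)
            mu_del = np.maximum((totals - draws) / (m - 1), floor)
            ll_null = stats.poisson.logpmf(draws, mu_del).sum(axis=1)
            r_low = int((ll_null <= ll_obs).sum())
            r_high = int((ll_null >= ll_obs).sum())
            p = 2.0 * min((r_low + 1) / (n_boot + 1), (r_high + 1) / (n_boot + 1))
            pvals[s, b] = min(p, 1.0)
    flat = pvals.ravel()
    valid = np.isfinite(flat)
    if valid.sum() == 0:
        return pvals, float("nan")
    rejected = multipletests(flat[valid], alpha=alpha, method="fdr_bh")[0]
    return pvals, float(rejected.mean())


def fano_series(counts: BinnedCounts, ddof: int = 1):
    """Per-bin Fano factor (variance/mean of counts across trials).

    Computed per stimulus, then averaged across stimuli; a stimulus is
    excluded at bins where its mean count is zero.  Returns
    (fano_per_bin, fano_mean).
    """
    n_bins = counts.n_bins
    per_stim = np.full((counts.n_stimuli, n_bins), np.nan)
    for s, c in enumerate(counts.counts):
        mean = c.mean(axis=0)
        var = c.var(axis=0, ddof=ddof)
        ok = mean > 0
        per_stim[s, ok] = var[ok] / mean[ok]
    with np.errstate(invalid="ignore"):
        fano_bin = np.nanmean(per_stim, axis=0)
    return fano_bin, float(np.nanmean(fano_bin))


def noise_correlation(counts: BinnedCounts):
    """Mean Pearson correlation of count residuals in consecutive bins.

    For each stimulus and each consecutive bin pair, the counts are
    centred per bin across trials and correlated across trials; pairs with
    zero variance are skipped.  Returns (mean, values).
    """
    values = []
    for c in counts.counts:
        if c.shape[0] < 3:
            raise ValueError("noise correlation needs at least 3 trials")
        resid = c - c.mean(axis=0, keepdims=True)
        for b in range(c.shape[1] - 1):
            x, y = resid[:, b], resid[:, b + 1]
            if x.std() == 0 or y.std() == 0:
                continue
            values.append(float(np.corrcoef(x, y)[0, 1]))
    values = np.asarray(values)
    mean = float(values.mean()) if values.size else float("nan")
    return mean, values


def stimulus_correlation(counts) -> float:
    """Mean correlation across stimuli of trial-averaged counts in
    consecutive bins; measures how strongly the stimulus drives the shared
    temporal structure of the response."""
    if isinstance(counts, BinnedCounts):
        mean_counts = np.stack([c.mean(axis=0) for c in counts.counts])
    elif isinstance(counts, BinnedRates):
        mean_counts = counts.mu
    else:
        mean_counts = np.asarray(counts, dtype=float)
    if mean_counts.shape[0] < 2:
        raise ValueError("need at least 2 stimuli")
    vals = []
    for b in range(mean_counts.shape[1] - 1):
        x, y = mean_counts[:, b], mean_counts[:, b + 1]
        if x.std() == 0 or y.std() == 0:
            continue
        vals.append(float(np.corrcoef(x, y)[0, 1]))
    return float(np.mean(vals)) if vals else float("nan")


def _psth(trials, window_ms: float, idx) -> np.ndarray:
    n = int(round(window_ms))
    out = np.zeros(n)
    for j in idx:
        t = trials[j]
        if len(t):
            out += np.histogram(t, bins=n, range=(0, window_ms))[0]
    return out / len(idx)


def _welch_segments(x: np.ndarray, nperseg: int):
    step = nperseg // 2
    n_seg = (x.size - nperseg) // step + 1
    win = signal.windows.hann(nperseg)
    segs = np.stack([x[k * step : k * step + nperseg] * win for k in range(n_seg)])
    return np.fft.rfft(segs, axis=1)


def _coherence_with_floor(x: np.ndarray, y: np.ndarray, fs: float, nperseg: int, n_null: int = 4):
    """Welch magnitude-squared coherence plus segment-mismatch null floors.

    Each floor re-pairs x segments with distant y segments, preserving both
    marginal spectra while destroying the alignment, and measures the purely
    statistical coherence of the estimator.
    """
    fx = _welch_segments(x, nperseg)
    fy = _welch_segments(y, nperseg)
    n_seg = fx.shape[0]
    sxx = (fx * fx.conj()).real.mean(axis=0)
    syy = (fy * fy.conj()).real.mean(axis=0)
    denom = np.maximum(sxx * syy, 1e-300)
    g2 = np.abs((fx * fy.conj()).mean(axis=0)) ** 2 / denom
    shifts = np.linspace(2, max(n_seg - 2, 3), n_null).astype(int)
    floors = np.stack(
        [np.abs((fx * np.roll(fy, s, axis=0).conj()).mean(axis=0)) ** 2 / denom for s in shifts]
    )
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    return freqs, g2, floors


def coherence_information(gamma2: np.ndarray, freqs: np.ndarray, f_hi: float) -> float:
    """Information rate (bits/s): minus the integral of log2(1 - coherence)
    over frequencies up to ``f_hi``."""
    keep = freqs <= f_hi
    vals = -np.log2(np.maximum(1.0 - gamma2[keep], 1e-12))
    return float(np.trapezoid(vals, freqs[keep]))


def coherence_info_fraction(
    spikes: SpikeTrainSet,
    f_cut: float = 50.0,
    f_max: float = 500.0,
    n_split: int = 10,
    seed: int = 0,
    nperseg: int = 200,
):
    """Fraction of spike-train coherence information below ``f_cut``.

    Trials of every stimulus are split into random halves; the coherence of
    the two half-PSTHs (Welch, Hann windows of ``nperseg`` ms, 50% overlap)
    is averaged over ``n_split`` halvings and corrected to the expected
    coherence between a single spike train and the true mean rate:

        gamma_AR^2 = 1 / (1 + (M/2) * (sqrt(1/gamma_half^2) - 1)),

    with M the trial count.  The returned fraction is
    ``I_AR(0..f_cut) / I_AR(0..f_max)``; NaN when the neuron never spikes.
    """
    if all(rec.spike_count() == 0 for rec in spikes.stimuli):
        return float("nan")
    if min(rec.n_trials for rec in spikes.stimuli) < 4:
        raise ValueError("coherence needs at least 4 trials per stimulus")
    rng = np.random.default_rng(seed)
    fs = 1000.0
    g_acc = floor_acc = None
    for _ in range(n_split):
        xs, ys = [], []
        for rec in spikes.stimuli:
            order = rng.permutation(rec.n_trials)
            half = rec.n_trials // 2
            xs.append(_psth(rec.trials, spikes.window_ms, order[:half]))
            ys.append(_psth(rec.trials, spikes.window_ms, order[half : 2 * half]))
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        freqs, g2, floors = _coherence_with_floor(x, y, fs, nperseg)
        g_acc = g2 if g_acc is None else g_acc + g2
        floor_acc = floors if floor_acc is None else floor_acc + floors
    g_mean = g_acc / n_split
    floors = floor_acc / n_split
    floor_mean = floors.mean(axis=0)
    # gate at the pooled upper quantile of the null floors: only frequencies
    # whose coherence clears what segment-mismatched pairings can produce
    # by chance are kept, then the mean floor is subtracted
    gate = np.percentile(floors, 99.0)
    significant = g_mean > np.maximum(gate, floor_mean)
    g_half = np.where(significant, (g_mean - floor_mean) / (1.0 - floor_mean), 0.0)
    g_half = np.clip(g_half, 0.0, 1.0)
    m = int(np.round(np.mean([rec.n_trials for rec in spikes.stimuli])))
    with np.errstate(divide="ignore", invalid="ignore"):
        gamma_ar = 1.0 / (1.0 + (m / 2.0) * (np.sqrt(1.0 / np.maximum(g_half, 1e-12)) - 1.0))
    gamma_ar = np.clip(gamma_ar, 0.0, 1.0 - 1e-12)  # weak-signal cells clip at 0
    i_cut = coherence_information(gamma_ar, freqs, f_cut)
    i_all = coherence_information(gamma_ar, freqs, f_max)
    if i_all <= 0:
        return float("nan")
    return float(i_cut / i_all)


def power_fraction(rates: RateEnsemble, f_cut: float = 50.0, nperseg: int = 200) -> float:
    """Cumulative normalised rate power below ``f_cut``, averaged over stimuli.

    Welch periodogram with 200 ms Hann windows, 50% overlap, at the rate
    sampling frequency.
    """
    fracs = []
    for r in rates.rate:
        freqs, pxx = signal.welch(
            r, fs=rates.fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2, detrend=False
        )
        cum = np.cumsum(pxx)
        if cum[-1] <= 0:
            continue
        fracs.append(float(np.interp(f_cut, freqs, cum / cum[-1])))
    return float(np.mean(fracs)) if fracs else float("nan")
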