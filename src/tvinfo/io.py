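"""Readers and writers for the package's tabular text formats.

Spike tables are long-format delimited text (comma or tab, sniffed) with
header columns ``neuron_id, stimulus_id, category, trial, spike_time_ms`` and
one spike per row.  A trial that produced no spikes is declared with a single
row whose ``spike_time_ms`` field is empty, so that silent trials are still
counted.  Trial indices are remapped to 0..M-1 per stimulus.
"""

from __future__ import annotations

import csv

import numpy as np
import pandas as pd

from .data import InfoSeries, SpikeTrainSet, StimulusRecord

__all__ = [
    "read_spike_table",
    "write_spike_table",
    "write_info_series",
    "read_info_series",
]

_COLUMNS = ["neuron_id", "stimulus_id", "category", "trial", "spike_time_ms"]


def _sniff_delimiter(path) -> str:
    with open(path, "r", newline="") as fh:
        sample = fh.read(4096)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_spike_table(path, window_ms: float = 600.0) -> SpikeTrainSet:
    """Read a long-format spike table into a validated :class:`SpikeTrainSet`.

    Raises
    ------
    ValueError
        On malformed rows (naming the line), spike times outside
        ``[0, window_ms)``, or stimuli with fewer than two trials.
    """
    delim = _sniff_delimiter(path)
    try:
        df = pd.read_csv(path, sep=delim, dtype=str)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed spike table {path}: {exc}") from exc
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spike table {path} lacks column(s) {missing}")

    neuron_ids = df["neuron_id"].dropna().unique()
    if len(neuron_ids) != 1:
        raise ValueError(f"spike table {path} must contain exactly one neuron_id")

    stimuli = []
    for (stim_id, category), grp in df.groupby(["stimulus_id", "category"], sort=False):
        trials: dict = {}
        for row in grp.itertuples():
            line = row.Index + 2  # header is line 1
            try:
                trial = int(row.trial)
            except (TypeError, ValueError):
                raise ValueError(f"line {line}: trial index {row.trial!r} is not an integer")
            times = trials.setdefault(trial, [])
            raw = row.spike_time_ms
            if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
                continue  # empty-time row: declares the trial, no spike
            try:
                t = float(raw)
            except ValueError:
                raise ValueError(f"line {line}: spike_time_ms {raw!r} is not a number")
            if not (0.0 <= t < window_ms):
                raise ValueError(
                    f"line {line}: spike time {t} ms outside [0, {window_ms}) for "
                    f"stimulus {stim_id!r}"
                )
            times.append(t)
        trial_list = [np.sort(np.asarray(trials[k], dtype=float)) for k in sorted(trials)]
        stimuli.append(StimulusRecord(str(stim_id), str(category), trial_list))

    return SpikeTrainSet(neuron_id=str(neuron_ids[0]), window_ms=window_ms, stimuli=stimuli)


def write_spike_table(spikes: SpikeTrainSet, path, sep: str = ",") -> None:
    """Write *spikes* in the long format understood by :func:`read_spike_table`."""
    rows = []
    for rec in spikes.stimuli:
        for j, trial in enumerate(rec.trials):
            if len(trial) == 0:
                rows.append((spikes.neuron_id, rec.stimulus_id, rec.category, j, ""))
            for t in trial:
                rows.append((spikes.neuron_id, rec.stimulus_id, rec.category, j, repr(float(t))))
    df = pd.DataFrame(rows, columns=_COLUMNS)
    df.to_csv(path, sep=sep, index=False)


def write_info_series(series: InfoSeries, path) -> None:
    """Write an information series as a TSV with one row per analysis bin.

    Columns are ``time_ms`` (bin end), ``info_bits``, ``se_bits`` and
    ``significant`` (the 3x-standard-error rule).  Bins at or after an
    estimator abort carry empty value cells.
    """
    times = series.times_ms()
    abort = series.abort_bin if series.abort_bin is not None else series.n_bins
    with open(path, "w") as fh:
        fh.write("time_ms\tinfo_bits\tse_bits\tsignificant\n")
        for b in range(series.n_bins):
            if b >= abort:
                fh.write(f"{times[b]:.12g}\t\t\t\n")
                continue
            info = series.info[b]
            if series.se is not None and np.isfinite(series.se[b]):
                se = series.se[b]
                sig = "1" if info > 3.0 * se else "0"
                fh.write(f"{times[b]:.12g}\t{info:.12g}\t{se:.12g}\t{sig}\n")
            else:
                fh.write(f"{times[b]:.12g}\t{info:.12g}\t\t\n")


def read_info_series(path, kind: str = "instantaneous_stim") -> InfoSeries:
    """Read a TSV produced by :func:`write_info_series`."""
    df = pd.read_csv(path, sep="\t")
    times = df["time_ms"].to_numpy(dtype=float)
    if len(times) > 1:
        bin_ms = float(times[1] - times[0])
    else:
        bin_ms = float(times[0])
    info = df["info_bits"].to_numpy(dtype=float)
    se = df["se_bits"].to_numpy(dtype=float) if df["se_bits"].notna().any() else None
    nan = np.flatnonzero(~np.isfinite(info))
    abort_bin = int(nan[0]) if nan.size else None
    return InfoSeries(bin_ms=bin_ms, info=info, se=se, kind=kind, abort_bin=abort_bin)


def bin_counts(spikes: SpikeTrainSet, bin_ms: float = 10.0):
    """Count spikes of every trial in half-open bins of width *bin_ms*.

    *bin_ms* must divide the response window; 600 ms at the default 10 ms
    gives 60 bins.  Binning conserves each trial's total spike count.
    """
    from .data import BinnedCounts

    n_bins_f = spikes.window_ms / bin_ms
    n_bins = int(round(n_bins_f))
    if abs(n_bins_f - n_bins) > 1e-9 or n_bins < 1:
        raise ValueError(f"bin_ms={bin_ms} does not divide window_ms={spikes.window_ms}")
    edges = bin_ms * np.arange(n_bins + 1)
    counts = []
    for rec in spikes.stimuli:
        c = np.zeros((rec.n_trials, n_bins), dtype=np.int64)
        for j, trial in enumerate(rec.trials):
            if len(trial):
                c[j] = np.histogram(trial, bins=edges)[0]
        counts.append(c)
    return BinnedCounts(bin_ms=bin_ms, counts=counts, stimulus_ids=spikes.stimulus_ids)
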