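"""End-to-end analysis of one neuron: rates -> information -> CII -> fits.

The pipeline mirrors how the estimators are meant to be combined: adaptive
KDE rates with jackknife replicates, instantaneous and cumulative
information for stimuli and categories (jackknife bias corrected, bootstrap
errors for the instantaneous series), the Categorical Information Index,
exponential fits of the cumulative curves, and the assumption diagnostics.
Every stochastic stage derives its stream from the single run seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .categorical import compute_cii
from .cumulative import MCParams, cumulative_info
from .data import SpikeTrainSet
from .diagnostics import (
    coherence_info_fraction,
    fano_series,
    noise_correlation,
    poisson_gof,
    power_fraction,
    stimulus_correlation,
)
from .fits import fit_exponential
from .instant import instantaneous_info, stimulus_priors
from .io import bin_counts, write_info_series
from .rates import estimate_rates, integrate_to_bins
from .uncertainty import jackknife_corrected_series, significance_mask

__all__ = ["RunConfig", "run_pipeline"]


@dataclasses.dataclass
class RunConfig:
    """All pipeline parameters, serialisable to a flat key=value file."""

    bin_ms: float = 10.0
    r_max: int = 20
    prior_scheme: str = "equal_stimulus"
    mc_chunk: int = 100_000
    mc_se_stop: float = 0.2
    mc_max_samples: int = 5_000_000
    mc_se_abort: float = 0.6
    nb_boot: int = 20
    n_perm: int = 10
    f_cut: float = 50.0
    gof_n_boot: int = 1000
    gof_alpha: float = 0.05
    seed: int = 0
    bias_correct: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.mc_se_stop < self.mc_se_abort):
            raise ValueError("require 0 < mc_se_stop < mc_se_abort")

    def mc_params(self, offset: int = 0) -> MCParams:
        return MCParams(
            chunk=self.mc_chunk,
            se_stop=self.mc_se_stop,
            max_samples=self.mc_max_samples,
            se_abort=self.mc_se_abort,
            seed=(self.seed + offset) & 0x7FFFFFFF,
        )

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        known = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, raw = line.partition("=")
                key, raw = key.strip(), raw.strip()
                if key not in known:
                    raise ValueError(f"unknown config key {key!r}")
                if key in ("prior_scheme",):
                    kwargs[key] = raw
                elif key in ("bias_correct",):
                    kwargs[key] = raw.lower() in ("1", "true", "yes")
                elif key in ("r_max", "mc_chunk", "mc_max_samples", "nb_boot", "n_perm", "gof_n_boot", "seed"):
                    kwargs[key] = int(raw)
                else:
                    kwargs[key] = float(raw)
        return cls(**kwargs)


def run_pipeline(config: RunConfig, spikes: SpikeTrainSet, out_dir, log=print) -> dict:
    """Run every analysis stage on one neuron; writes TSV/JSON to *out_dir*.

    Returns a summary dict (also written as ``summary.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_file(out / "config.txt")
    summary: dict = {"neuron_id": spikes.neuron_id}

    log("stage: rate estimation (adaptive KDE + jackknife)")
    ens = estimate_rates(spikes, jackknife=True)
    rates = integrate_to_bins(ens, bin_ms=config.bin_ms, r_max=config.r_max)
    cmap = spikes.category_map()
    priors = stimulus_priors(cmap, config.prior_scheme)

    log("stage: instantaneous information")
    inst_stim = instantaneous_info(rates, priors)
    inst_cat = instantaneous_info(rates, priors=None, grouping=cmap)
    if config.bias_correct:
        est_stim = lambda r: instantaneous_info(r, priors).info
        est_cat = lambda r: instantaneous_info(r, grouping=cmap).info
        if config.nb_boot >= 2:
            from .uncertainty import bootstrap_corrected_series

            inst_stim.info, inst_stim.se = bootstrap_corrected_series(
                spikes, est_stim, nb_boot=config.nb_boot, seed=config.seed + 5,
                bin_ms=config.bin_ms, r_max=config.r_max,
            )
            inst_cat.info, inst_cat.se = bootstrap_corrected_series(
                spikes, est_cat, nb_boot=config.nb_boot, seed=config.seed + 6,
                bin_ms=config.bin_ms, r_max=config.r_max,
            )
        else:
            inst_stim.info = jackknife_corrected_series(rates, est_stim)
            inst_cat.info = jackknife_corrected_series(rates, est_cat)
    write_info_series(inst_stim, out / "instant_stim.tsv")
    write_info_series(inst_cat, out / "instant_cat.tsv")

    log("stage: cumulative information (Monte Carlo)")
    ci_stim = cumulative_info(rates, priors, None, config.mc_params(1))
    ci_cat = cumulative_info(rates, None, cmap, config.mc_params(2))
    write_info_series(ci_stim, out / "cumulative_stim.tsv")
    write_info_series(ci_cat, out / "cumulative_cat.tsv")
    for name, series in (("stim", ci_stim), ("cat", ci_cat)):
        if series.abort_bin is not None:
            log(f"cumulative {name}: aborted at bin {series.abort_bin} (unreliable MC error)")
            summary[f"abort_bin_{name}"] = series.abort_bin

    mask, any_sig = significance_mask(ci_stim)
    summary["any_significant_stim"] = any_sig

    if cmap.n_categories > 1 and cmap.n_categories < cmap.n_stimuli:
        log("stage: categorical information index")
        cii = compute_cii(
            rates, cmap, config.mc_params(3), n_perm=config.n_perm, seed=config.seed,
            ci_stim=ci_stim, cci=ci_cat,
        )
        _write_cii(cii, out / "cii.tsv")
        finite = np.isfinite(cii.cii)
        summary["cii_time_average"] = (
            float(np.nanmean(cii.cii[finite])) if finite.any() else None
        )

    log("stage: exponential fits")
    for name, series, i_max in (
        ("stim", ci_stim, np.log2(cmap.n_stimuli)),
        ("cat", ci_cat, np.log2(max(cmap.n_categories, 2))),
    ):
        try:
            if any_sig:
                fit = fit_exponential(series, i_max=i_max)
                summary[f"fit_{name}"] = dataclasses.asdict(fit)
        except (ValueError, RuntimeError) as exc:
            log(f"fit {name}: {exc}")

    log("stage: diagnostics")
    counts = bin_counts(spikes, bin_ms=config.bin_ms)
    _, gof_frac = poisson_gof(counts, rates, n_boot=config.gof_n_boot, alpha=config.gof_alpha, seed=config.seed + 11)
    fano_bin, fano_mean = fano_series(counts)
    noise_mean, _ = noise_correlation(counts)
    summary.update(
        gof_rejected_fraction=gof_frac,
        fano_mean=fano_mean,
        noise_corr_mean=noise_mean,
        stim_corr_mean=stimulus_correlation(counts),
        power_fraction=power_fraction(ens, f_cut=config.f_cut),
    )
    try:
        summary["coherence_fraction"] = coherence_info_fraction(
            spikes, f_cut=config.f_cut, seed=config.seed + 13
        )
    except ValueError as exc:
        log(f"coherence: {exc}")

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary


def _write_cii(cii, path) -> None:
    times = cii.times_ms()
    with open(path, "w") as fh:
        fh.write("time_ms\tcci_bits\tfloor_bits\texpected_bits\tceiling_bits\tcii\n")
        for b in range(cii.cci.size):
            vals = [times[b], cii.cci[b], cii.floor[b], cii.expected[b], cii.ceiling[b], cii.cii[b]]
            fh.write("\t".join("" if not np.isfinite(v) else f"{v:.12g}" for v in vals) + "\n")
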