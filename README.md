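# tvinfo — time-varying information in spike trains

`tvinfo` estimates how much a single neuron's spike train tells an observer
about which stimulus was presented — and about which *category* the stimulus
belongs to — as a function of time after stimulus onset.  It was built for
trial-based sensory-neuroscience experiments (its motivating system is the
avian auditory cortex processing communication calls), where a modest number
of trials (~10) per stimulus must support information estimates over a large
stimulus set.

## The model

Spike counts `y_t` in successive analysis bins (default 10 ms over a 600 ms
response window) are modelled as an inhomogeneous Poisson process: given
stimulus `s_i`, the count in bin *t* is Poisson with mean `mu_si(t)`, the
integral of the time-varying firing rate.  Rates are estimated from pooled
spike times with an adaptive-bandwidth Gaussian kernel density estimator.
Two information quantities follow:

* **instantaneous information**  `I_t = H(Y_t) − H(Y_t | S)`, the mutual
  information between the stimulus and the count in one bin, evaluated with
  closed-form Poisson entropies (count sums truncated at `R_max = 20`);
* **cumulative information**  `CI_t = H(Y_t,…,Y_0) − H(Y_t,…,Y_0 | S)`.
  The conditional term is an exact running sum (counts are independent
  across bins given the stimulus).  The joint response entropy is estimated
  by Monte Carlo importance sampling from the product of the per-bin
  marginal mixtures (self-normalised, chunk-jackknife bias corrected, with
  a standard-error stopping rule), bracketed by an exact running-window
  lower bound and a Markov-chain upper bound.

Category information replaces the stimulus-conditional distributions by
within-category mixtures.  The **Categorical Information Index (CII)**
locates the categorical cumulative information between a random-grouping
floor (0), the value expected from the stimulus information alone (1), and
a full-invariance ceiling (2).  Cumulative curves are summarised by a
delayed exponential `CI_mod(t) = k·I_max·(1 − e^{−(t−dt)/τ})` and the
relative value at 300 ms, `k300`.  Bias from limited trials is removed by
jackknifing the rate estimates; errors come from bootstrapping the
pipeline.  Diagnostics check the Poisson assumptions (likelihood bootstrap
with Benjamini–Hochberg FDR, Fano factors, noise correlations) and the
10-ms temporal resolution (coherence information and rate power below
50 Hz).

## A worked example

```python
from tvinfo import MCParams, cumulative_info, instantaneous_info, make_model_neuron
from tvinfo.validation import true_binned_rates

spec = make_model_neuron("onset")        # same burst at 4 latencies
rates = true_binned_rates(spec)          # per-bin Poisson means
inst = instantaneous_info(rates)
ci = cumulative_info(rates, mc=MCParams(seed=0, min_chunks=8), t_max=29)
print(f"peak instantaneous: {inst.info.max():.3f} bits")
print(f"cumulative at 300 ms: {ci.info[29]:.3f} ± {ci.se[29]:.3f} bits")
```

prints

```
peak instantaneous: 0.200 bits
cumulative at 300 ms: 1.823 ± 0.194 bits
```

No single bin discriminates the four stimuli well (0.20 bits out of 2),
but integrating across bins the neuron approaches the 2-bit ceiling: by
300 ms most of the latency code has been read out, and by 600 ms the
cumulative information saturates near 2 bits
(`tvinfo.validation.onset_cumulative_info`).  The `examples/` scripts walk
through rate recovery, both information estimators, the CII and the full
pipeline; the `tvinfo` command exposes the same stages as subcommands
(`simulate`, `rates`, `info`, `cii`, `fit`, `diagnose`, `run`).

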