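# Methods

## Model and scope

`tvinfo` treats a neuron's response to stimulus `s_i` as an inhomogeneous
Poisson process: the spike count `y_t` in an analysis bin of width `Δ`
(default 10 ms) is Poisson with mean `mu_si(t)`, and counts in different
bins are independent *given the stimulus*.  Under this parametrisation the
instantaneous mutual information between stimulus and count,
`I_t = H(Y_t) − H(Y_t|S)`, has closed-form entropies, and the cumulative
information `CI_t = H(Y_t..Y_0) − H(Y_t..Y_0|S)` has an exact conditional
term (the running sum of per-bin conditional entropies).  The joint
*unconditional* distribution is a finite mixture of product distributions
and is not independent across bins — estimating its entropy is the hard
part of the problem and the reason three estimators are provided.

The Poisson assumption is a modelling choice, not a fact about the data:
because the Poisson distribution maximises count entropy at fixed mean,
conditional entropies are overestimated under mild deviations and the
information values are lower bounds.  The diagnostics module quantifies how
far a dataset departs from the assumptions (goodness of fit, Fano factors,
noise correlations) rather than enforcing them.

All count sums truncate at `R_max` (default 20, i.e. 2 spikes/ms in a
10-ms bin).  A guard verifies the truncated Poisson mass is within 1e−12
of 1; `integrate_to_bins` raises `R_max` automatically when an estimated
rate demands it.  Mixture pmfs are renormalised after truncation so every
estimator works with one exact, self-consistent distribution (this also
lets deliberately truncated toy models, used by the enumeration oracles in
the tests, remain internally coherent via `BinnedRates.trunc_tol`).
Summands with pmf below 1e−300 contribute zero (the `p log p → 0` limit);
joint probabilities are always accumulated in log space with log-sum-exp
over the stimulus mixture.

## Rate estimation

Per stimulus, spike times pooled over the M trials are smoothed with
Gaussian kernels.  The global bandwidth minimises the Poisson-process MISE
cross-validation cost
`C(w) = Σ_{ij} k_{√2·w}(t_i−t_j) − 2 Σ_{i≠j} k_w(t_i−t_j)` over a 30-point
log grid from 1 ms to a quarter window; the cost is evaluated from the
autocorrelation of 1-ms binned counts, which makes each evaluation O(T)
rather than O(N²).  Local adaptation re-optimises the same cost in
overlapping windows (five global bandwidths long, 50% overlap, windows with
fewer than 5 spikes keep the global value) and the per-spike bandwidth is
linearly interpolated between window centres.  Each kernel is renormalised
to unit mass inside `[0, T]`, so no rate mass leaks past the window edges
and `∫rate·dt·M` equals the pooled spike count.  Output is in spikes/ms at
1 kHz.

Degenerate stimuli fall back to a constant rate: `1/(2·M·N_t)` with no
spikes, `1/(M·N_t)` with one spike (`N_t` = number of 1-ms samples).  The
same constant also floors every estimated curve so downstream logs are
finite.  After integration to bins, means are floored at 1/20 expected
spikes per bin; the floor is read as *per analysis bin* (consistent with
`R_max = 20` counts per bin), exposed as `mu_floor`.

Jackknife replicates re-run the full estimator (including bandwidth
selection) on each delete-one trial set, normalised by M−1.  On the three
model archetypes at 10 trials the mean absolute rate error is below
0.01 spikes/ms (validated against the generator's ground truth), well
under the 0.02 spikes/ms level at which information estimates from true
and estimated rates become indistinguishable.

## The Monte Carlo joint-entropy estimator

Count vectors are drawn from the proposal
`q(ȳ) = Π_b p(y_b)` — the product of the per-bin marginal mixtures —
truncated at `R_max` exactly like the target, so importance weights
`w = p/q` are always finite.  The entropy estimate is the *self-normalised*
ratio `Σ w·(−log2 p) / Σ w`, accumulated in chunks of 100 000 samples; a
delete-one-chunk jackknife removes the ratio's O(1/N) bias and provides the
standard error.  Sampling stops when that error falls below `se_stop`
(default 0.2 bits), subject to a chunk floor (`min_chunks`, default 4), and
is capped at 5 000 000 samples; if the error still exceeds `se_abort`
(default 0.6 bits) at the cap the estimate is flagged unreliable and no
later time point of the series is computed (`abort_bin`).

Self-normalisation matters.  In this many-bin regime the importance
weights are approximately log-normal with a dispersion that grows with the
total correlation `Σ_b I_b − CI_t` of the joint distribution; the plain
weighted mean `Σ w·(−log2 p)/N` is destroyed by the weight-scale noise
(errors of tens of bits on 60-bin problems whose truth the exact-sampling
oracle pins to ±0.01 bits), while the ratio cancels it.  Even so, the
estimator has a feasibility horizon: once the weight dispersion outruns the
sample cap the jackknife error grows and the abort rule fires — this is the
designed behaviour, and it is what limits strongly driven neurons at long
integration times.  For a 60-bin end point the chunk floor should be raised
(32 chunks are used in the validation scenarios): with few chunks the
jackknife error estimate is itself too noisy to stop on.

Each time point uses an independent generator seeded by `(seed, t_end)`,
so series are reproducible bit for bit and replicate runs are independent.

Two deterministic estimators bracket the Monte Carlo value: the exact
running window (full enumeration over the last `n_bins` bins, default 4;
a lower bound on `CI_t` because older bins are forgotten) and the
Markov-chain approximation of order 1–4 (chain-rule decomposition with
bounded history; an upper bound because the neglected long-range dependence
inflates the joint entropy; exact when the order spans the history).  Both
enumerate `(R_max+1)^(order+1)` outcomes and guard against budget blow-ups.

## Categories and the CII

Category information averages the stimulus-conditional pmfs within each
category (uniform within-category weights, `p(c) = 1/n_c`) and treats the
resulting per-bin category pmfs as conditionally independent across bins —
the same structural assumption the stimulus-level model makes.  Priors over
stimuli are either uniform (`1/n_s`) or category-balanced
(`1/(k_i·n_c)`); the default is uniform for stimulus information and
category-balanced weighting inside the categorical quantities.

The CII compares the categorical cumulative information (CCI) to three
references per bin: the **floor** (mean CCI over random stimulus-to-
category assignments preserving category sizes; `n_perm` = 10 by default —
averaging reduces the floor's variance, which matters for small stimulus
sets where a random assignment can coincide with the true grouping), the
**expected** value (stimulus information converted to a correct-decoding
probability through the symmetric confusion matrix
`mi = log2 n − H2(p) − (1−p)·log2(n−1)`, inverted by root bracketing to
1e−12, then grouped by category and read off as `H_row + H_col − H_tot`),
and the **ceiling** (stimulus CI capped at `log2 n_c`).  The index is the
piecewise-linear position of CCI among the three, clipped to [0, 2] with
the raw value retained.  Each branch requires its own reference spread to
be positive; bins where estimation noise inverts or collapses a spread are
undefined rather than extrapolated.  Because the spreads are fractions of
a bit, index computations should run the Monte Carlo estimator well below
its default stopping error (0.02 bits is used for the ceiling archetype,
0.005 bits for floor-level indices in the validation scenarios).

## Uncertainty

The delete-one jackknife over trials removes the O(1/M) positive bias of
plug-in information estimates: replicate *j* pairs the j-th delete-one rate
across stimuli (with unequal trial counts, the smallest M sets the
replicate count) and the corrected value is
`M·θ − (M−1)·mean_j θ_(−j)`.  On null simulations (four identical
0.05 spikes/ms stimuli, 10 trials) the corrected instantaneous information
averages +0.010 bits versus +0.016 uncorrected; the residual is the
higher-order bias the first-order jackknife cannot see, and it is an order
of magnitude below typical signal levels.  Standard errors bootstrap the
whole pipeline (`NB` = 20 trial resamples with replacement within stimulus,
fresh Monte Carlo streams) and report `sqrt(var/NB)`.  Bins with
information above three local standard errors are flagged significant;
cumulative series lacking any significant bin are not fitted.

## Exponential fits

`CI_mod(t) = k·I_max·(1 − e^{−(t−dt)/τ})` for `t > dt` (0 before), with
`k ∈ [0,1]`, `τ ∈ (0, 10·T]`, `dt ∈ [0, T]`; `I_max` is supplied by the
caller as `log2 n_s` or `log2 n_c`.  Bounded trust-region least squares
from a 3×3×3 multi-start grid; the reported `k300` is the fitted model at
300 ms relative to `I_max`.  Noiseless curves are recovered to <1% and
0.02-bit-noise curves to <10% (test suite).

## Diagnostics

*Poisson GOF*: per (stimulus, bin), the log likelihood of the M counts
under delete-one means (zero-count means floored at `0.5/(M−1)`) is
compared with 1000 bootstrap replicates drawn from a Poisson at the
KDE-estimated mean; two-tailed p-values use the doubling convention with
(r+1)/(n+1) continuity correction; Benjamini–Hochberg FDR at 0.05 across
all cells of a neuron; all-zero cells are excluded.  *Fano*: across-trial
sample variance over mean (ddof = 1 by default, toggleable), per stimulus,
averaged across stimuli.  *Noise/stimulus correlations*: Pearson
correlations of residual counts (across trials) and of trial-averaged
counts (across stimuli) in consecutive bins, zero-variance pairs skipped.

*Temporal resolution*: the split-half PSTH coherence is corrected to the
expected single-train/true-mean coherence
`γ²_AR = 1/(1 + (M/2)(√(1/γ²_half) − 1))` and integrated as
`I_AR = −∫ log2(1−γ²) df`; the reported fraction is `I_AR(0..50 Hz)` over
`I_AR(0..500 Hz)`.  Spectra use Welch averaging with 200-ms Hann windows at
50% overlap.  Because the coherence estimator has a finite-segment floor
(~1/n_segments across the whole band, which would otherwise dominate the
integral of a band-limited signal), segment-mismatch null pairings estimate
that floor and only frequencies exceeding its pooled 99th percentile enter
the integral, floor-subtracted.  The cumulative rate-power fraction keeps
the DC component (a constant rate is all-DC by construction) and evaluates
the normalised cumulative Welch periodogram at 50 Hz.

## The simulator and what passing tests show

Model neurons are piecewise-constant rate profiles at 1 kHz: *rate*
(constant, distinct amplitudes 0.01–0.09 spikes/ms), *onset* (equal
0.065 spikes/ms bursts of 200 ms at latencies 0/100/200/300 ms over a
0.005 spikes/ms baseline), *temporal* (equal bursts at disjoint times),
*invariant* (0.01/0.01/0.2/0.2 spikes/ms with two categories of two) and
*interleaved* (0.01/0.04/0.08/0.12 spikes/ms with category labels
alternating along the rank order).  Spikes are drawn as per-1-ms Poisson
counts with uniform jitter — exact for piecewise-constant rates.  The
onset amplitude sits deliberately inside the importance sampler's feasible
window: strong enough that the true cumulative information at 600 ms is
1.95 bits (measured by exact mixture sampling, which is available for the
simulator but not for real data), weak enough that the weight dispersion
stays within the 5e6-sample budget.

These archetypes exercise the estimators under exactly the assumptions the
method makes (Poisson counts, conditional independence, stationary trial
statistics).  Passing them demonstrates correctness of the estimation
machinery, not robustness to real data's violations — bursting,
refractoriness, trial-to-trial gain drift, noise correlations.  The
diagnostics module is the tool for judging those on a given dataset, and
the known direction of the main violation (information is underestimated,
i.e. the estimates are conservative) is inherited from the maximum-entropy
property of the Poisson model.

## Problem sizes in the shipped checks

The validation scenarios run at desk scale: 60-bin windows, 4 stimuli,
10 trials; the Monte Carlo endpoint estimates average 16 replicate runs
(~1.6–5 M samples each); CII scenarios stop at 100 ms (10 bins) with
10 floor permutations; the null-centring check uses 30 simulation seeds.
Exhaustive-enumeration oracles run on ≤3 bins with truncated support.
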