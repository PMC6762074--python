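"""Simulate the three coding archetypes and recover their firing rates.

Builds Rate, Onset and Temporal model neurons, draws ten inhomogeneous-
Poisson trials per stimulus, estimates the time-varying rates with the
adaptive KDE and prints the recovery error.  Errors well below
0.02 spikes/ms mean the estimated rates are essentially interchangeable
with the true ones for the information calculations downstream.
"""

from tvinfo import kde_validation_error, make_model_neuron

for archetype in ("rate", "onset", "temporal"):
    spec = make_model_neuron(archetype)
    err = kde_validation_error(spec, n_trials=10, seed=0)
    amps = spec.rates.max(axis=1)
    print(f"{archetype:9s} peak rates {amps.round(3)} spikes/ms -> "
          f"mean |KDE - true| = {err:.4f} spikes/ms")
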