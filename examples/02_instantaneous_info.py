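"""Instantaneous mutual information along the response of a Temporal neuron.

The Temporal archetype responds to each of four stimuli with an identical
burst placed at a stimulus-specific time.  During a burst, one stimulus is
nearly perfectly discriminable from the other three, which carries about
0.5 bits (out of the 2-bit maximum for four equiprobable stimuli); between
bursts the information falls back to ~0.
"""

import numpy as np

from tvinfo import instantaneous_info, make_model_neuron
from tvinfo.validation import true_binned_rates

spec = make_model_neuron("temporal", amplitudes=0.2)
rates = true_binned_rates(spec)
series = instantaneous_info(rates)

peak = float(series.info.max())
print("bin end (ms) | I_t (bits)")
for t, v in zip(series.times_ms()[::6], series.info[::6]):
    print(f"{t:9.0f}    | {v:.3f}")
print(f"peak instantaneous information: {peak:.3f} bits "
      "(one of four stimuli discriminated -> ~0.5 bits expected)")
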