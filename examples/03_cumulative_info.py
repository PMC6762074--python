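"""Cumulative information of the Onset neuron, three estimators compared.

The Onset archetype fires the same 200-ms burst at four stimulus-specific
latencies.  Its instantaneous information is moderate at any single bin,
but the cumulative information integrates evidence across bins and
approaches the 2-bit ceiling (log2 of 4 stimuli) by 600 ms.  The Monte
Carlo importance-sampling estimate is bracketed by the exact 4-bin running
window (a lower bound: it forgets older bins) and the order-4 Markov-chain
approximation (an upper bound: it overestimates the joint entropy).
"""

import numpy as np

from tvinfo import MCParams, cumulative_info, exact_window_info, markov_joint_entropy
from tvinfo.instant import condition_tables, entropy_of_pmf
from tvinfo.simulate import make_model_neuron
from tvinfo.validation import true_binned_rates

spec = make_model_neuron("onset")
rates = true_binned_rates(spec)

mc = MCParams(seed=0, min_chunks=8)
ci = cumulative_info(rates, mc=mc, t_max=29)
win = exact_window_info(rates, n_bins=4)
w, pmf = condition_tables(rates)
cond = (w @ entropy_of_pmf(pmf)).cumsum()

print("t (ms) | window(4) |  MC (se)      | Markov(4)")
for t_end in (4, 9, 19, 29):
    mk = markov_joint_entropy(rates, t_end=t_end, order=4) - cond[t_end]
    print(f"{(t_end + 1) * 10:5.0f}  |  {win.info[t_end]:.3f}    | "
          f"{ci.info[t_end]:.3f} ({ci.se[t_end]:.3f}) | {mk:.3f}")
print("lower bound <= MC <= upper bound at every time; by 600 ms the MC "
      "estimate saturates near 2 bits (see tvinfo.validation.onset_cumulative_info)")
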