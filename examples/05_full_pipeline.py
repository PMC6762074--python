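"""Full analysis of one simulated neuron via the pipeline.

Simulates an invariant categorical neuron, writes its spike table, runs
rates -> information -> CII -> fits -> diagnostics, and prints the summary.
Equivalent shell command:

    tvinfo simulate --archetype invariant --n-trials 10 --seed 0 --out spikes.csv
    tvinfo run spikes.csv --seed 0 --out out/
"""

import json
import tempfile
from pathlib import Path

from tvinfo import make_model_neuron, sample_spikes
from tvinfo.pipeline import RunConfig, run_pipeline

spec = make_model_neuron("invariant")
spikes = sample_spikes(spec, n_trials=10, seed=0)

out = Path(tempfile.mkdtemp(prefix="tvinfo_"))
config = RunConfig(seed=0, nb_boot=0, n_perm=5, mc_se_stop=0.05,
                   mc_max_samples=1_000_000, gof_n_boot=300)
summary = run_pipeline(config, spikes, out)
print(json.dumps(summary, indent=2, default=str))
print(f"per-bin tables written to {out}")
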