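"""Run a few DPX trials of the neurotypical two-ring agent.

Each trial simulates the perception and memory rings (the perception ring
feeds the memory ring through a weak localized NMDA projection), decodes
both per ms, accumulates representational evidence into left/right
accumulators, and crosses noisy collapsing decision boundaries to produce a
choice and a reaction time.  AX requires the left (target) response; AY, BX
and BY require right.  A shortened 1500-ms delay keeps this demo quick
(~2 min); the standard task uses a 4000-ms delay.
"""

from ringdpx import dpx_protocol, neurotypical_agent, sample_trial_sequence
from ringdpx.decision_agent import run_dpx_block
from ringdpx.io import trial_results_to_frame

protocol = dpx_protocol(isi_ms=1500.0)
trials = sample_trial_sequence(6, seed=7)
results = run_dpx_block(neurotypical_agent(), trials, protocol)

print(trial_results_to_frame(results).to_string(index=False))
# memory_outcome "maintain" means the memory ring held the cue bump through
# the delay (the basis of correct AX/BX responding); rt_ms is measured from
# probe onset.
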