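"""Simulate one cue-probe trial of the low-inertia (perception) ring and
decode what it represents.

The cue at pi/2 ignites a localized activity bump that persists through the
2-s delay on recurrent NMDA drive alone; at 0.9 uS afferent conductance the
probe at 3pi/2 overcomes this ring's inertia and the bump jumps.
"""

import numpy as np

from ringdpx import (cue_probe_protocol, estimate_tuning_curve,
                     decode_state_timeline, classify_trial_outcome,
                     perception_preset, run_ring)

protocol = cue_probe_protocol()
ring = perception_preset()
trial = run_ring(ring, protocol.stimuli("cue", "probe", g_ampa_aff=0.9),
                 protocol.duration_ms, seed=42)

print(f"pyramidal spikes: {len(trial.spikes_pyr)}, "
      f"interneuron spikes: {len(trial.spikes_int)}")
for t0, t1, label in [(0, 500, "pre-cue"), (500, 1000, "cue"),
                      (1500, 3000, "delay"), (3000, 3500, "probe"),
                      (3500, 4000, "post-probe")]:
    print(f"  {label:>10s} ({t0}-{t1} ms): "
          f"{trial.spikes_pyr.mean_rate_hz(t0, t1):5.2f} Hz population mean")

tuning = estimate_tuning_curve(trial.spikes_pyr, 900.0, 1000.0)
timeline = decode_state_timeline(trial.spikes_pyr, tuning, protocol.labels,
                                 protocol.duration_ms)
outcome = classify_trial_outcome(timeline, "cue", "probe",
                                 protocol.cue_window, protocol.probe_window)
print(f"cue representation onset: {outcome.t_cue_onset} ms")
print(f"trial outcome: {outcome.outcome}"
      + (f" (probe acquired at {outcome.t_jump:.0f} ms)"
         if outcome.t_jump else ""))
# A "jump" means the ring tracked the new stimulus instead of holding the
# old one -- the perception-like behavior this preset is tuned for.
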