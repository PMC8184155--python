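"""A small excitation-inhibition regime map.

Sweeps the pyramidal and interneuron NMDA conductances around the
perception preset at fixed afferent drive (0.9 uS) and classifies seeded
cue-probe trials.  High pyramidal + low interneuron conductance favors
holding or epileptic firing; the reverse favors collapse; the band between
tracks stimuli (jump).  The full exploration uses an 11 x 11 x 11 grid
at 20+ trials per cell; this demo uses a 2 x 2 corner at 5 trials
(~4 min on one core).
"""

from ringdpx import SweepGrid, perception_preset, run_regime_sweep

grid = SweepGrid(nmda_pyr=(0.33, 0.37), nmda_int=(0.30, 0.33),
                 ampa_aff=(0.9,), trials_per_cell=5)
df = run_regime_sweep(grid, perception_preset(), seed=11, progress=True)
print()
print(df.to_string(index=False))
# frac_jump ~ 1 at (0.37, 0.30): perception-like tracking; frac_maintain
# rises at (0.37, 0.33): memory-like holding; frac_collapse dominates at
# (0.33, 0.30): too little recurrent excitation to hold a bump.
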