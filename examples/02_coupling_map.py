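"""Event-locked variable-window coupling map for one synthetic recording.

Couples STN spikes to a 60-80 Hz gamma burst around contralateral grip
onset, computes the 16x29 PLV/PPC map with equal-spike adaptive windows,
and reports where the map peaks.
"""
import numpy as np

from spikegamma.coupling import CouplingContext, coupling_map
from spikegamma.synth import SyntheticConfig, make_spike_phase_recording

cfg = SyntheticConfig(n_trials_per_side=14, coupling_depth=0.8, seed=1)
rng = np.random.default_rng(1)
schedule, signal, phase, spikes, truth = make_spike_phase_recording(cfg, rng)

ctx = CouplingContext.from_signal(spikes, schedule, signal, 1000.0)
contra = schedule[schedule["side"] == "contra"]
cmap = coupling_map(ctx, contra)

print(f"target spikes/window: {cmap.target}")
print(f"window widths: {np.nanmin(cmap.widths):.3f}-"
      f"{np.nanmax(cmap.widths):.3f} s "
      f"(mean {np.nanmean(cmap.widths):.3f} s)")
b, p = np.unravel_index(np.nanargmax(cmap.plv), cmap.plv.shape)
label, lo, hi = cmap.scheme.bins[b]
print(f"map maximum: PLV = {cmap.plv[b, p]:.3f} "
      f"(PPC = {cmap.ppc[b, p]:.3f}) in the {lo:.0f}-{hi:.0f} Hz bin "
      f"at grid point {p} (grip onset is point 14)")
print(f"interpolated display grid: {cmap.interpolated().shape}")
print("\nWith coupling depth m = 0.8 the expected movement-window PLV is")
print("m/2 = 0.40; the maximum sits in a gamma bin between the Go cue and")
print("grip onset (points 7-14), where the generator places the coupling.")
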