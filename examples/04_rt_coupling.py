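"""Does stronger pre-movement coupling precede faster grips?

Simulates a cohort whose coupling depth decreases with reaction time
(slope = dm/dRT = -0.5), then runs both RT analyses: the fast-vs-slow
median-split cluster contrast of full coupling maps, and the 7-bin
PLV-to-RT correlation with a Fisher-z group test.
"""
import numpy as np

from spikegamma.coupling import CouplingContext
from spikegamma.rt_vigor import (binned_rt_correlation, median_split_contrast,
                                 rt_correlation_group)
from spikegamma.synth import SyntheticConfig, make_spike_phase_recording

cfg = SyntheticConfig(n_trials_per_side=14, coupling_depth=0.5,
                      rt_coupling_slope=-0.5, base_rate=60.0, seed=3)
rng = np.random.default_rng(3)

contexts, rs = [], []
for r in range(12):
    sched, signal, phase, spikes, _ = make_spike_phase_recording(cfg, rng)
    contexts.append(CouplingContext.from_signal(spikes, sched, signal, 1000.0))
    rs.append(binned_rt_correlation(spikes, sched, phase, 1000.0).r)

contrast = median_split_contrast(contexts, var="rt", side="contra",
                                 n_perm=500, rng=rng)
sig = [c for c in contrast.cluster.clusters if c.significant and c.z_sum > 0]
print(f"fast-minus-slow significant positive clusters: {len(sig)}")
for c in sig:
    rows, cols = np.where(c.cells)
    print(f"  cluster rows {rows.min()}-{rows.max()} (freq bins), "
          f"points {cols.min()}-{cols.max()} (Go = 7, grip onset = 14), "
          f"z-sum = {c.z_sum:.0f}, p = {c.p:.3f}")

g = rt_correlation_group(np.array(rs))
print(f"binned PLV-RT correlation: mean R = {g['mean_r']:.2f}, "
      f"t = {g['t']:.2f}, p = {g['p']:.4f}, n = {g['n']}")
print("\nA negative mean R plus a pre-onset gamma cluster in the fast-slow")
print("contrast reproduces the RT effect: trials with stronger spike-to-")
print("gamma coupling right after the Go cue are the faster ones.")
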