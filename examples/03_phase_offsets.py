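"""Contra-vs-ipsi preferred-phase offset with circular statistics.

Simulates 23 recordings whose ipsilateral preferred gamma phase is opposite
(offset pi) to the contralateral one, extracts spike-coincident phases in
the movement window, and runs the group offset analysis: circular-median
preferred phases, PPC-based inclusion, dispersion CI, and a V-test against
a 180 degree offset.
"""
import numpy as np

from spikegamma.circular import SidePhases, preferred_phase_offsets
from spikegamma.synth import SyntheticConfig, make_spike_phase_recording

cfg = SyntheticConfig(n_trials_per_side=10, coupling_depth=0.5,
                      ipsi_offset=np.pi, seed=2)
rng = np.random.default_rng(2)

cohort = []
for r in range(23):
    sched, _, phase, spikes, _ = make_spike_phase_recording(
        cfg, rng, make_signal=False)
    s = np.sort(spikes)
    sides = {}
    for side in ("contra", "ipsi"):
        pieces = []
        for g in sched.loc[sched["side"] == side, "grip_on_s"]:
            i0, i1 = np.searchsorted(s, (g - 0.1, g + 0.4))
            idx = np.minimum((s[i0:i1] * 1000).astype(int), len(phase) - 1)
            pieces.append(phase[idx])
        sides[side] = np.concatenate(pieces)
    cohort.append(SidePhases(f"r{r}", sides["contra"], sides["ipsi"]))

res = preferred_phase_offsets(cohort, mu0=np.pi)
print(f"included recordings (PPC > 0 both sides): {res.included.sum()}/23")
print(f"group mean offset: {res.group.mean % (2 * np.pi):.2f} rad "
      f"(true offset: pi = {np.pi:.2f})")
print(f"95% CI: [{res.group.ci[0]:.2f}, {res.group.ci[1]:.2f}] rad")
print(f"V-test toward 180 deg: u = {res.vtest.u:.2f}, p = {res.vtest.p:.2g}")
print("\nA significant V-test with the CI covering pi says spikes lock to")
print("opposite gamma phases for the two effector sides — the timing code")
print("the analysis is designed to detect.")
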