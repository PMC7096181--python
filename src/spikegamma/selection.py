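"""Bipolar derivation and per-side ECoG contact selection.

For each recording and effector side, the bipolar contact pair with the
highest spike-to-gamma (60-80 Hz) PLV in a [-0.1, 0.4] s window around grip
onset is selected for further analysis; significance of the selected
contact requires both a trial-shuffle criterion and a matched-count
pre-movement baseline criterion (one-sided alpha = 0.1 each).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coupling import plv, ppc, ppc_from_plv
from .dataio import SignalChannel
from .timefreq import GAMMA_BAND, phase_series

MOVEMENT_WINDOW = (-0.1, 0.4)    # s relative to grip onset
BASELINE_WINDOW = (-3.0, -2.0)   # s relative to grip onset


def bipolar_derivation(channels: list[SignalChannel]) -> list[SignalChannel]:
    """Neighbour differences along the strip: contact_i - contact_{i+1},
    n contacts -> n-1 bipolar channels; common-mode signals cancel."""
    if len(channels) < 2:
        raise ValueError("need at least 2 contacts for a bipolar derivation")
    out = []
    for a, b in zip(channels[:-1], channels[1:]):
        coords = None
        if a.coords_mm is not None and b.coords_mm is not None:
            coords = (np.asarray(a.coords_mm) + np.asarray(b.coords_mm)) / 2
        out.append(SignalChannel(f"{a.label}-{b.label}", a.rate,
                                 a.samples - b.samples, coords, a.units))
    return out


def movement_window_phases(spike_times: np.ndarray, grip_on: np.ndarray,
                           phase: np.ndarray, rate: float,
                           window: tuple[float, float] = MOVEMENT_WINDOW
                           ) -> np.ndarray:
    """Phases coinciding with spikes pooled over per-trial windows around
    grip onset."""
    s = np.sort(np.asarray(spike_times, dtype=float))
    t = []
    for g in np.asarray(grip_on, dtype=float):
        i0, i1 = np.searchsorted(s, (g + window[0], g + window[1]))
        t.append(s[i0:i1])
    t = np.concatenate(t) if t else np.empty(0)
    idx = np.clip(np.round(t * rate).astype(int), 0, len(phase) - 1)
    return phase[idx]


@dataclass
class ContactSelection:
    recording_id: str
    side: str
    channel: int          # index into the bipolar list
    label: str
    plv: float
    ppc: float
    n_spikes: int
    flag_shuffle: bool | None = None
    flag_baseline: bool | None = None

    @property
    def significant(self) -> bool:
        return bool(self.flag_shuffle) and bool(self.flag_baseline)


def select_contact(
    spike_times: np.ndarray,
    trials: pd.DataFrame,
    bipolar: list[SignalChannel],
    side: str,
    band: tuple[float, float] = GAMMA_BAND,
    window: tuple[float, float] = MOVEMENT_WINDOW,
    recording_id: str = "",
    phases: np.ndarray | None = None,
) -> ContactSelection:
    """Pick the bipolar channel with the highest pooled-spike gamma PLV in
    the movement window for one side; ties go to the lowest channel index.

    `phases` may pass precomputed (n_channels, n_samples) gamma phases to
    avoid refiltering.
    """
    v = trials["valid"].astype(bool) & (trials["side"] == side)
    grip_on = trials.loc[v, "grip_on_s"].to_numpy(float)
    if len(grip_on) < 1:
        raise ValueError(f"no valid {side} trials")
    rate = bipolar[0].rate
    best = None
    for ci, ch in enumerate(bipolar):
        ph = (phases[ci] if phases is not None
              else phase_series(ch.samples, rate, band).phase)
        sp = movement_window_phases(spike_times, grip_on, ph, rate, window)
        if sp.size == 0:
            continue
        cand = (plv(sp), -ci, ci, ch.label, sp)
        if best is None or cand[:2] > best[:2]:
            best = cand
    if best is None:
        raise ValueError("no spikes in the movement window on any channel")
    val, _, ci, label, sp = best
    return ContactSelection(recording_id, side, ci, label, val,
                            ppc(sp), sp.size)


def contact_significance(
    spike_times: np.ndarray,
    trials: pd.DataFrame,
    phase: np.ndarray,
    rate: float,
    side: str = "contra",
    window: tuple[float, float] = MOVEMENT_WINDOW,
    baseline: tuple[float, float] = BASELINE_WINDOW,
    n_perm: int = 500,
    alpha: float = 0.1,
    rng: np.random.Generator | None = None,
) -> tuple[bool, bool | None, dict]:
    """Dual-criterion significance of movement-window coupling on a channel.

    flag_shuffle: observed PPC exceeds the (1-alpha) quantile of a null made
    by permuting the spike-to-LFP trial association (spike offsets re grip
    onset reassigned to other trials' windows), identically for the whole
    window. flag_baseline: observed PPC exceeds the (1-alpha) quantile of
    PPCs from spike-count-matched draws out of a -3..-2 s pre-movement
    window; None (and overall non-significant) if too few baseline spikes.
    """
    rng = rng or np.random.default_rng()
    v = trials["valid"].astype(bool) & (trials["side"] == side)
    grip_on = trials.loc[v, "grip_on_s"].to_numpy(float)
    s = np.sort(np.asarray(spike_times, dtype=float))
    n_samples = len(phase)

    # observed
    offs, tr_idx = [], []
    for j, g in enumerate(grip_on):
        i0, i1 = np.searchsorted(s, (g + window[0], g + window[1]))
        offs.append(s[i0:i1] - g)
        tr_idx.append(np.full(i1 - i0, j))
    offs = np.concatenate(offs)
    tr_idx = np.concatenate(tr_idx)
    if offs.size == 0:
        raise ValueError("no spikes in the movement window")
    unit = np.exp(1j * phase)

    def ppc_at(times):
        idx = np.clip(np.round(times * rate).astype(int), 0, n_samples - 1)
        return ppc_from_plv(float(np.abs(unit[idx].mean())), len(times))

    obs = ppc_at(grip_on[tr_idx] + offs)

    null_shuffle = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(len(grip_on))
        null_shuffle[k] = ppc_at(grip_on[perm[tr_idx]] + offs)
    flag_shuffle = bool(obs > np.quantile(null_shuffle, 1 - alpha))

    base = []
    for g in grip_on:
        i0, i1 = np.searchsorted(s, (g + baseline[0], g + baseline[1]))
        base.append(s[i0:i1])
    base = np.concatenate(base)
    flag_baseline: bool | None
    if base.size < offs.size:
        flag_baseline = None  # insufficient pre-movement spikes
        null_base = np.empty(0)
    else:
        null_base = np.empty(n_perm)
        for k in range(n_perm):
            draw = rng.choice(base, size=offs.size, replace=False)
            null_base[k] = ppc_at(draw)
        flag_baseline = bool(obs > np.quantile(null_base, 1 - alpha))
    detail = {"ppc": obs, "null_shuffle": null_shuffle, "null_baseline": null_base}
    return flag_shuffle, flag_baseline, detail
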