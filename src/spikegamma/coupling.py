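"""Spike-field coupling estimators and the event-locked variable-window map.

The central quantity is the phase-locking value over LFP phases coinciding
with spikes,

    PLV = | (1/n) * sum_t exp(i * phi_t) |,

together with its bias-corrected companion, the pairwise phase consistency

    PPC = n/(n-1) * (PLV^2 - 1/n),

whose expectation is 0 in the absence of coupling regardless of n.

Because PLV is inflated at small n, coupling is evaluated on an event-locked
grid of 29 time points per trial (8 equidistant points per inter-event
interval, shared endpoints merged) using windows whose widths adapt so that
the summed across-trials spike count matches a per-recording target at every
point.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .timefreq import FrequencyScheme, default_scheme, unit_phase_bank

N_GRID_POINTS = 29
POINTS_PER_INTERVAL = 8
#: grid indices of the four anchoring task events (cue, go, grip on, grip off)
EVENT_POINT_INDEX = (0, 7, 14, 21)
POST_OFFSET_S = 0.4


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def plv(phases: np.ndarray) -> float:
    """Length of the mean unit phase vector; in [0, 1]. NaN for n = 0."""
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        return float("nan")
    return float(np.abs(np.mean(np.exp(1j * phases))))


def ppc(phases: np.ndarray) -> float:
    """Pairwise phase consistency, n/(n-1)*(PLV^2 - 1/n). NaN for n < 2.

    Unbiased under no coupling: equals the average cosine of the phase
    difference over all spike pairs, and may be negative.
    """
    phases = np.asarray(phases, dtype=float)
    n = phases.size
    if n < 2:
        return float("nan")
    return ppc_from_plv(plv(phases), n)


def ppc_from_plv(plv_value: float, n: int) -> float:
    if n < 2:
        return float("nan")
    return float(n / (n - 1) * (plv_value**2 - 1.0 / n))


@dataclass(frozen=True)
class CouplingEstimate:
    plv: float
    ppc: float
    n: int


def coupling_estimate(phases: np.ndarray) -> CouplingEstimate:
    phases = np.asarray(phases, dtype=float)
    return CouplingEstimate(plv(phases), ppc(phases), phases.size)


# ---------------------------------------------------------------------------
# event-locked grid
# ---------------------------------------------------------------------------

@dataclass
class EventLockedGrid:
    """29 per-trial time points anchored to the four task events.

    Each of the four inter-event intervals (cue->go, go->grip on, grip
    on->grip off, grip off->grip off + 0.4 s) is subdivided into 8
    equidistant points including both endpoints; shared endpoints are merged
    ([1-8, 2-8, 2-8, 2-8]), giving 29 points.
    """

    points: np.ndarray       # (n_trials, 29) seconds
    interval_id: np.ndarray  # (29,) which interval each point belongs to
    frac: np.ndarray         # (29,) fractional position within its interval
    trial_index: np.ndarray  # (n_trials,) positional index into the trial table

    @property
    def n_trials(self) -> int:
        return self.points.shape[0]

    def mean_interval_durations(self) -> np.ndarray:
        """Average duration of the four inter-event intervals (s)."""
        ev = self.points[:, list(EVENT_POINT_INDEX) + [N_GRID_POINTS - 1]]
        return np.diff(ev, axis=1).mean(axis=0)


def build_grid(trials: pd.DataFrame) -> EventLockedGrid:
    """Build the event-locked grid from a trial table (valid trials only)."""
    t = trials[trials["valid"].astype(bool)] if "valid" in trials else trials
    if len(t) == 0:
        raise ValueError("no valid trials")
    events = t[["cue_on_s", "go_on_s", "grip_on_s", "grip_off_s"]].to_numpy(float)
    events = np.column_stack([events, events[:, -1] + POST_OFFSET_S])
    if np.any(np.diff(events, axis=1) <= 0):
        bad = np.where(np.any(np.diff(events, axis=1) <= 0, axis=1))[0]
        raise ValueError(f"non-monotone or degenerate events in trial rows {bad}")

    fracs = np.linspace(0.0, 1.0, POINTS_PER_INTERVAL)
    points, interval_id, frac = [], [], []
    for k in range(4):
        f = fracs if k == 0 else fracs[1:]
        seg = events[:, k][:, None] + f[None, :] * (
            events[:, k + 1] - events[:, k]
        )[:, None]
        points.append(seg)
        interval_id.extend([k] * len(f))
        frac.extend(f)
    pts = np.hstack(points)
    assert pts.shape[1] == N_GRID_POINTS
    return EventLockedGrid(
        pts, np.asarray(interval_id), np.asarray(frac),
        t.index.to_numpy() if hasattr(t, "index") else np.arange(len(t)),
    )


# ---------------------------------------------------------------------------
# equal-spike adaptive windows
# ---------------------------------------------------------------------------

MIN_TARGET = 50
RATE_WINDOW_S = 0.3


def target_spike_count(spike_times: np.ndarray, trials: pd.DataFrame) -> int:
    """Per-recording target spike count for the adaptive windows.

    The expected number of spikes an across-trials 0.3 s window captures:
    the mean within-trial firing rate (total spikes within all trial spans,
    cue to grip off + 0.4 s, divided by the summed span length) times 0.3 s
    times the number of trials. A window of ~0.3 s width centred at the same
    task point in every trial then sums to about this count. Floored at 50
    so very sparse recordings still use a representative sample.
    """
    t = trials[trials["valid"].astype(bool)] if "valid" in trials else trials
    if len(t) == 0:
        raise ValueError("no valid trials")
    s = np.sort(np.asarray(spike_times, dtype=float))
    t0 = t["cue_on_s"].to_numpy(float)
    t1 = t["grip_off_s"].to_numpy(float) + POST_OFFSET_S
    total_len = float(np.sum(t1 - t0))
    if total_len <= 0:
        raise ValueError("zero total trial length")
    n_spikes = int(np.sum(np.searchsorted(s, t1) - np.searchsorted(s, t0)))
    mean_rate = n_spikes / total_len
    return max(MIN_TARGET, int(round(mean_rate * RATE_WINDOW_S * len(t))))


@dataclass
class WindowSpikes:
    """Per grid point: chosen window and the spikes it captured.

    widths are full window widths (s); a NaN width marks a point where no
    width within the cap captured a single spike. spike_trial/spike_time/
    spike_offset are ragged lists over the 29 points; offsets are the spike
    times relative to that trial's window centre (used by trial-shuffle
    permutation nulls).
    """

    widths: np.ndarray
    counts: np.ndarray
    target: int
    spike_trial: list[np.ndarray]
    spike_time: list[np.ndarray]
    spike_offset: list[np.ndarray]


def adaptive_windows(
    spike_times: np.ndarray,
    grid: EventLockedGrid,
    target: int,
    min_width: float = 0.010,
    max_width: float = 2.0,
    step: float = 0.001,
) -> WindowSpikes:
    """Choose, per grid point, the symmetric window matching the spike target.

    The width is searched on a discrete 1 ms grid from 10 ms to 2 s; the
    across-trials summed spike count closest to the target wins; exact ties
    go to the smaller width (counts are non-decreasing in width, so the
    search is a bisection). The same width applies to every trial at that
    point.
    """
    if target < 1:
        raise ValueError("target must be >= 1")
    s = np.sort(np.asarray(spike_times, dtype=float))
    widths = np.arange(min_width, max_width + step / 2, step)

    def count(centres: np.ndarray, w: float) -> int:
        return int(np.sum(np.searchsorted(s, centres + w / 2)
                          - np.searchsorted(s, centres - w / 2)))

    w_out = np.full(N_GRID_POINTS, np.nan)
    c_out = np.zeros(N_GRID_POINTS, dtype=int)
    sp_trial: list[np.ndarray] = []
    sp_time: list[np.ndarray] = []
    sp_off: list[np.ndarray] = []
    for p in range(N_GRID_POINTS):
        centres = grid.points[:, p]
        # bisect for the smallest width with count >= target
        lo, hi = 0, len(widths) - 1
        if count(centres, widths[hi]) < target:
            k = hi  # cap reached; best achievable is the widest window
        else:
            while lo < hi:
                mid = (lo + hi) // 2
                if count(centres, widths[mid]) >= target:
                    hi = mid
                else:
                    lo = mid + 1
            k = lo
        c_hi = count(centres, widths[k])
        if k > 0:
            c_lo = count(centres, widths[k - 1])
            # strictly closer wins; tie -> smaller width
            if abs(c_lo - target) <= abs(c_hi - target):
                k, c_hi = k - 1, c_lo
        if c_hi == 0:
            sp_trial.append(np.empty(0, dtype=int))
            sp_time.append(np.empty(0))
            sp_off.append(np.empty(0))
            continue  # point marked missing (NaN width)
        w = widths[k]
        w_out[p], c_out[p] = w, c_hi
        tr, tt, off = [], [], []
        for j, c in enumerate(centres):
            i0, i1 = np.searchsorted(s, (c - w / 2, c + w / 2))
            tr.append(np.full(i1 - i0, j))
            tt.append(s[i0:i1])
            off.append(s[i0:i1] - c)
        sp_trial.append(np.concatenate(tr))
        sp_time.append(np.concatenate(tt))
        sp_off.append(np.concatenate(off))
    return WindowSpikes(w_out, c_out, target, sp_trial, sp_time, sp_off)


# ---------------------------------------------------------------------------
# coupling map
# ---------------------------------------------------------------------------

@dataclass
class CouplingMap:
    """16 x 29 PLV/PPC matrices with window metadata.

    `interpolated()` applies factor-2 mesh refinement (two rounds of 2x
    bilinear refinement, i.e. linear evaluation at 2^2*(n-1)+1 nodes per
    side) giving the 61 x 113 display grid.
    """

    plv: np.ndarray
    ppc: np.ndarray
    widths: np.ndarray
    counts: np.ndarray
    target: int
    scheme: FrequencyScheme
    mean_interval_durations: np.ndarray

    def interpolated(self, which: str = "plv") -> np.ndarray:
        return interpolate_map(getattr(self, which))

    def time_axis(self, n_points: int | None = None) -> np.ndarray:
        """Grid-point times (s from the cue) with interval lengths rescaled
        to the cohort/recording average durations."""
        return rescaled_time_axis(self.mean_interval_durations, n_points)


def interpolate_map(values: np.ndarray, factor: int = 2) -> np.ndarray:
    """Mesh refinement by `factor` rounds of 2x bilinear subdivision.

    Linear interpolation is idempotent under refinement, so the result is
    bilinear evaluation on a (2^f*(nr-1)+1) x (2^f*(nc-1)+1) grid: 16 x 29
    maps become 61 x 113.
    """
    v = np.asarray(values, dtype=float)
    nr, nc = v.shape
    rows = np.linspace(0, nr - 1, (1 << factor) * (nr - 1) + 1)
    cols = np.linspace(0, nc - 1, (1 << factor) * (nc - 1) + 1)
    tmp = np.empty((nr, len(cols)))
    for i in range(nr):
        tmp[i] = np.interp(cols, np.arange(nc), v[i])
    out = np.empty((len(rows), len(cols)))
    for j in range(len(cols)):
        out[:, j] = np.interp(rows, np.arange(nr), tmp[:, j])
    return out


def rescaled_time_axis(mean_durations: np.ndarray,
                       n_points: int | None = None) -> np.ndarray:
    """Per-interval linear time axis whose interval lengths are the given
    average durations; n_points refined grids share the anchoring."""
    d = np.asarray(mean_durations, dtype=float)
    edges = np.concatenate([[0.0], np.cumsum(d)])
    n_points = n_points or N_GRID_POINTS
    if (n_points - 1) % 4:
        raise ValueError("n_points must place events on shared nodes")
    per = (n_points - 1) // 4
    axis = [np.array([0.0])]
    for k in range(4):
        seg = np.linspace(edges[k], edges[k + 1], per + 1)[1:]
        axis.append(seg)
    return np.concatenate(axis)


@dataclass
class CouplingContext:
    """One recording's ingredients for coupling analyses: spike times, the
    trial table, and the complex unit-phase bank of the analysis channel."""

    spike_times: np.ndarray
    trials: pd.DataFrame
    unit_phases: np.ndarray  # (n_bins, n_samples) complex
    rate: float
    scheme: FrequencyScheme

    @classmethod
    def from_signal(cls, spike_times, trials, signal, rate,
                    scheme: FrequencyScheme | None = None) -> "CouplingContext":
        scheme = scheme or default_scheme()
        return cls(np.asarray(spike_times, float), trials,
                   unit_phase_bank(signal, rate, scheme), rate, scheme)


def phases_at(unit_phases: np.ndarray, times: np.ndarray, rate: float) -> np.ndarray:
    """Band phases at spike times by nearest-sample lookup: (n_bins, n_spikes)."""
    idx = np.clip(np.round(np.asarray(times) * rate).astype(int), 0,
                  unit_phases.shape[1] - 1)
    return np.angle(unit_phases[:, idx])


def coupling_map(
    ctx: CouplingContext,
    trials: pd.DataFrame | None = None,
    target: int | None = None,
    windows: WindowSpikes | None = None,
) -> CouplingMap:
    """Event-locked variable-window coupling map for one recording.

    `trials` restricts to a subset (e.g. one effector side); the spike-count
    target and windows are recomputed for that subset unless supplied.
    """
    trials = ctx.trials if trials is None else trials
    grid = build_grid(trials)
    if target is None:
        target = target_spike_count(ctx.spike_times, trials)
    if windows is None:
        windows = adaptive_windows(ctx.spike_times, grid, target)
    n_bins = ctx.scheme.n_bins
    plv_map = np.full((n_bins, N_GRID_POINTS), np.nan)
    n_map = windows.counts
    for p in range(N_GRID_POINTS):
        t = windows.spike_time[p]
        if t.size == 0:
            continue
        idx = np.clip(np.round(t * ctx.rate).astype(int), 0,
                      ctx.unit_phases.shape[1] - 1)
        plv_map[:, p] = np.abs(ctx.unit_phases[:, idx].mean(axis=1))
    with np.errstate(invalid="ignore"):
        n = np.maximum(n_map, 2)
        ppc_map = np.where(
            n_map[None, :] >= 2,
            n / (n - 1) * (plv_map**2 - 1.0 / n),
            np.nan,
        )
    return CouplingMap(plv_map, ppc_map, windows.widths, windows.counts,
                       target, ctx.scheme, grid.mean_interval_durations())


def spike_triggered_average(
    spike_times: np.ndarray, filtered: np.ndarray, rate: float,
    half_window: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean of filtered-LFP snippets centred on spikes.

    Returns (lags_s, sta). Spikes whose snippet would cross a signal edge
    are dropped; zero usable spikes is an error.
    """
    s = np.asarray(spike_times, dtype=float)
    h = int(round(half_window * rate))
    idx = np.round(s * rate).astype(int)
    ok = (idx - h >= 0) & (idx + h < len(filtered))
    idx = idx[ok]
    if idx.size == 0:
        raise ValueError("no spikes with a full snippet inside the signal")
    offs = np.arange(-h, h + 1)
    snippets = filtered[idx[:, None] + offs[None, :]]
    return offs / rate, snippets.mean(axis=0)
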