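"""Time-resolved firing rate and firing-pattern characteristics.

Rates use fixed 0.3 s windows around each event-locked grid point; the
pattern metrics (robust ISI CV = MAD/median x 100, %burst = fraction of
ISIs < 10 ms, ISI mode from a kernel density after burst exclusion) reuse
the equal-spike adaptive windows so that their sampling variability matches
the coupling estimates. Baselines are medians over same-sized segments of
the whole recording. Units are classified as increasing/decreasing only if
a significant rate cluster falls between the Go cue and movement offset —
the dissociation between stable rates and dynamic phase coupling rests on
this classification.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .cluster_stats import ClusterResult, sign_flip_baseline_test
from .coupling import (EventLockedGrid, WindowSpikes, N_GRID_POINTS,
                       RATE_WINDOW_S, EVENT_POINT_INDEX)

BURST_ISI_S = 0.010


def isi_cv_robust(isis: np.ndarray) -> float:
    """Median absolute deviation of the ISIs divided by the median, x 100.
    Scale-free: invariant to multiplying all ISIs by a constant."""
    isis = np.asarray(isis, dtype=float)
    if isis.size < 1:
        return float("nan")
    med = np.median(isis)
    if med == 0:
        return float("nan")
    return float(np.median(np.abs(isis - med)) / med * 100.0)


def pct_burst(isis: np.ndarray) -> float:
    isis = np.asarray(isis, dtype=float)
    if isis.size < 1:
        return float("nan")
    return float(np.mean(isis < BURST_ISI_S) * 100.0)


def isi_mode(isis: np.ndarray, grid_lo: float = 0.002,
             grid_hi: float = 2.0, n_grid: int = 256) -> float:
    """Mode of the ISI density after excluding bursts (ISIs < 10 ms).

    Gaussian KDE with the normal-reference bandwidth, evaluated on a
    log-spaced grid between 2 ms and 2 s. Degenerate samples (all ISIs
    equal) return that ISI.
    """
    isis = np.asarray(isis, dtype=float)
    isis = isis[isis >= BURST_ISI_S]
    if isis.size == 0:
        return float("nan")
    med = np.median(isis)
    if isis.size == 1 or np.ptp(isis) < 1e-9 * med:
        return float(med)
    # augment the log-spaced grid with the data values so narrow density
    # peaks cannot fall between grid nodes
    grid = np.union1d(np.geomspace(grid_lo, grid_hi, n_grid),
                      np.clip(np.unique(isis), grid_lo, grid_hi))
    dens = gaussian_kde(isis)(grid)
    return float(grid[np.argmax(dens)])


@dataclass
class FiringProfile:
    rate: np.ndarray          # spikes/s per grid point (0.3 s windows)
    cv_robust: np.ndarray     # % per grid point (adaptive windows)
    pct_burst: np.ndarray     # % per grid point
    isi_mode: np.ndarray      # s per grid point
    baseline_rate: float
    baseline_cv_robust: float
    baseline_pct_burst: float
    baseline_isi_mode: float
    baseline_uncertain: bool  # < 10 baseline segments

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for metric in ("rate", "cv_robust", "pct_burst", "isi_mode"):
            vals = getattr(self, metric)
            base = getattr(self, f"baseline_{metric}")
            for p, v in enumerate(vals):
                rows.append({"point": p, "metric": metric, "value": v,
                             "baseline": base})
        return pd.DataFrame(rows)


def instantaneous_rate(spike_times: np.ndarray, duration: float,
                       rate: float = 1000.0, sd: float = 0.050) -> np.ndarray:
    """Gaussian-kernel rate estimate (spikes/s) on a regular time grid;
    default kernel SD 50 ms."""
    from scipy.ndimage import gaussian_filter1d
    n = int(round(duration * rate))
    counts = np.bincount(
        np.clip(np.round(np.asarray(spike_times) * rate).astype(int), 0,
                n - 1), minlength=n)
    return gaussian_filter1d(counts.astype(float), sd * rate) * rate


def rate_curves(spike_times: np.ndarray, grid: EventLockedGrid,
                window: float = RATE_WINDOW_S) -> np.ndarray:
    """Per-trial firing-rate curves (n_trials, 29) from fixed windows."""
    s = np.sort(np.asarray(spike_times, dtype=float))
    lo = grid.points - window / 2
    hi = grid.points + window / 2
    counts = np.searchsorted(s, hi) - np.searchsorted(s, lo)
    return counts / window


def firing_profile(spike_times: np.ndarray, grid: EventLockedGrid,
                   windows: WindowSpikes,
                   recording_duration: float | None = None) -> FiringProfile:
    """All four metrics per grid point plus whole-recording baselines.

    ISI metrics attribute each ISI to the window containing its terminating
    spike and need >= 2 ISIs per window (NaN otherwise).
    """
    s = np.sort(np.asarray(spike_times, dtype=float))
    rates = rate_curves(spike_times, grid).mean(axis=0)
    cv = np.full(N_GRID_POINTS, np.nan)
    pb = np.full(N_GRID_POINTS, np.nan)
    mode = np.full(N_GRID_POINTS, np.nan)
    all_isis = np.diff(s)
    for p in range(N_GRID_POINTS):
        tt = windows.spike_time[p]
        if tt.size == 0:
            continue
        idx = np.searchsorted(s, tt)
        idx = idx[idx > 0]          # ISI terminates at this spike
        isis = all_isis[idx - 1]
        if isis.size < 2:
            continue
        cv[p] = isi_cv_robust(isis)
        pb[p] = pct_burst(isis)
        mode[p] = isi_mode(isis)
    base = baseline_characteristics(
        s, recording_duration if recording_duration is not None
        else (float(s[-1]) if s.size else 0.0), windows.target)
    return FiringProfile(rates, cv, pb, mode, base["rate"], base["cv_robust"],
                         base["pct_burst"], base["isi_mode"],
                         base["uncertain"])


def baseline_characteristics(spike_times: np.ndarray, duration: float,
                             target: int,
                             rate_window: float = RATE_WINDOW_S) -> dict:
    """Per-metric baseline medians from whole-recording segments.

    The rate baseline splits the recording into 0.3 s segments; the pattern
    metrics split the spike train into consecutive segments holding `target`
    spikes each (the coupling target count), so baseline and task estimates
    share their sample size. Fewer than 10 segments flags the estimate as
    uncertain.
    """
    s = np.sort(np.asarray(spike_times, dtype=float))
    if duration <= rate_window:
        raise ValueError("recording shorter than one baseline segment")
    n_seg = int(duration / rate_window)
    edges = np.arange(n_seg + 1) * rate_window
    counts = np.diff(np.searchsorted(s, edges))
    base_rate = float(np.median(counts / rate_window))

    cvs, pbs, modes = [], [], []
    for i0 in range(0, s.size - target + 1, target):
        seg = s[i0:i0 + target]
        isis = np.diff(seg)
        if isis.size < 2:
            continue
        cvs.append(isi_cv_robust(isis))
        pbs.append(pct_burst(isis))
        modes.append(isi_mode(isis))
    uncertain = len(cvs) < 10 or n_seg < 10
    med = lambda x: float(np.median(x)) if x else float("nan")
    return {"rate": base_rate, "cv_robust": med(cvs), "pct_burst": med(pbs),
            "isi_mode": med(modes), "uncertain": uncertain,
            "n_pattern_segments": len(cvs)}


def classify_response(
    spike_times: np.ndarray,
    trials: pd.DataFrame,
    grid: EventLockedGrid,
    n_perm: int = 1000,
    pre_p: float = 0.05,
    baseline: tuple[float, float] = (-0.5, 0.0),  # s relative to (cue, go)
    rng: np.random.Generator | None = None,
) -> tuple[str, ClusterResult]:
    """'increase' / 'decrease' / 'none' by the sign of a significant rate
    cluster between the Go cue and movement offset.

    Per-trial rate curves are normalized by each trial's baseline rate
    (cue - 0.5 s to Go) and tested against zero with trial-level sign flips;
    significant clusters outside the Go-to-grip-offset grid span do not
    change the label.
    """
    rng = rng or np.random.default_rng()
    s = np.sort(np.asarray(spike_times, dtype=float))
    v = trials["valid"].astype(bool)
    cue = trials.loc[v, "cue_on_s"].to_numpy(float)
    go = trials.loc[v, "go_on_s"].to_numpy(float)
    b0, b1 = cue + baseline[0], go + baseline[1]
    base_rate = ((np.searchsorted(s, b1) - np.searchsorted(s, b0))
                 / np.maximum(b1 - b0, 1e-9))
    curves = rate_curves(spike_times, grid) - base_rate[:, None]
    res = sign_flip_baseline_test(curves, n_perm=n_perm, pre_p=pre_p, rng=rng)
    go_pt, off_pt = EVENT_POINT_INDEX[1], EVENT_POINT_INDEX[3]
    label = "none"
    best = 0.0
    for c in res.clusters:
        if not c.significant:
            continue
        span = np.flatnonzero(c.cells)
        if span.size and span.min() <= off_pt and span.max() >= go_pt:
            if abs(c.z_sum) > abs(best):
                best = c.z_sum
                label = "increase" if c.z_sum > 0 else "decrease"
    return label, res
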