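"""High-frequency activity, polarity standardization, and gamma-phase-binned
spiking probability.

The sign of a bipolar ECoG derivation is arbitrary, so gamma "peak" and
"trough" are not comparable across recordings until standardized. The >300
Hz high-frequency activity (HFA) envelope — a proxy of local multi-unit
discharge — is invariant to that sign, and physiological gamma peaks
coincide with HFA maxima; if the mean HFA around gamma phase 0 is lower
than around +/-pi, the bipolar signal is flipped. Spiking probabilities are
then computed in k = 4 phase bins (width pi/2) in the movement window and
baseline-normalized.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ttest_rel, wilcoxon
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

from .selection import MOVEMENT_WINDOW, movement_window_phases
from .timefreq import (GAMMA_BAND, highpass_two_pass, lowpass_two_pass,
                       phase_series, wrap_angle)

N_HFA_BINS = 126
HFA_SMOOTH_BINS = 20
BASELINE_START_S = -3.0  # movement-window-sized baseline starts here


def compute_hfa(wideband: np.ndarray, rate: float, lfp_rate: float = 1000.0,
                hp: float = 300.0, lp: float = 100.0,
                method: str = "rectify") -> np.ndarray:
    """HFA envelope: high-pass at 300 Hz, full-wave rectify (or analytic
    amplitude), low-pass at 100 Hz, downsample to the LFP time base."""
    if rate <= 2 * hp:
        raise ValueError(f"wideband rate {rate} too low for a {hp} Hz high-pass")
    x = highpass_two_pass(wideband, rate, hp)
    if method == "rectify":
        env = np.abs(x)
    elif method == "analytic":
        from scipy.signal import hilbert
        env = np.abs(hilbert(x))
    else:
        raise ValueError("method must be 'rectify' or 'analytic'")
    env = lowpass_two_pass(env, rate, lp)
    factor = rate / lfp_rate
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("wideband rate must be an integer multiple of lfp rate")
    return env[:: int(round(factor))]


def circular_moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Wrap-around moving average; preserves the profile mean exactly."""
    if width <= 1:
        return np.asarray(x, dtype=float).copy()
    n = len(x)
    kernel = np.ones(width) / width
    ext = np.concatenate([x, x, x])
    return np.convolve(ext, kernel, mode="same")[n:2 * n]


@dataclass
class HfaProfile:
    bin_centres: np.ndarray
    mean_hfa: np.ndarray
    smoothed: np.ndarray
    flip: bool
    flat: bool  # no distinguishable peak; flip decision not attempted


def hfa_phase_profile(gamma_phase: np.ndarray, hfa: np.ndarray,
                      n_bins: int = N_HFA_BINS,
                      smooth_width: int = HFA_SMOOTH_BINS) -> HfaProfile:
    """Mean HFA in equally spaced, non-overlapping gamma-phase bins spanning
    the full cycle, circularly smoothed."""
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    centres = (edges[:-1] + edges[1:]) / 2
    which = np.clip(np.digitize(gamma_phase, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(which, weights=hfa, minlength=n_bins)
    counts = np.bincount(which, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        raw = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    # unvisited phase bins carry no evidence; fill with the overall mean so
    # they neither create nor destroy a peak
    filled = np.where(np.isnan(raw), np.nanmean(raw), raw)
    sm = circular_moving_average(filled, smooth_width)
    return HfaProfile(centres, raw, sm, flip=False, flat=False)


def standardize_polarity(
    signal: np.ndarray, hfa: np.ndarray, rate: float,
    band: tuple[float, float] = GAMMA_BAND,
    middle_halfwidth: float = 0.2 * np.pi,
    side_width: float = 0.2 * np.pi,
) -> tuple[np.ndarray, np.ndarray, HfaProfile]:
    """Flip the bipolar signal so its gamma peak coincides with the HFA peak.

    Whole-recording gamma phase is binned against the HFA; the mean smoothed
    HFA in a 0.4pi-wide window centred at phase 0 (where the gamma-filtered
    signal peaks) is compared with the mean over two 0.2pi-wide windows at
    the cycle edges (the troughs). Middle < sides means the recorded
    polarity put HFA maxima at the trough, so the signal is multiplied by
    -1 (phases rotate by pi). A flat profile leaves the signal unflipped
    with a warning flag.

    Returns (standardized signal, standardized gamma phase, HfaProfile).
    """
    phi = phase_series(signal, rate, band).phase
    prof = hfa_phase_profile(phi, hfa)
    middle = prof.smoothed[np.abs(prof.bin_centres) <= middle_halfwidth].mean()
    sides = prof.smoothed[np.abs(prof.bin_centres) >= np.pi - side_width].mean()
    spread = np.ptp(prof.smoothed)
    scale = np.mean(np.abs(prof.smoothed)) + 1e-300
    if spread / scale < 1e-6:
        prof.flat = True
        return signal, phi, prof
    prof.flip = bool(middle < sides)
    if prof.flip:
        return -signal, wrap_angle(phi + np.pi), prof
    return signal, phi, prof


@dataclass
class PhaseBinProfile:
    """Baseline-normalized spiking probability per gamma-phase bin.

    raw_prob and baseline_prob each sum to 1; rel_change = raw - baseline
    sums to 0.
    """

    edges: np.ndarray
    raw_prob: np.ndarray
    baseline_prob: np.ndarray

    @property
    def rel_change(self) -> np.ndarray:
        return self.raw_prob - self.baseline_prob


def binned_spike_probability(
    spike_times: np.ndarray,
    phase: np.ndarray,
    rate: float,
    trials: pd.DataFrame,
    side: str,
    k: int = 4,
    window: tuple[float, float] = MOVEMENT_WINDOW,
    baseline_start: float = BASELINE_START_S,
) -> PhaseBinProfile | None:
    """Spiking probability per phase bin for one effector side.

    Movement-window spikes come from `window` around grip onset; the
    baseline uses a same-sized window starting `baseline_start` s before
    grip onset. Returns None when either window holds no spikes.
    """
    edges = np.linspace(-np.pi, np.pi, k + 1)
    v = trials["valid"].astype(bool) & (trials["side"] == side)
    grip_on = trials.loc[v, "grip_on_s"].to_numpy(float)
    width = window[1] - window[0]
    mov = movement_window_phases(spike_times, grip_on, phase, rate, window)
    base = movement_window_phases(spike_times, grip_on, phase, rate,
                                  (baseline_start, baseline_start + width))
    if mov.size == 0 or base.size == 0:
        return None

    def probs(ph):
        h, _ = np.histogram(wrap_angle(ph), bins=edges)
        return h / h.sum()

    return PhaseBinProfile(edges, probs(mov), probs(base))


def _paired_test(a: np.ndarray, b: np.ndarray, alpha_norm: float = 0.05):
    """Paired t-test, or Wilcoxon signed-rank if the differences fail a
    Lilliefors normality check."""
    d = np.asarray(a) - np.asarray(b)
    if np.allclose(d, 0):
        return "t", 0.0, 1.0
    normal = lilliefors(d)[1] > alpha_norm
    if normal:
        stat, p = ttest_rel(a, b)
        return "t", float(stat), float(p)
    stat, p = wilcoxon(a, b)
    return "wilcoxon", float(stat), float(p)


def compare_bins(rel_contra: np.ndarray, rel_ipsi: np.ndarray,
                 alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise phase-bin statistics across recordings with FDR correction.

    Three families, each Benjamini-Hochberg corrected on its own: bin-vs-bin
    within the contra side, within the ipsi side, and contra-vs-ipsi per
    bin. Inputs are (n_recordings, k) relative-change matrices.
    """
    rel_contra = np.asarray(rel_contra, dtype=float)
    rel_ipsi = np.asarray(rel_ipsi, dtype=float)
    if rel_contra.shape[0] < 2:
        raise ValueError("need >= 2 recordings")
    k = rel_contra.shape[1]
    rows = []
    for family, data in (("within_contra", rel_contra), ("within_ipsi", rel_ipsi)):
        for i in range(k):
            for j in range(i + 1, k):
                test, stat, p = _paired_test(data[:, i], data[:, j])
                rows.append({"family": family, "a": f"bin{i + 1}",
                             "b": f"bin{j + 1}", "test": test, "stat": stat,
                             "p": p})
    for i in range(k):
        test, stat, p = _paired_test(rel_contra[:, i], rel_ipsi[:, i])
        rows.append({"family": "between_sides", "a": f"contra_bin{i + 1}",
                     "b": f"ipsi_bin{i + 1}", "test": test, "stat": stat,
                     "p": p})
    df = pd.DataFrame(rows)
    df["p_fdr"] = np.nan
    df["significant"] = False
    for family, idx in df.groupby("family").groups.items():
        rej, p_adj, *_ = multipletests(df.loc[idx, "p"], alpha=alpha,
                                       method="fdr_bh")
        df.loc[idx, "p_fdr"] = p_adj
        df.loc[idx, "significant"] = rej
    return df
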