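"""Reaction-time and vigor analyses: median-split coupling contrasts and the
binned coupling-to-RT correlation.

The question: does stronger STN spike-to-cortical-gamma coupling just after
the Go cue precede faster grips? Trials are median-split by RT (or peak
force / peak yank as vigor controls) and full coupling maps are contrasted
with the cluster permutation engine; per recording, pooled post-Go spikes
are also split into 7 equal-count bins to correlate bin PLV with bin RT,
with Fisher-z transformed coefficients t-tested against zero at the group
level.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, ttest_1samp, ttest_rel, wilcoxon
from statsmodels.stats.diagnostic import lilliefors

from .cluster_stats import ClusterResult, cluster_permutation_test
from .coupling import CouplingContext, CouplingMap, coupling_map, plv
from .timefreq import GAMMA_BAND

SPLIT_VARIABLES = {"rt": "rt_s", "peak_force": "peak_force_N",
                   "peak_yank": "peak_yank_N_per_ms"}
N_RT_BINS = 7
GO_WINDOW_S = 0.5
FISHER_CLAMP = 1.0 - 1e-6


def median_split(trials: pd.DataFrame, var: str = "rt",
                 side: str = "contra") -> tuple[pd.DataFrame, pd.DataFrame]:
    """(lower, upper) trial halves of one side; values strictly below the
    median go low, the median trial (odd n) joins the upper half, so half
    sizes differ by at most one."""
    col = SPLIT_VARIABLES[var]
    v = trials["valid"].astype(bool) & (trials["side"] == side)
    t = trials[v].sort_values(col, kind="stable")
    n = len(t)
    return t.iloc[: n // 2], t.iloc[n // 2:]


@dataclass
class SplitContrast:
    var: str
    side: str
    maps_low: list[CouplingMap]
    maps_high: list[CouplingMap]
    cluster: ClusterResult
    excluded: list[str]


def median_split_contrast(
    contexts: list[CouplingContext],
    var: str = "rt",
    side: str = "contra",
    statistic: str = "plv",
    min_per_half: int = 4,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    ids: list[str] | None = None,
) -> SplitContrast:
    """Cohort-level low-vs-high contrast of coupling maps after a median
    split; windows and spike targets are recomputed per trial subset.
    Recordings with fewer than `min_per_half` trials per half are excluded.
    For RT splits the cluster of interest is low-minus-high (fast - slow).
    """
    rng = rng or np.random.default_rng()
    ids = ids or [str(i) for i in range(len(contexts))]
    maps_low, maps_high, excluded = [], [], []
    for ctx, rid in zip(contexts, ids):
        low, high = median_split(ctx.trials, var, side)
        if len(low) < min_per_half or len(high) < min_per_half:
            excluded.append(rid)
            continue
        maps_low.append(coupling_map(ctx, low))
        maps_high.append(coupling_map(ctx, high))
    if len(maps_low) < 2:
        raise ValueError("fewer than 2 recordings with enough trials per half")
    a = np.stack([getattr(m, statistic) for m in maps_low])
    b = np.stack([getattr(m, statistic) for m in maps_high])
    res = cluster_permutation_test(a, maps_b=b, n_perm=n_perm, rng=rng)
    return SplitContrast(var, side, maps_low, maps_high, res, excluded)


@dataclass
class RtCorrelation:
    bin_plv: np.ndarray
    bin_rt: np.ndarray
    r: float


def binned_rt_correlation(
    spike_times: np.ndarray,
    trials: pd.DataFrame,
    gamma_phase: np.ndarray,
    rate: float,
    side: str = "contra",
    window: float = GO_WINDOW_S,
    n_bins: int = N_RT_BINS,
) -> RtCorrelation:
    """Per-recording Pearson correlation between binned PLV and RT.

    Trials are sorted by RT; all spikes in a 0.5 s window after the Go cue
    are ordered accordingly and split into 7 equal-count bins; each bin
    yields one PLV and the mean of the per-spike trial RTs. Needs >= 2
    spikes per bin; r is NaN (excluded from the group test) when RTs or
    PLVs are degenerate.
    """
    v = trials["valid"].astype(bool) & (trials["side"] == side)
    t = trials[v].sort_values("rt_s", kind="stable")
    s = np.sort(np.asarray(spike_times, dtype=float))
    ph, rt_per_spike = [], []
    for row in t.itertuples():
        i0, i1 = np.searchsorted(s, (row.go_on_s, row.go_on_s + window))
        times = s[i0:i1]
        idx = np.clip(np.round(times * rate).astype(int), 0,
                      len(gamma_phase) - 1)
        ph.append(gamma_phase[idx])
        rt_per_spike.append(np.full(i1 - i0, row.rt_s))
    ph = np.concatenate(ph)
    rt_per_spike = np.concatenate(rt_per_spike)
    if ph.size < 2 * n_bins:
        raise ValueError(f"need at least {2 * n_bins} post-Go spikes")
    bins_ph = np.array_split(ph, n_bins)
    bins_rt = np.array_split(rt_per_spike, n_bins)
    bin_plv = np.array([plv(b) for b in bins_ph])
    bin_rt = np.array([b.mean() for b in bins_rt])
    if np.ptp(bin_rt) == 0 or np.ptp(bin_plv) == 0:
        return RtCorrelation(bin_plv, bin_rt, float("nan"))
    r = float(pearsonr(bin_plv, bin_rt)[0])
    return RtCorrelation(bin_plv, bin_rt, r)


def fisher_z(r: np.ndarray) -> np.ndarray:
    """arctanh with |r| clamped just below 1 to stay finite."""
    r = np.clip(np.asarray(r, dtype=float), -FISHER_CLAMP, FISHER_CLAMP)
    return np.arctanh(r)


def rt_correlation_group(rs: np.ndarray) -> dict:
    """Group test of per-recording correlations: Fisher-z then one-sample
    t-test against zero (NaN correlations dropped)."""
    rs = np.asarray(rs, dtype=float)
    rs = rs[np.isfinite(rs)]
    if rs.size < 5:
        raise ValueError("need >= 5 finite correlations for the group test")
    z = fisher_z(rs)
    t, p = ttest_1samp(z, 0.0)
    return {"mean_r": float(np.tanh(z.mean())), "mean_z": float(z.mean()),
            "t": float(t), "p": float(p), "n": int(rs.size)}


def group_compare(a: np.ndarray, b: np.ndarray | None = None,
                  is_correlation: bool = False,
                  alpha_norm: float = 0.05) -> dict:
    """Paired group comparison (or one-sample test against 0 when b is None)
    following the normality rule: paired t-test if a Lilliefors test does
    not reject normality of the differences, Wilcoxon signed-rank
    otherwise. Correlation inputs are Fisher-z transformed first (clamped
    at |r| = 1 - 1e-6)."""
    a = np.asarray(a, dtype=float)
    clamped = False
    if is_correlation:
        clamped = bool(np.any(np.abs(a) >= 1)
                       or (b is not None and np.any(np.abs(np.asarray(b)) >= 1)))
        a = fisher_z(a)
        b = fisher_z(b) if b is not None else None
    d = a - (np.asarray(b, dtype=float) if b is not None else 0.0)
    if d.size < 5:
        raise ValueError("need n >= 5 pairs")
    if np.allclose(d, d[0]) and d[0] == 0:
        return {"test": "t", "stat": 0.0, "p": 1.0, "n": int(d.size),
                "clamped": clamped}
    normal = lilliefors(d)[1] > alpha_norm
    if normal:
        if b is None:
            stat, p = ttest_1samp(a, 0.0)
        else:
            stat, p = ttest_rel(a, np.asarray(b, dtype=float))
        test = "t"
    else:
        stat, p = wilcoxon(d)
        test = "wilcoxon"
    return {"test": test, "stat": float(stat), "p": float(p),
            "n": int(d.size), "clamped": clamped}
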