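"""Cluster-based permutation statistics for time-frequency maps and rate
curves, with the three null constructions used in the pipeline:

* paired condition contrasts (label permutation == sign flip of differences),
* trial-shuffle nulls that break the spike-to-LFP trial association while
  keeping both margins intact, and
* sign-flip tests of baseline-normalized firing rates against zero.

The engine standardizes the observed statistic cell-wise against the
permutation distribution (z = (obs - perm mean) / perm SD), forms
4-connected suprathreshold clusters at |z| >= z(pre_p, two-sided), and
compares each observed cluster's |z-sum| with the permutation distribution
of the maximal absolute cluster sum.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import norm

from .coupling import (CouplingContext, EVENT_POINT_INDEX, EventLockedGrid,
                       WindowSpikes, N_GRID_POINTS, adaptive_windows,
                       build_grid, target_spike_count)

FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class Cluster:
    cells: np.ndarray      # boolean mask over the map
    z_sum: float
    p: float
    significant: bool


@dataclass
class ClusterResult:
    z_map: np.ndarray
    clusters: list[Cluster]
    null_max_sums: np.ndarray
    threshold: float
    excluded_cells: np.ndarray  # zero permutation variance, left out
    permutations: np.ndarray | None = None  # logged for audit

    @property
    def significant_mask(self) -> np.ndarray:
        m = np.zeros_like(self.z_map, dtype=bool)
        for c in self.clusters:
            if c.significant:
                m |= c.cells
        return m

    @property
    def any_significant(self) -> bool:
        return any(c.significant for c in self.clusters)


def _signed_clusters(z: np.ndarray, thr: float):
    """Connected suprathreshold clusters (4-connectivity), signed z-sums."""
    out = []
    finite = np.isfinite(z)
    for sign in (1, -1):
        mask = finite & (sign * z >= thr)
        labels, n = ndimage.label(mask, structure=FOUR_CONN)
        for k in range(1, n + 1):
            cells = labels == k
            out.append((cells, float(z[cells].sum())))
    return out


def _max_abs_cluster_sum(z: np.ndarray, thr: float) -> float:
    cl = _signed_clusters(z, thr)
    return max((abs(s) for _, s in cl), default=0.0)


def _engine(obs: np.ndarray, perm_stats: np.ndarray, pre_p: float,
            permutations=None) -> ClusterResult:
    """Common core: cell-wise standardization + max-cluster-sum null."""
    thr = float(norm.ppf(1 - pre_p / 2))
    mu = perm_stats.mean(axis=0)
    sd = perm_stats.std(axis=0, ddof=1)
    excluded = sd == 0
    sd_safe = np.where(excluded, np.nan, sd)
    z_obs = (obs - mu) / sd_safe
    null_max = np.array([
        _max_abs_cluster_sum((perm_stats[k] - mu) / sd_safe, thr)
        for k in range(perm_stats.shape[0])
    ])
    crit = np.percentile(null_max, 95)
    clusters = []
    for cells, zsum in _signed_clusters(z_obs, thr):
        p = float(np.mean(null_max >= abs(zsum)))
        clusters.append(Cluster(cells, zsum, p, abs(zsum) > crit))
    return ClusterResult(z_obs, clusters, null_max, thr, excluded, permutations)


def cluster_permutation_test(
    maps_a: np.ndarray,
    maps_b: np.ndarray | None = None,
    null_maps: np.ndarray | None = None,
    n_perm: int = 1000,
    pre_p: float = 0.05,
    rng: np.random.Generator | None = None,
) -> ClusterResult:
    """Cluster permutation test of per-recording maps.

    Two modes:

    * paired contrast: `maps_a` and `maps_b` are (n_rec, F, T); condition
      labels are permuted per recording (equivalently, the per-recording
      differences are sign-flipped) `n_perm` times;
    * sampler null: `null_maps` is (n_rec, n_perm, F, T) of per-recording
      null maps (e.g. from `shuffle_null_coupling`); the observed group mean
      of `maps_a` is standardized against the group means of the null draws.

    NaN cells (missing grid points) are excluded from clustering.
    """
    rng = rng or np.random.default_rng()
    a = np.atleast_3d(np.asarray(maps_a, dtype=float))
    if (maps_b is None) == (null_maps is None):
        raise ValueError("provide exactly one of maps_b or null_maps")
    if maps_b is not None:
        d = a - np.atleast_3d(np.asarray(maps_b, dtype=float))
        return sign_flip_test(d, n_perm=n_perm, pre_p=pre_p, rng=rng)
    null = np.asarray(null_maps, dtype=float)
    if null.shape[0] != a.shape[0] or null.shape[2:] != a.shape[1:]:
        raise ValueError("null_maps must be (n_rec, n_perm, F, T) matching maps_a")
    obs = np.nanmean(a, axis=0)
    perm_stats = np.nanmean(null, axis=0)  # (n_perm, F, T)
    return _engine(obs, perm_stats, pre_p)


def sign_flip_test(
    diffs: np.ndarray,
    n_perm: int = 1000,
    pre_p: float = 0.05,
    rng: np.random.Generator | None = None,
) -> ClusterResult:
    """Sign-flip cluster test of per-recording (or per-trial) difference maps
    against zero. `diffs` is (n_units, F, T) or (n_units, T)."""
    rng = rng or np.random.default_rng()
    d = np.asarray(diffs, dtype=float)
    squeeze = d.ndim == 2
    if squeeze:
        d = d[:, None, :]
    n_units = d.shape[0]
    if n_units < 2:
        raise ValueError("need at least 2 units to permute")
    flat = d.reshape(n_units, -1)
    obs = np.nanmean(d, axis=0)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_units))
    nan_mask = np.isnan(flat)
    filled = np.where(nan_mask, 0.0, flat)
    denom = np.maximum((~nan_mask).sum(axis=0), 1)
    perm_stats = (signs @ filled) / denom
    perm_stats = perm_stats.reshape(n_perm, *d.shape[1:])
    perm_stats[:, np.isnan(obs)] = np.nan
    res = _engine(obs, perm_stats, pre_p, permutations=signs)
    if squeeze:
        res.z_map = res.z_map[0]
        for c in res.clusters:
            c.cells = c.cells[0]
        res.excluded_cells = res.excluded_cells[0]
    return res


def sign_flip_baseline_test(
    rate_curves: np.ndarray,
    n_perm: int = 1000,
    pre_p: float = 0.05,
    rng: np.random.Generator | None = None,
) -> ClusterResult:
    """Test baseline-normalized per-trial rate curves (n_trials, T) against 0
    by flipping the sign of randomly chosen trials."""
    return sign_flip_test(rate_curves, n_perm=n_perm, pre_p=pre_p, rng=rng)


def shuffle_null_coupling(
    ctx: CouplingContext,
    trials=None,
    n_perm: int = 500,
    rng: np.random.Generator | None = None,
    windows: WindowSpikes | None = None,
    target: int | None = None,
    return_permutations: bool = False,
):
    """Trial-shuffle null coupling maps for one recording.

    Per permutation one random trial-to-trial reassignment is drawn and
    applied identically at every time-frequency cell: each spike of trial j
    is mapped to a single coherent time in trial perm[j] by an
    event-anchored piecewise-linear warp (cue, Go, grip on, grip off +
    0.4 s), and its LFP phase is read there. Window memberships, widths and
    spike trains are kept intact, so every null map holds exactly the
    observed spike counts, and a spike shared by overlapping windows
    contributes the same phase at every grid point — matching the
    across-cell correlation structure of the observed map, without which
    the max-cluster null would be too small. Returns (n_perm, F, T) PLV
    maps (and the logged permutation vectors if requested).
    """
    rng = rng or np.random.default_rng()
    trials = ctx.trials if trials is None else trials
    grid = build_grid(trials)
    n_trials = grid.n_trials
    if n_trials < 2:
        raise ValueError("trial shuffling needs at least 2 trials")
    if target is None:
        target = target_spike_count(ctx.spike_times, trials)
    if windows is None:
        windows = adaptive_windows(ctx.spike_times, grid, target)
    n_bins, n_samples = ctx.unit_phases.shape
    # event anchors per trial for the piecewise-linear inter-trial warp
    anchors = grid.points[:, list(EVENT_POINT_INDEX) + [N_GRID_POINTS - 1]]
    null = np.full((n_perm, n_bins, N_GRID_POINTS), np.nan)
    perms = np.stack([rng.permutation(n_trials) for _ in range(n_perm)])
    # flatten the per-point spike lists once; phases are gathered per perm
    pts, trs, tts = [], [], []
    for p in range(N_GRID_POINTS):
        tr = windows.spike_trial[p]
        if tr.size == 0:
            continue
        pts.append(np.full(tr.size, p))
        trs.append(tr)
        tts.append(windows.spike_time[p])
    if not pts:
        return (null, perms) if return_permutations else null
    pts = np.concatenate(pts)
    trs = np.concatenate(trs)
    tts = np.concatenate(tts)
    for k in range(n_perm):
        t_new = np.empty_like(tts)
        for j in range(n_trials):
            sel = trs == j
            if not sel.any():
                continue
            src, dst = anchors[j], anchors[perms[k][j]]
            t = tts[sel]
            w = np.interp(t, src, dst)
            w = np.where(t < src[0], t - src[0] + dst[0], w)
            w = np.where(t > src[-1], t - src[-1] + dst[-1], w)
            t_new[sel] = w
        idx = np.clip(np.round(t_new * ctx.rate).astype(int), 0, n_samples - 1)
        ph = ctx.unit_phases[:, idx]  # (F, total_spikes)
        for p in np.unique(pts):
            null[k, :, p] = np.abs(ph[:, pts == p].mean(axis=1))
    if return_permutations:
        return null, perms
    return null
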