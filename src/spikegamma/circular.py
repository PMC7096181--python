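"""Circular statistics: summaries, confidence intervals, the V-test, and the
contra-vs-ipsi preferred-phase offset analysis.

All angles are radians wrapped to (-pi, pi]. The group-level question these
routines serve: is the preferred cortical-gamma phase of STN spikes during
ipsilateral gripping offset by ~180 deg from the contralateral one?
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .coupling import ppc
from .timefreq import wrap_angle


def resultant(angles: np.ndarray) -> tuple[float, float]:
    """(mean direction, mean resultant length R-bar)."""
    z = np.mean(np.exp(1j * np.asarray(angles, dtype=float)))
    return float(np.angle(z)), float(np.abs(z))


def circular_mean(angles) -> float:
    return resultant(angles)[0]


def circular_median(angles: np.ndarray) -> float:
    """Circular median: the angle minimizing the mean circular absolute
    deviation, searched over the data angles and their antipodes; ties go to
    the candidate closest to the circular mean."""
    a = wrap_angle(np.asarray(angles, dtype=float))
    if a.size == 0:
        raise ValueError("no angles")
    if a.size == 1:
        return float(a[0])
    cand = wrap_angle(np.concatenate([a, a + np.pi]))
    dev = np.pi - np.abs(np.pi - np.abs(a[None, :] - cand[:, None]))
    mdev = dev.mean(axis=1)
    best = np.flatnonzero(np.isclose(mdev, mdev.min()))
    if best.size > 1:
        mu = circular_mean(a)
        dist = np.abs(wrap_angle(cand[best] - mu))
        best = best[[np.argmin(dist)]]
    return float(cand[best[0]])


def circular_dispersion(angles: np.ndarray) -> float:
    """Fisher's circular dispersion delta = (1 - rho2) / (2 R-bar^2), with
    rho2 the second central trigonometric moment."""
    a = np.asarray(angles, dtype=float)
    mu, r = resultant(a)
    rho2 = float(np.mean(np.cos(2 * (a - mu))))
    return (1.0 - rho2) / (2.0 * r**2)


@dataclass
class CircularSummary:
    mean: float
    median: float
    r: float
    n: int
    ci: tuple[float, float] | None  # 95% CI for the mean direction
    ci_defined: bool

    def ci_covers(self, mu0: float) -> bool:
        if self.ci is None:
            return False
        half = wrap_angle(self.ci[1] - self.mean)
        return bool(abs(wrap_angle(mu0 - self.mean)) <= abs(half) + 1e-12)


def circular_summary(angles: np.ndarray, ci_level: float = 0.95) -> CircularSummary:
    """Circular mean/median/R-bar plus a dispersion-based CI for the mean.

    The CI is mean +/- arcsin(z * sqrt(delta/n)); it is undefined (flagged)
    when the sample is too dispersed for the arcsine argument to stay in
    [-1, 1] or when n < 3.
    """
    a = wrap_angle(np.asarray(angles, dtype=float))
    mu, r = resultant(a)
    med = circular_median(a)
    n = a.size
    ci = None
    ok = False
    if n >= 3 and r > 1e-12:
        z = norm.ppf(0.5 + ci_level / 2)
        arg = z * np.sqrt(circular_dispersion(a) / n)
        if arg < 1.0:
            half = float(np.arcsin(arg))
            ci = (wrap_angle(mu - half), wrap_angle(mu + half))
            ok = True
    return CircularSummary(mu, med, r, n, ci, ok)


@dataclass
class VTestResult:
    """V-test for concentration around a pre-specified direction mu0.

    V = n * R-bar * cos(mean - mu0); u = V * sqrt(2/n); p is the upper-tail
    standard-normal probability of u. Small p indicates concentration around
    mu0; angles concentrated at the antipode give u < 0 and large p.
    """

    v: float
    u: float
    p: float
    n: int
    mu0: float


def v_test(angles: np.ndarray, mu0: float) -> VTestResult:
    a = np.asarray(angles, dtype=float)
    n = a.size
    if n < 2:
        raise ValueError("V-test needs n >= 2")
    mean, r = resultant(a)
    v = n * r * np.cos(mean - mu0)
    u = v * np.sqrt(2.0 / n)
    return VTestResult(float(v), float(u), float(norm.sf(u)), n, float(mu0))


# ---------------------------------------------------------------------------
# preferred-phase offsets between effector sides
# ---------------------------------------------------------------------------

@dataclass
class SidePhases:
    """Spike-coincident gamma phases of one recording for both sides, with
    spike times relative to grip onset (for time-resolved variants)."""

    recording_id: str
    contra_phase: np.ndarray
    ipsi_phase: np.ndarray
    contra_reltime: np.ndarray | None = None
    ipsi_reltime: np.ndarray | None = None


@dataclass
class PhaseOffsetResult:
    recording_id: list[str]
    contra_pref: np.ndarray   # circular median per recording
    ipsi_pref: np.ndarray
    contra_ppc: np.ndarray
    ipsi_ppc: np.ndarray
    included: np.ndarray      # PPC > 0 on both sides
    offsets: np.ndarray       # wrapped contra - ipsi, included recordings only
    group: CircularSummary | None
    vtest: VTestResult | None


def preferred_phase_offsets(
    side_phases: list[SidePhases], mu0: float = np.pi, min_included: int = 3
) -> PhaseOffsetResult:
    """Per-recording preferred phases (circular medians of spike-coincident
    phases in the movement window), their contra - ipsi offsets, and the
    group mean/CI plus a V-test against mu0 = pi.

    Recordings are included only when the movement-window PPC is positive on
    both sides (a near-uniform phase sample has no meaningful preferred
    phase). Recordings are unweighted.
    """
    ids, cpref, ipref, cppc, ippc = [], [], [], [], []
    for sp in side_phases:
        ids.append(sp.recording_id)
        c, i = np.asarray(sp.contra_phase), np.asarray(sp.ipsi_phase)
        cpref.append(circular_median(c) if c.size else np.nan)
        ipref.append(circular_median(i) if i.size else np.nan)
        cppc.append(ppc(c))
        ippc.append(ppc(i))
    cpref, ipref = np.array(cpref), np.array(ipref)
    cppc, ippc = np.array(cppc), np.array(ippc)
    included = (cppc > 0) & (ippc > 0)
    offsets = wrap_angle(cpref[included] - ipref[included])
    group = vt = None
    if offsets.size >= min_included:
        group = circular_summary(offsets)
        vt = v_test(offsets, mu0)
    return PhaseOffsetResult(ids, cpref, ipref, cppc, ippc, included,
                             offsets, group, vt)


def offset_timecourse(
    side_phases: list[SidePhases],
    window: float = 0.5,
    step: float = 0.05,
    span: tuple[float, float] = (-1.0, 1.0),
    mu0: float = np.pi,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """V-test p-value for the contra - ipsi offset in sliding windows around
    grip onset.

    Returns (window centres, p(t), n recordings per window). Recordings with
    no spikes on either side in a window are dropped for that window.
    """
    n_win = int(np.floor((span[1] - span[0] - window) / step)) + 1
    centres = span[0] + window / 2 + step * np.arange(n_win)
    pvals = np.full(n_win, np.nan)
    counts = np.zeros(n_win, dtype=int)
    for k, c in enumerate(centres):
        lo, hi = c - window / 2, c + window / 2
        offs = []
        for sp in side_phases:
            if sp.contra_reltime is None or sp.ipsi_reltime is None:
                raise ValueError("offset_timecourse needs spike times relative "
                                 "to grip onset")
            cm = (sp.contra_reltime >= lo) & (sp.contra_reltime < hi)
            im = (sp.ipsi_reltime >= lo) & (sp.ipsi_reltime < hi)
            if cm.sum() == 0 or im.sum() == 0:
                continue
            offs.append(wrap_angle(circular_median(sp.contra_phase[cm])
                                   - circular_median(sp.ipsi_phase[im])))
        counts[k] = len(offs)
        if len(offs) >= 2:
            pvals[k] = v_test(np.asarray(offs), mu0).p
    return centres, pvals, counts
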