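"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure the coupling analysis assumes: a cued
grip task (cue -> Go after 1-2 s, grip within 2 s of Go, trials every
~4.7 s), a cortical strip whose one contact carries a 60-80 Hz narrowband
stochastic gamma oscillation bursting around contralateral grip onset on a
1/f + beta background, STN spike trains whose intensity is modulated by the
gamma phase,

    lambda(t) = rate(t) * (1 + m(t) * cos(phi_gamma(t) - mu(t))),

realized by exact thinning, and a 30 kHz wideband channel whose >300 Hz
envelope co-modulates with the gamma phase at a configurable polarity.
Coupling depth m, preferred phase mu (ipsilateral offset by `ipsi_offset`),
per-trial reaction-time dependence of m, and the wideband polarity are all
recorded as ground truth.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .dataio import Recording, SignalChannel, SpikeTrain
from .timefreq import bandpass_two_pass, highpass_two_pass, wrap_angle
from scipy.signal import hilbert
from scipy.ndimage import gaussian_filter1d


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic cohort.

    Defaults mirror the recorded cohort where the task defines them (28
    recordings, ~18 trials per side, Go delay uniform 1-2 s, RT 0.53 +/-
    0.21 s truncated at 2 s, grip duration 0.98 +/- 0.45 s, trial starts
    every 4.7 +/- 1.2 s); amplitudes the recordings do not pin down (burst
    SNR, noise slope, HFA modulation depth) are free parameters documented
    here and in the methods note.
    """

    n_recordings: int = 28
    n_trials_per_side: int = 18
    seed: int = 0
    # oscillations
    gamma_f0: float = 70.0
    gamma_band: tuple[float, float] = (60.0, 80.0)
    beta_f0: float = 20.0
    beta_band: tuple[float, float] = (15.0, 25.0)
    gamma_baseline_amp: float = 0.4
    gamma_burst_amp: float = 1.5
    beta_amp: float = 1.0
    beta_suppression: float = 0.3   # multiplicative during movement
    beta_rebound: float = 1.6       # multiplicative after grip offset
    noise_amp: float = 1.0
    noise_exponent: float = 1.0     # 1/f slope of the background
    line_noise: bool = False
    line_amp: float = 0.5
    # spiking
    base_rate: float = 30.0                 # spikes/s, STN tonic range
    coupling_depth: float = 0.5             # m in [0, 1]
    preferred_phase_contra: float = 0.0     # mu, rad
    ipsi_offset: float = float(np.pi)       # rad
    mu_jitter_sd: float = 0.2               # across-recording jitter of mu
    rt_coupling_slope: float = 0.0  # dm/dRT (1/s); negative: fast -> strong
    pre_go_coupling_s: float = 0.3          # coupling window starts this before Go
    gamma_burst_window: tuple[float, float] = (-0.1, 0.4)  # s re grip onset
    # behaviour
    rt_mean: float = 0.53
    rt_sd: float = 0.21
    grip_dur_mean: float = 0.98
    grip_dur_sd: float = 0.45
    iti_mean: float = 4.7
    iti_sd: float = 1.2
    # strip / wideband
    n_contacts: int = 6
    gamma_contact: int = 2
    lfp_rate: float = 1000.0
    wideband_rate: float = 30000.0
    include_wideband: bool = True
    hfa_polarity: str = "peak"   # 'peak' or 'trough'
    hfa_depth: float = 0.3
    hfa_contra_gain: float = 0.3  # movement-related HFA rise, contra bursts

    def __post_init__(self):
        if not 0 <= self.coupling_depth <= 1:
            raise ValueError("coupling_depth must be in [0, 1]")
        if self.base_rate <= 0 or self.lfp_rate <= 0:
            raise ValueError("rates must be positive")
        if not 0 < self.gamma_band[0] < self.gamma_band[1] < self.lfp_rate / 2:
            raise ValueError("gamma band outside (0, Nyquist)")
        if self.hfa_polarity not in ("peak", "trough"):
            raise ValueError("hfa_polarity must be 'peak' or 'trough'")
        if self.rt_mean <= 0 or self.grip_dur_mean <= 0 or self.iti_mean <= 0:
            raise ValueError("mean durations must be positive")


@dataclass
class RecordingTruth:
    recording_id: str
    m_contra: float
    m_ipsi: float
    mu_contra: float
    mu_ipsi: float
    polarity: str
    trial_m: np.ndarray        # per-trial pre-onset coupling depth
    gamma_phase: np.ndarray | None = None  # ground-truth phase series (1 kHz)

    def as_json(self) -> dict:
        d = {k: v for k, v in asdict(self).items() if k != "gamma_phase"}
        d["trial_m"] = np.asarray(self.trial_m).tolist()
        return d


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------

def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    s2 = np.log(1 + (sd / mean) ** 2)
    return np.log(mean) - s2 / 2, np.sqrt(s2)


def make_trial_schedule(config: SyntheticConfig,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Randomized-side trial table with the task's timing statistics.

    Cue->Go delays are uniform on [1, 2] s; RTs are truncated-lognormal with
    the configured mean/sd, capped at 2 s; grip durations lognormal; trial
    starts separated by ~iti_mean +/- iti_sd.
    """
    n = 2 * config.n_trials_per_side
    if n < 1:
        raise ValueError("need at least one trial")
    sides = np.array(["contra"] * config.n_trials_per_side
                     + ["ipsi"] * config.n_trials_per_side)
    rng.shuffle(sides)
    iti = np.maximum(rng.normal(config.iti_mean, config.iti_sd, n), 3.2)
    cue = 4.0 + np.concatenate([[0.0], np.cumsum(iti[:-1])])
    go = cue + rng.uniform(1.0, 2.0, n)
    mu, sig = _lognormal_params(config.rt_mean, config.rt_sd)
    rt = rng.lognormal(mu, sig, n)
    for _ in range(100):  # truncate at the 2 s validity limit
        bad = rt > 2.0
        if not bad.any():
            break
        rt[bad] = rng.lognormal(mu, sig, int(bad.sum()))
    rt = np.minimum(rt, 2.0)
    grip_on = go + rt
    mu_d, sig_d = _lognormal_params(config.grip_dur_mean, config.grip_dur_sd)
    dur = np.clip(rng.lognormal(mu_d, sig_d, n), 0.15, 2.5)
    grip_off = grip_on + dur
    if np.any(grip_off <= grip_on) or np.any(grip_on <= go):
        raise ValueError("impossible timing generated (negative duration)")
    return pd.DataFrame({
        "trial_id": np.arange(n),
        "cue_on_s": cue, "go_on_s": go, "grip_on_s": grip_on,
        "grip_off_s": grip_off, "side": sides, "rt_s": rt,
        "peak_force_N": np.maximum(rng.normal(97.0, 40.0, n), 5.0),
        "peak_yank_N_per_ms": np.maximum(rng.normal(0.45, 0.25, n), 0.02),
        "valid": np.ones(n, dtype=int),
    })


# ---------------------------------------------------------------------------
# signals
# ---------------------------------------------------------------------------

def one_over_f_noise(n: int, rate: float, exponent: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f^exponent, unit RMS."""
    w = rng.standard_normal(n)
    spectrum = np.fft.rfft(w)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spectrum * shaping, n)
    return x / x.std()


def narrowband_oscillation(n: int, rate: float, band: tuple[float, float],
                           rng: np.random.Generator) -> np.ndarray:
    """Stochastic narrowband oscillation (band-passed white noise, unit RMS);
    its instantaneous phase is non-trivial, unlike a pure sinusoid."""
    x = bandpass_two_pass(rng.standard_normal(n), rate, band[0], band[1])
    return x / x.std()


def _window_mask(t: np.ndarray, starts, stops) -> np.ndarray:
    m = np.zeros_like(t, dtype=bool)
    for a, b in zip(np.atleast_1d(starts), np.atleast_1d(stops)):
        m |= (t >= a) & (t < b)
    return m


def synthesize_lfp(schedule: pd.DataFrame, config: SyntheticConfig,
                   rng: np.random.Generator):
    """Multi-contact strip signals plus the ground-truth gamma phase.

    Returns (channels (n_contacts, n_samples), gamma_phase (n_samples,),
    duration_s). Only contact `gamma_contact` carries the gamma component;
    its amplitude rises in the burst window of contralateral trials only.
    Beta is common to all contacts with per-contact gains (so bipolar
    derivations retain it), suppressed during movement and rebounding after
    grip offset.
    """
    fs = config.lfp_rate
    duration = float(schedule["grip_off_s"].max()) + 2.0
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    contra = schedule["side"] == "contra"
    g_on = schedule["grip_on_s"].to_numpy(float)
    g_off = schedule["grip_off_s"].to_numpy(float)
    go = schedule["go_on_s"].to_numpy(float)

    gamma = narrowband_oscillation(n, fs, config.gamma_band, rng)
    gamma_phase = np.angle(hilbert(gamma))
    burst = _window_mask(t, g_on[contra] + config.gamma_burst_window[0],
                         g_on[contra] + config.gamma_burst_window[1])
    g_env = np.where(burst, config.gamma_burst_amp, config.gamma_baseline_amp)
    g_env = gaussian_filter1d(g_env.astype(float), 0.025 * fs)

    beta = narrowband_oscillation(n, fs, config.beta_band, rng)
    b_env = np.ones(n)
    b_env[_window_mask(t, go, g_off)] = config.beta_suppression
    b_env[_window_mask(t, g_off + 0.1, g_off + 0.7)] = config.beta_rebound
    b_env = gaussian_filter1d(b_env, 0.05 * fs) * config.beta_amp

    beta_gain = rng.uniform(0.5, 1.5, config.n_contacts)
    channels = np.empty((config.n_contacts, n))
    for c in range(config.n_contacts):
        ch = config.noise_amp * one_over_f_noise(n, fs, config.noise_exponent, rng)
        ch += beta_gain[c] * b_env * beta
        if c == config.gamma_contact:
            ch = ch + g_env * gamma
        if config.line_noise:
            ch += config.line_amp * np.sin(2 * np.pi * 60.0 * t
                                           + rng.uniform(0, 2 * np.pi))
        channels[c] = ch
    return channels, gamma_phase, duration


def sample_spikes(gamma_phase: np.ndarray, rate_profile, m, mu,
                  rng: np.random.Generator, fs: float = 1000.0) -> np.ndarray:
    """Spike times from an inhomogeneous point process with conditional
    intensity lambda(t) = rate(t) * (1 + m(t) cos(phi(t) - mu(t))).

    `rate_profile`, `m`, `mu` may be scalars or per-sample arrays. Realized
    by thinning of a homogeneous process at lambda_max = max(rate)*(1+max m),
    which is exact for bounded intensity. Expected spike-phase density is
    (1 + m cos(theta - mu)) / 2pi.
    """
    n = len(gamma_phase)
    duration = n / fs
    rate = np.broadcast_to(np.asarray(rate_profile, dtype=float), (n,))
    m_arr = np.broadcast_to(np.asarray(m, dtype=float), (n,))
    mu_arr = np.broadcast_to(np.asarray(mu, dtype=float), (n,))
    if np.any(m_arr < 0) or np.any(m_arr > 1):
        raise ValueError("coupling depth m must be within [0, 1] "
                         "(intensity would go negative)")
    lam_max = float(rate.max() * (1 + m_arr.max()))
    n_cand = rng.poisson(lam_max * duration)
    cand = np.sort(rng.uniform(0, duration, n_cand))
    idx = np.minimum((cand * fs).astype(int), n - 1)
    lam = rate[idx] * (1 + m_arr[idx] * np.cos(gamma_phase[idx] - mu_arr[idx]))
    keep = rng.uniform(0, lam_max, n_cand) < lam
    return cand[keep]


def coupling_profiles(schedule: pd.DataFrame, config: SyntheticConfig,
                      mu_contra: float, mu_ipsi: float, n_samples: int,
                      fs: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample coupling depth m(t) and preferred phase mu(t).

    Coupling is confined to each trial's pre-Go-through-onset window
    ([go - pre_go_coupling_s, grip_on], where the per-trial, RT-dependent
    depth m_i = clip(m + slope*(rt_i - rt_mean), 0, 1) applies; the slope is
    dm/dRT, so a negative slope makes fast grips couple more strongly) and
    the gamma burst window around grip onset (base depth m). Returns
    (m_profile, mu_profile, trial_m).
    """
    t = np.arange(n_samples) / fs
    m_prof = np.zeros(n_samples)
    mu_prof = np.zeros(n_samples)
    trial_m = np.empty(len(schedule))
    for i, row in enumerate(schedule.itertuples()):
        mu_trial = mu_contra if row.side == "contra" else mu_ipsi
        m_i = float(np.clip(
            config.coupling_depth
            + config.rt_coupling_slope * (row.rt_s - config.rt_mean), 0.0, 1.0))
        trial_m[i] = m_i
        pre = (t >= row.go_on_s - config.pre_go_coupling_s) & (t < row.grip_on_s)
        burst = ((t >= row.grip_on_s + config.gamma_burst_window[0])
                 & (t < row.grip_on_s + config.gamma_burst_window[1]))
        m_prof[pre] = m_i
        m_prof[burst & ~pre] = config.coupling_depth
        m_prof[burst & pre] = max(m_i, config.coupling_depth)
        mu_prof[pre | burst] = mu_trial
    return m_prof, mu_prof, trial_m


def synthesize_wideband(gamma_phase: np.ndarray, polarity: str,
                        rng: np.random.Generator,
                        lfp_component: np.ndarray | None = None,
                        depth: float = 0.3, lfp_rate: float = 1000.0,
                        wideband_rate: float = 30000.0,
                        slow_envelope: np.ndarray | None = None) -> np.ndarray:
    """30 kHz wideband channel whose >300 Hz envelope tracks the gamma phase.

    The broadband (>300 Hz high-passed) noise amplitude is modulated as
    1 + depth*cos(phi_gamma - phi0) with phi0 = 0 for 'peak' polarity and pi
    for 'trough'; an optional slow envelope (at the LFP rate, e.g. a
    movement-related multi-unit activity rise) multiplies on top, as does
    the (upsampled) LFP of the gamma-carrying contact.
    """
    if polarity not in ("peak", "trough"):
        raise ValueError("polarity must be 'peak' or 'trough'")
    factor = wideband_rate / lfp_rate
    n30 = int(round(len(gamma_phase) * factor))
    t_lo = np.arange(len(gamma_phase)) / lfp_rate
    t_hi = np.arange(n30) / wideband_rate
    # upsample the phase through its cartesian embedding (no unwrap seams)
    c = np.interp(t_hi, t_lo, np.cos(gamma_phase))
    s = np.interp(t_hi, t_lo, np.sin(gamma_phase))
    phi0 = 0.0 if polarity == "peak" else np.pi
    mod = 1.0 + depth * (np.cos(phi0) * c + np.sin(phi0) * s)
    if slow_envelope is not None:
        mod *= np.interp(t_hi, t_lo, slow_envelope)
    noise = highpass_two_pass(rng.standard_normal(n30), wideband_rate, 300.0)
    noise /= noise.std()
    wb = noise * mod
    if lfp_component is not None:
        wb = wb + np.interp(t_hi, t_lo, lfp_component)
    return wb


def make_spike_phase_recording(config: SyntheticConfig,
                               rng: np.random.Generator,
                               noise_amp: float = 0.5,
                               make_signal: bool = True):
    """Light-weight recording: schedule, one gamma-carrying signal, its
    ground-truth phase, and coupled spikes — no strip or wideband.

    Used where an analysis only needs the spike/phase structure (offset
    statistics, RT-coupling recovery, calibration replicates); the signal is
    the narrowband gamma oscillation plus 1/f background so full
    time-frequency banks can still be computed from it.
    """
    schedule = make_trial_schedule(config, rng)
    fs = config.lfp_rate
    n = int(round((float(schedule["grip_off_s"].max()) + 2.0) * fs))
    gamma = narrowband_oscillation(n, fs, config.gamma_band, rng)
    gamma_phase = np.angle(hilbert(gamma))
    mu_c = wrap_angle(config.preferred_phase_contra
                      + rng.normal(0.0, config.mu_jitter_sd))
    mu_i = wrap_angle(mu_c + config.ipsi_offset)
    m_prof, mu_prof, trial_m = coupling_profiles(
        schedule, config, mu_c, mu_i, n, fs)
    spikes = sample_spikes(gamma_phase, config.base_rate, m_prof, mu_prof,
                           rng, fs=fs)
    signal = None
    if make_signal:
        signal = gamma + noise_amp * one_over_f_noise(
            n, fs, config.noise_exponent, rng)
    truth = RecordingTruth("", config.coupling_depth, config.coupling_depth,
                           mu_c, mu_i, config.hfa_polarity, trial_m, None)
    return schedule, signal, gamma_phase, spikes, truth


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def make_recording(config: SyntheticConfig, rng: np.random.Generator,
                   recording_id: str,
                   keep_gamma_phase: bool = False
                   ) -> tuple[Recording, RecordingTruth]:
    schedule = make_trial_schedule(config, rng)
    channels, gamma_phase, duration = synthesize_lfp(schedule, config, rng)
    mu_c = wrap_angle(config.preferred_phase_contra
                      + rng.normal(0.0, config.mu_jitter_sd))
    mu_i = wrap_angle(mu_c + config.ipsi_offset)
    m_prof, mu_prof, trial_m = coupling_profiles(
        schedule, config, mu_c, mu_i, len(gamma_phase), config.lfp_rate)
    spikes = sample_spikes(gamma_phase, config.base_rate, m_prof, mu_prof,
                           rng, fs=config.lfp_rate)
    lfp = [SignalChannel(f"ecog_{c}", config.lfp_rate, channels[c])
           for c in range(config.n_contacts)]
    wb = None
    if config.include_wideband:
        t = np.arange(len(gamma_phase)) / config.lfp_rate
        contra_on = schedule.loc[schedule["side"] == "contra",
                                 "grip_on_s"].to_numpy(float)
        slow = np.ones(len(gamma_phase))
        slow[_window_mask(t, contra_on + config.gamma_burst_window[0],
                          contra_on + config.gamma_burst_window[1])] += \
            config.hfa_contra_gain
        slow = gaussian_filter1d(slow, 0.025 * config.lfp_rate)
        wb = SignalChannel(
            "wideband", config.wideband_rate,
            synthesize_wideband(gamma_phase, config.hfa_polarity, rng,
                                lfp_component=channels[config.gamma_contact],
                                depth=config.hfa_depth,
                                lfp_rate=config.lfp_rate,
                                wideband_rate=config.wideband_rate,
                                slow_envelope=slow))
    rec = Recording(
        recording_id,
        SpikeTrain(recording_id + "_u1",
                   "single" if rng.uniform() < 12 / 28 else "multi", spikes),
        lfp, schedule, wb)
    truth = RecordingTruth(recording_id, config.coupling_depth,
                           config.coupling_depth, mu_c, mu_i,
                           config.hfa_polarity, trial_m,
                           gamma_phase if keep_gamma_phase else None)
    return rec, truth


def make_cohort(config: SyntheticConfig, keep_gamma_phase: bool = False
                ) -> tuple[list[Recording], list[RecordingTruth]]:
    """Reproducible cohort: recording r uses an RNG spawned from
    (config.seed, r), so identical seeds give identical cohorts."""
    recs, truths = [], []
    for r in range(config.n_recordings):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, r]))
        rec, tr = make_recording(config, rng, f"rec{r:03d}",
                                 keep_gamma_phase=keep_gamma_phase)
        recs.append(rec)
        truths.append(tr)
    return recs, truths
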