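"""Band-limited phase/amplitude extraction and event-locked power maps.

All decompositions use zero-phase (forward-backward) Butterworth filtering
followed by the Hilbert transform, so that phase 0 falls on local maxima of
the band-passed signal (cosine convention) and no group delay is introduced.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import next_fast_len
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, hilbert, sosfiltfilt


@dataclass(frozen=True)
class FrequencyScheme:
    """Set of frequency bins used for time-frequency decompositions.

    The default scheme has 16 bins: four canonical low-frequency bands
    (theta 5-8, alpha 8-12, low-beta 12-20, high-beta 20-30 Hz) followed by
    20 Hz-wide bins at centre frequencies 40 ... 150 Hz in 10 Hz steps.
    """

    bins: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        for label, lo, hi in self.bins:
            if not 0 < lo < hi:
                raise ValueError(f"invalid band {label}: ({lo}, {hi})")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def labels(self) -> list[str]:
        return [b[0] for b in self.bins]

    @property
    def edges(self) -> np.ndarray:
        return np.array([(lo, hi) for _, lo, hi in self.bins])

    def index_of(self, label: str) -> int:
        return self.labels.index(label)


def default_scheme() -> FrequencyScheme:
    bins = [
        ("theta", 5.0, 8.0),
        ("alpha", 8.0, 12.0),
        ("low_beta", 12.0, 20.0),
        ("high_beta", 20.0, 30.0),
    ]
    for fc in range(40, 151, 10):
        bins.append((f"gamma_{fc}", fc - 10.0, fc + 10.0))
    return FrequencyScheme(tuple(bins))


#: the 60-80 Hz narrowband gamma bin (centre 70 Hz) used throughout
GAMMA_BAND = (60.0, 80.0)


@dataclass
class PhaseAmplitudeSeries:
    """Instantaneous phase (rad, in (-pi, pi]) and amplitude of one band."""

    band: tuple[float, float]
    rate: float
    phase: np.ndarray
    amplitude: np.ndarray


def _check_band(f_lo: float, f_hi: float, rate: float) -> None:
    nyq = rate / 2.0
    if not 0 < f_lo < f_hi < nyq:
        raise ValueError(
            f"band ({f_lo}, {f_hi}) Hz outside (0, Nyquist={nyq}) for rate {rate}"
        )


def bandpass_two_pass(
    x: np.ndarray, rate: float, f_lo: float, f_hi: float, order: int = 4
) -> np.ndarray:
    """Zero-phase band-pass: 4th-order Butterworth applied forward and backward.

    The two-pass application doubles the effective attenuation and cancels
    the phase response; edges are handled by reflection padding.
    """
    _check_band(f_lo, f_hi, rate)
    sos = butter(order, [f_lo, f_hi], btype="bandpass", fs=rate, output="sos")
    return sosfiltfilt(sos, np.asarray(x, dtype=float))


def highpass_two_pass(x, rate, f_c, order=4):
    if not 0 < f_c < rate / 2:
        raise ValueError(f"cutoff {f_c} Hz outside (0, Nyquist) for rate {rate}")
    sos = butter(order, f_c, btype="highpass", fs=rate, output="sos")
    return sosfiltfilt(sos, np.asarray(x, dtype=float))


def lowpass_two_pass(x, rate, f_c, order=4):
    if not 0 < f_c < rate / 2:
        raise ValueError(f"cutoff {f_c} Hz outside (0, Nyquist) for rate {rate}")
    sos = butter(order, f_c, btype="lowpass", fs=rate, output="sos")
    return sosfiltfilt(sos, np.asarray(x, dtype=float))


def notch_line_noise(x, rate, base=60.0, harmonics=3, order=2, width=2.0):
    """Optional 60/120/180 Hz notch stage (off by default in the pipeline)."""
    y = np.asarray(x, dtype=float)
    for k in range(1, harmonics + 1):
        f0 = base * k
        if f0 + width >= rate / 2:
            break
        sos = butter(order, [f0 - width, f0 + width], btype="bandstop", fs=rate,
                     output="sos")
        y = sosfiltfilt(sos, y)
    return y


def analytic_phase_amplitude(
    filtered: np.ndarray, rate: float, band: tuple[float, float]
) -> PhaseAmplitudeSeries:
    """Hilbert-transform phase and amplitude of an already band-passed signal.

    Phase follows the cosine convention: 0 at local maxima of the filtered
    signal, +/-pi at local minima. A constant input has no defined phase and
    is returned as NaN.
    """
    x = np.asarray(filtered, dtype=float)
    if np.ptp(x) == 0:
        nan = np.full_like(x, np.nan)
        return PhaseAmplitudeSeries(band, rate, nan, np.zeros_like(x))
    n = len(x)
    z = hilbert(x, N=next_fast_len(n))[:n]  # fast-length FFT, then truncate
    return PhaseAmplitudeSeries(band, rate, np.angle(z), np.abs(z))


def phase_series(x: np.ndarray, rate: float, band: tuple[float, float],
                 order: int = 4) -> PhaseAmplitudeSeries:
    """Band-pass then Hilbert in one step."""
    return analytic_phase_amplitude(
        bandpass_two_pass(x, rate, band[0], band[1], order=order), rate, band
    )


def unit_phase_bank(x: np.ndarray, rate: float,
                    scheme: FrequencyScheme | None = None) -> np.ndarray:
    """Complex unit phasors e^{i phi_b(t)} for every bin of the scheme.

    Returns a (n_bins, n_samples) complex64 array; this is the in-memory
    container downstream coupling estimators index with spike times.
    """
    scheme = scheme or default_scheme()
    out = np.empty((scheme.n_bins, len(x)), dtype=np.complex64)
    for i, (_, lo, hi) in enumerate(scheme.bins):
        ps = phase_series(x, rate, (lo, hi))
        out[i] = np.exp(1j * ps.phase)
    return out


def tf_power_map(
    x: np.ndarray,
    rate: float,
    grid_points: np.ndarray,
    scheme: FrequencyScheme | None = None,
    window: float = 0.3,
    stat: str = "mean",
) -> np.ndarray:
    """Event-locked relative power map (n_bins x n_points).

    Power is the squared analytic amplitude averaged within a fixed window
    around each grid point, averaged across trials, then divided by that
    bin's median windowed power over the entire recording
    (whole-recording-median normalization computed on the same moving-window
    statistic, so stationary noise maps to ~1 everywhere).

    Parameters
    ----------
    grid_points : (n_trials, n_points) array of window centres in seconds.
    stat : 'mean' or 'median' within-window statistic.
    """
    scheme = scheme or default_scheme()
    grid_points = np.asarray(grid_points, dtype=float)
    n_trials, n_points = grid_points.shape
    n = len(x)
    half = int(round(window / 2 * rate))
    centres = np.round(grid_points * rate).astype(int)
    reducer = np.median if stat == "median" else np.mean

    out = np.full((scheme.n_bins, n_points), np.nan)
    for b, (_, lo, hi) in enumerate(scheme.bins):
        amp2 = analytic_phase_amplitude(
            bandpass_two_pass(x, rate, lo, hi), rate, (lo, hi)
        ).amplitude ** 2
        med = np.median(uniform_filter1d(amp2, 2 * half))
        csum = np.concatenate([[0.0], np.cumsum(amp2)])
        for p in range(n_points):
            vals = []
            for t in range(n_trials):
                i0, i1 = centres[t, p] - half, centres[t, p] + half
                if i0 < 0 or i1 > n:
                    continue  # window outside signal -> skipped, not an error
                if stat == "mean":
                    vals.append((csum[i1] - csum[i0]) / (i1 - i0))
                else:
                    vals.append(reducer(amp2[i0:i1]))
            if vals:
                out[b, p] = np.mean(vals) / med
    return out


def wrap_angle(a):
    """Wrap angles to (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    w = -(np.mod(-a + np.pi, 2 * np.pi) - np.pi)
    return w if w.ndim else float(w)
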