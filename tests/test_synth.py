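import numpy as np
import pytest
from scipy.signal import periodogram
from scipy.stats import chisquare

from spikegamma.circular import circular_mean
from spikegamma.coupling import plv
from spikegamma.synth import (SyntheticConfig, make_cohort,
                              make_trial_schedule, sample_spikes,
                              synthesize_lfp, synthesize_wideband)
from spikegamma.timefreq import wrap_angle


def _schedule(rng, n_per_side=500):
    cfg = SyntheticConfig(n_trials_per_side=n_per_side)
    return make_trial_schedule(cfg, rng), cfg


class TestSchedule:
    def test_timing_constraints_hold_at_scale(self, rng):
        sched, _ = _schedule(rng, 500)  # 1000 trials
        delay = sched["go_on_s"] - sched["cue_on_s"]
        assert np.all((delay >= 1.0) & (delay <= 2.0))
        assert np.all(sched.loc[sched["valid"] == 1, "rt_s"] <= 2.0)
        assert np.all(np.diff(sched["cue_on_s"]) > 0)
        # RT distribution honours the configured moments
        assert sched["rt_s"].mean() == pytest.approx(0.53, abs=0.05)

    def test_sides_balanced_and_randomized(self, rng):
        sched, _ = _schedule(rng, 100)
        assert (sched["side"] == "contra").sum() == 100
        runs = (sched["side"] != sched["side"].shift()).sum()
        assert runs > 50  # not blocked

    def test_fixed_seed_reproducible(self):
        cfg = SyntheticConfig(n_trials_per_side=20)
        s1 = make_trial_schedule(cfg, np.random.default_rng(3))
        s2 = make_trial_schedule(cfg, np.random.default_rng(3))
        assert s1.equals(s2)


class TestLfp:
    @pytest.fixture(scope="class")
    def lfp(self):
        cfg = SyntheticConfig(n_trials_per_side=12)
        rng = np.random.default_rng(8)
        sched = make_trial_schedule(cfg, rng)
        channels, phase, dur = synthesize_lfp(sched, cfg, rng)
        return cfg, sched, channels, phase

    def _band_power_ratio(self, x, sched, side, fs=1000.0, band=(60, 80)):
        from spikegamma.timefreq import bandpass_two_pass
        g = bandpass_two_pass(x, fs, *band)
        p_burst, p_pre = [], []
        rows = sched[sched["side"] == side]
        for r in rows.itertuples():
            b0, b1 = int((r.grip_on_s - 0.1) * fs), int((r.grip_on_s + 0.4) * fs)
            a0, a1 = int((r.cue_on_s - 1.0) * fs), int((r.cue_on_s - 0.5) * fs)
            p_burst.append(np.mean(g[b0:b1] ** 2))
            p_pre.append(np.mean(g[a0:a1] ** 2))
        return np.mean(p_burst) / np.mean(p_pre)

    def test_contra_burst_raises_gamma_power_ipsi_does_not(self, lfp):
        cfg, sched, channels, _ = lfp
        x = channels[cfg.gamma_contact]
        assert self._band_power_ratio(x, sched, "contra") > 2.0
        assert self._band_power_ratio(x, sched, "ipsi") == pytest.approx(
            1.0, abs=0.5)

    def test_gamma_confined_to_one_contact(self, lfp):
        cfg, sched, channels, _ = lfp
        ratios = [self._band_power_ratio(channels[c], sched, "contra")
                  for c in range(cfg.n_contacts)]
        assert int(np.argmax(ratios)) == cfg.gamma_contact
        others = [r for c, r in enumerate(ratios) if c != cfg.gamma_contact]
        assert max(others) < 1.5

    def test_gamma_channel_spectrum_peaks_in_band(self, lfp):
        cfg, sched, channels, _ = lfp
        f, pxx = periodogram(channels[cfg.gamma_contact], fs=1000.0)
        sel = f > 40
        fpeak = f[sel][np.argmax(pxx[sel])]
        assert 60 <= fpeak <= 80

    def test_beta_suppressed_then_rebounds(self, lfp):
        cfg, sched, channels, _ = lfp
        from spikegamma.timefreq import bandpass_two_pass
        fs = 1000.0
        b = bandpass_two_pass(channels[0], fs, *cfg.beta_band)
        move, rebound, base = [], [], []
        for r in sched.itertuples():
            move.append(np.mean(
                b[int(r.go_on_s * fs):int(r.grip_off_s * fs)] ** 2))
            rebound.append(np.mean(
                b[int((r.grip_off_s + 0.15) * fs):
                  int((r.grip_off_s + 0.65) * fs)] ** 2))
            base.append(np.mean(
                b[int((r.cue_on_s - 1.0) * fs):int(r.cue_on_s * fs)] ** 2))
        assert np.mean(move) < 0.5 * np.mean(base)
        assert np.mean(rebound) > 1.2 * np.mean(base)


class TestSpikes:
    FS = 1000.0

    def _phase(self, dur, rng):
        n = int(dur * self.FS)
        t = np.arange(n) / self.FS
        return np.angle(np.exp(1j * (2 * np.pi * 70 * t + rng.uniform(0, 7))))

    def test_m_zero_plv_squared_matches_uniform_expectation(self, rng):
        phase = self._phase(30, rng)
        vals = []
        for _ in range(1000):
            sp = sample_spikes(phase, 10.0, 0.0, 0.0, rng, self.FS)
            idx = np.minimum((sp * self.FS).astype(int), len(phase) - 1)
            ph = phase[idx]
            if len(ph) > 10:
                vals.append((plv(ph) ** 2, len(ph)))
        mean_plv2 = np.mean([v for v, _ in vals])
        mean_inv_n = np.mean([1 / n for _, n in vals])
        assert mean_plv2 == pytest.approx(mean_inv_n, rel=0.15)

    @pytest.mark.parametrize("m", [0.2, 0.5, 0.8])
    def test_plv_converges_to_m_over_2(self, m, rng):
        phase = self._phase(600, rng)
        sp = sample_spikes(phase, 10.0, m, 1.0, rng, self.FS)
        assert len(sp) >= 5000
        idx = np.minimum((sp * self.FS).astype(int), len(phase) - 1)
        assert plv(phase[idx]) == pytest.approx(m / 2, abs=0.02)

    def test_circular_mean_recovers_mu(self, rng):
        phase = self._phase(300, rng)
        mu = -2.0
        sp = sample_spikes(phase, 10.0, 0.6, mu, rng, self.FS)
        sp = sp[:2000]
        idx = np.minimum((sp * self.FS).astype(int), len(phase) - 1)
        est = circular_mean(phase[idx])
        assert abs(wrap_angle(est - mu)) < 0.1

    def test_spike_phase_histogram_matches_cardioid_density(self, rng):
        """Chi-squared goodness of fit of the spike-phase histogram against
        (1 + m cos(theta - mu)) / 2pi at n = 10^4."""
        m, mu = 0.5, 0.8
        phase = self._phase(1200, rng)
        sp = sample_spikes(phase, 10.0, m, mu, rng, self.FS)
        idx = np.minimum((sp * self.FS).astype(int), len(phase) - 1)
        ph = phase[idx][:10_000]
        edges = np.linspace(-np.pi, np.pi, 21)
        obs, _ = np.histogram(ph, bins=edges)
        centres = (edges[:-1] + edges[1:]) / 2
        expected = len(ph) * (1 + m * np.cos(centres - mu)) * np.diff(edges) \
            / (2 * np.pi)
        expected *= obs.sum() / expected.sum()
        assert chisquare(obs, expected).pvalue > 0.01

    def test_m_outside_unit_interval_rejected(self, rng):
        phase = self._phase(1, rng)
        with pytest.raises(ValueError):
            sample_spikes(phase, 10.0, 1.2, 0.0, rng, self.FS)


class TestWideband:
    def test_envelope_modulation_depth_recovered(self, rng):
        fs_lo, fs_hi, d = 1000.0, 30000.0, 0.3
        t = np.arange(int(20 * fs_lo)) / fs_lo
        phase = np.angle(np.exp(1j * 2 * np.pi * 70 * t))
        wb = synthesize_wideband(phase, "peak", rng, depth=d)
        from spikegamma.phase_bins import compute_hfa
        hfa = compute_hfa(wb, fs_hi)
        n = min(len(hfa), len(phase))
        # envelope regression: hfa ~ a + b cos(phase); depth = b / a
        X = np.column_stack([np.ones(n), np.cos(phase[:n])])
        coef, *_ = np.linalg.lstsq(X, hfa[:n], rcond=None)
        assert coef[1] / coef[0] == pytest.approx(d, rel=0.2)

    def test_polarity_flips_envelope_phase(self, rng):
        fs_lo = 1000.0
        t = np.arange(int(10 * fs_lo)) / fs_lo
        phase = np.angle(np.exp(1j * 2 * np.pi * 70 * t))
        from spikegamma.phase_bins import compute_hfa
        hpk = compute_hfa(synthesize_wideband(phase, "peak", rng), 30000.0)
        htr = compute_hfa(synthesize_wideband(phase, "trough", rng), 30000.0)
        n = min(len(hpk), len(phase))
        c = np.cos(phase[:n])
        assert np.corrcoef(c, hpk[:n])[0, 1] > 0.3
        assert np.corrcoef(c, htr[:n])[0, 1] < -0.3


class TestCohort:
    def test_ipsi_offset_realized_in_expectation(self):
        cfg = SyntheticConfig(n_recordings=3, n_trials_per_side=10,
                              coupling_depth=0.8, include_wideband=False,
                              seed=21)
        recs, truths = make_cohort(cfg, keep_gamma_phase=True)
        for rec, tr in zip(recs, truths):
            assert abs(wrap_angle(tr.mu_ipsi - tr.mu_contra - np.pi)) < 1e-9

    def test_cohort_reproducible_for_fixed_seed(self):
        cfg = SyntheticConfig(n_recordings=2, n_trials_per_side=8,
                              include_wideband=False, seed=5)
        r1, _ = make_cohort(cfg)
        r2, _ = make_cohort(cfg)
        assert np.array_equal(r1[0].spike_train.times, r2[0].spike_train.times)
        assert np.array_equal(r1[1].lfp[0].samples, r2[1].lfp[0].samples)
        assert r1[0].trials.equals(r2[0].trials)
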