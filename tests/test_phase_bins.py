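import numpy as np
import pytest

from spikegamma.phase_bins import (binned_spike_probability,
                                   circular_moving_average, compare_bins,
                                   compute_hfa, hfa_phase_profile,
                                   standardize_polarity)
from spikegamma.synth import sample_spikes, synthesize_wideband
from spikegamma.timefreq import wrap_angle
from tests.test_coupling import make_trials

FS = 1000.0
FS_WB = 30000.0


class TestHfa:
    def test_hfa_tracks_amplitude_modulation(self, rng):
        n = int(10 * FS_WB)
        t = np.arange(n) / FS_WB
        env = 1 + 0.5 * np.cos(2 * np.pi * 70 * t)
        from spikegamma.timefreq import highpass_two_pass
        noise = highpass_two_pass(rng.standard_normal(n), FS_WB, 300.0)
        hfa = compute_hfa(noise * env, FS_WB)
        env_lo = env[:: int(FS_WB / FS)][: len(hfa)]
        core = slice(500, len(hfa) - 500)
        assert np.corrcoef(env_lo[core], hfa[core])[0, 1] > 0.8

    def test_pure_70hz_tone_leaves_no_hfa(self):
        t = np.arange(int(5 * FS_WB)) / FS_WB
        hfa = compute_hfa(np.cos(2 * np.pi * 70 * t), FS_WB)
        assert np.mean(hfa[500:-500] ** 2) < 1e-6

    def test_analytic_variant_agrees_with_rectification(self, rng):
        n = int(8 * FS_WB)
        t = np.arange(n) / FS_WB
        env = 1 + 0.4 * np.cos(2 * np.pi * 70 * t)
        from spikegamma.timefreq import highpass_two_pass
        x = highpass_two_pass(rng.standard_normal(n), FS_WB, 300.0) * env
        h1 = compute_hfa(x, FS_WB, method="rectify")
        h2 = compute_hfa(x, FS_WB, method="analytic")
        core = slice(500, len(h1) - 500)
        assert np.corrcoef(h1[core], h2[core])[0, 1] > 0.95

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            compute_hfa(np.zeros(1000), 500.0)


class TestPolarity:
    def _pair(self, rng, polarity, dur=20.0):
        n = int(dur * FS)
        t = np.arange(n) / FS
        from spikegamma.timefreq import bandpass_two_pass
        g = bandpass_two_pass(rng.standard_normal(n), FS, 60, 80)
        g /= g.std()
        from scipy.signal import hilbert
        phase = np.angle(hilbert(g))
        wb = synthesize_wideband(phase, polarity, rng)
        hfa = compute_hfa(wb, FS_WB)[:n]
        signal = g + 0.3 * rng.standard_normal(n)
        return signal, hfa

    def test_peak_polarity_not_flipped(self, rng):
        sig, hfa = self._pair(rng, "peak")
        _, _, prof = standardize_polarity(sig, hfa, FS)
        assert prof.flip is False

    def test_trough_polarity_flipped(self, rng):
        sig, hfa = self._pair(rng, "trough")
        _, _, prof = standardize_polarity(sig, hfa, FS)
        assert prof.flip is True

    def test_standardization_is_sign_invariant(self, rng):
        """standardize(x) and standardize(-x) give identical phases."""
        sig, hfa = self._pair(rng, "peak")
        s1, p1, _ = standardize_polarity(sig, hfa, FS)
        s2, p2, _ = standardize_polarity(-sig, hfa, FS)
        assert np.allclose(s1, s2)
        assert np.allclose(wrap_angle(p1 - p2), 0.0, atol=1e-9)

    def test_flat_profile_flagged_not_flipped(self, rng):
        n = int(10 * FS)
        sig = np.cos(2 * np.pi * 70 * np.arange(n) / FS)
        hfa = np.ones(n)
        out, _, prof = standardize_polarity(sig, hfa, FS)
        assert prof.flat and not prof.flip
        assert np.array_equal(out, sig)

    def test_circular_smoothing_preserves_mean(self, rng):
        x = rng.standard_normal(126)
        sm = circular_moving_average(x, 20)
        assert sm.mean() == pytest.approx(x.mean(), abs=1e-12)

    def test_hfa_profile_bins_cover_cycle(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 50_000)
        prof = hfa_phase_profile(phase, np.ones_like(phase))
        assert len(prof.bin_centres) == 126
        assert prof.bin_centres[0] == pytest.approx(-np.pi + np.pi / 126)
        assert np.allclose(np.diff(prof.bin_centres), 2 * np.pi / 126)


class TestBinnedProbability:
    def _spiky_recording(self, rng, m, mu, n_trials=10):
        trials = make_trials(n_trials, cue0=6.0)
        n = int((trials["grip_off_s"].max() + 2) * FS)
        t = np.arange(n) / FS
        phase = np.angle(np.exp(1j * 2 * np.pi * 70 * t))
        spikes = sample_spikes(phase, 30.0, m, mu, rng, FS)
        return trials, phase, spikes

    def test_uniform_spiking_gives_quarter_probabilities(self, rng):
        trials, phase, spikes = self._spiky_recording(rng, 0.0, 0.0, 20)
        prof = binned_spike_probability(spikes, phase, FS, trials, "contra")
        assert prof.raw_prob.sum() == pytest.approx(1.0, abs=1e-12)
        assert prof.baseline_prob.sum() == pytest.approx(1.0, abs=1e-12)
        assert prof.rel_change.sum() == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(prof.raw_prob, 0.25, atol=0.12)

    def test_concentrated_spiking_peaks_in_bin_containing_mu(self, rng):
        trials, phase, spikes = self._spiky_recording(rng, 0.9, 0.8)
        prof = binned_spike_probability(spikes, phase, FS, trials, "contra")
        # mu = 0.8 lies in bin [pi/2 wide] number 3 of edges -pi..pi
        assert np.argmax(prof.raw_prob) == np.digitize(0.8, prof.edges) - 1

    @pytest.mark.parametrize("mu", np.linspace(-np.pi * 7 / 8, np.pi * 7 / 8, 8))
    def test_max_bin_tracks_mu_around_the_circle(self, mu, rng):
        trials, phase, spikes = self._spiky_recording(rng, 0.95, mu)
        prof = binned_spike_probability(spikes, phase, FS, trials, "contra",
                                        k=4)
        assert np.argmax(prof.raw_prob) == np.digitize(wrap_angle(mu),
                                                       prof.edges) - 1

    def test_five_bin_variant(self, rng):
        trials, phase, spikes = self._spiky_recording(rng, 0.5, 0.0)
        prof = binned_spike_probability(spikes, phase, FS, trials, "contra",
                                        k=5)
        assert len(prof.raw_prob) == 5
        assert prof.raw_prob.sum() == pytest.approx(1.0)

    def test_empty_window_returns_none(self, rng):
        trials, phase, _ = self._spiky_recording(rng, 0.0, 0.0)
        few = np.array([0.5])  # no spike near any grip
        assert binned_spike_probability(few, phase, FS, trials, "contra") is None


class TestCompareBins:
    def _profiles(self, rng, mu_c, mu_i, n_rec=20, m=0.7, n_spk=400):
        rel_c, rel_i = [], []
        edges = np.linspace(-np.pi, np.pi, 5)
        for _ in range(n_rec):
            pc = rng.vonmises(mu_c, 2 * m, n_spk)
            pi_ = rng.vonmises(mu_i, 2 * m, n_spk)
            base = rng.uniform(-np.pi, np.pi, n_spk)
            h = lambda a: np.histogram(a, bins=edges)[0] / n_spk
            rel_c.append(h(pc) - h(base))
            rel_i.append(h(pi_) - h(base))
        return np.stack(rel_c), np.stack(rel_i)

    def test_opposite_preferences_differ_in_opposite_bin(self, rng):
        rel_c, rel_i = self._profiles(rng, 0.8, 0.8 - np.pi, n_rec=28)
        df = compare_bins(rel_c, rel_i)
        between = df[df["family"] == "between_sides"]
        # the bin holding the contra preference and its antipode both differ
        bin_c = np.digitize(0.8, np.linspace(-np.pi, np.pi, 5))
        row = between[between["a"] == f"contra_bin{bin_c}"]
        assert bool(row["significant"].iloc[0])

    def test_null_fdr_calibration(self, rng):
        hits = []
        for _ in range(20):
            rel_c, rel_i = self._profiles(rng, 0.0, 0.0, n_rec=12, m=0.0)
            df = compare_bins(rel_c, rel_i)
            hits.append(df["significant"].sum())
        assert np.mean(hits) < 1.0  # few false discoveries across 16 tests

    def test_swapping_sides_flips_between_side_statistics(self, rng):
        rel_c, rel_i = self._profiles(rng, 0.5, -0.5, n_rec=10)
        d1 = compare_bins(rel_c, rel_i)
        d2 = compare_bins(rel_i, rel_c)
        b1 = d1[d1["family"] == "between_sides"]["stat"].to_numpy()
        b2 = d2[d2["family"] == "between_sides"]["stat"].to_numpy()
        # t statistics flip sign exactly; Wilcoxon statistics change role
        tmask = (d1[d1["family"] == "between_sides"]["test"] == "t").to_numpy()
        assert np.allclose(b1[tmask], -b2[tmask])
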