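"""Coherence, envelope, phase and phase-locking tests."""

import numpy as np
import pytest
from scipy import signal as sp_signal

from slowsync import coupling as cp
from slowsync.synthgen import LfpComponent, LfpSpec, carrier_phase, gen_coupled_lfp, gen_vonmises_spikes
from slowsync.types import EnvelopeSeries, PhaseSeries

from conftest import brute_welch_msc


class TestPowerCoherence:
    def test_self_coherence_is_one(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(4000)
        coh = cp.power_coherence(x, x, 100.0)
        assert np.all(coh.msc > 1 - 1e-9)

    def test_independent_noise_bias_matches_bruteforce(self):
        rng = np.random.default_rng(1)
        fs = 100.0
        x = rng.standard_normal(6000)
        y = rng.standard_normal(6000)
        coh = cp.power_coherence(x, y, fs)
        freqs_b, msc_b, k = brute_welch_msc(x, y, fs, nperseg=200, noverlap=100)
        np.testing.assert_allclose(coh.frequencies, freqs_b)
        np.testing.assert_allclose(coh.msc, msc_b, atol=1e-10)
        assert coh.msc[1:].mean() == pytest.approx(1.0 / coh.n_segments, rel=0.5)

    def test_common_tone_matches_closed_form(self):
        # msc(f) = Ps^2 / ((Ps+P1)(Ps+P2)) at the tone bin
        fs, dur = 100.0, 400.0
        t = np.arange(int(fs * dur)) / fs
        rng = np.random.default_rng(2)
        s = np.cos(2 * np.pi * 1.0 * t)
        e1 = rng.standard_normal(t.size)
        e2 = 1.5 * rng.standard_normal(t.size)
        coh = cp.power_coherence(s + e1, s + e2, fs)
        nperseg = int(2 * fs)
        f, ps = sp_signal.welch(s, fs, nperseg=nperseg)
        _, p1 = sp_signal.welch(e1, fs, nperseg=nperseg)
        _, p2 = sp_signal.welch(e2, fs, nperseg=nperseg)
        i = np.argmin(np.abs(f - 1.0))
        expected = ps[i] ** 2 / ((ps[i] + p1[i]) * (ps[i] + p2[i]))
        assert coh.msc[np.argmin(np.abs(coh.frequencies - 1.0))] == pytest.approx(
            expected, rel=0.10
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            cp.power_coherence(np.zeros(1000), np.zeros(999), 100.0)


class TestGammaEnvelope:
    FS = 200.0

    def test_am_modulation_peak_recovered(self):
        t = np.arange(int(120 * self.FS)) / self.FS
        x = (1 + 0.8 * np.cos(2 * np.pi * 0.1 * t)) * np.cos(2 * np.pi * 50.0 * t)
        env = cp.gamma_envelope(x, self.FS)
        assert env.step == pytest.approx(0.5)
        freqs, pxx = cp.envelope_spectrum(env, correct_one_over_f=False)
        sel = (freqs > 0.02) & (freqs < 0.5)
        peak = freqs[sel][np.argmax(pxx[sel])]
        assert peak == pytest.approx(0.10, abs=0.02)

    def test_constant_tone_envelope_flat(self):
        t = np.arange(int(90 * self.FS)) / self.FS
        env = cp.gamma_envelope(np.cos(2 * np.pi * 50.0 * t), self.FS)
        assert env.power.std() / env.power.mean() < 0.05

    def test_one_over_f_corrected_spectrum_flat(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(int(300 * self.FS))
        env = cp.gamma_envelope(x, self.FS)
        freqs, pxx = cp.envelope_spectrum(env, correct_one_over_f=True)
        pos = (freqs > 0) & (pxx > 0)
        slope = np.polyfit(np.log10(freqs[pos]), np.log10(pxx[pos]), 1)[0]
        assert abs(slope) < 0.1

    def test_short_record_rejected(self):
        with pytest.raises(ValueError, match="60 s"):
            cp.gamma_envelope(np.zeros(int(30 * self.FS)), self.FS)


class TestUltraslowCoherence:
    def _envelopes(self, shared_amp, seed=0, dur=600.0):
        rng = np.random.default_rng(seed)
        n = int(dur * 2)  # 0.5 s steps
        t = np.arange(n) * 0.5
        shared = shared_amp * (1 + np.cos(2 * np.pi * 0.1 * t))
        e1 = EnvelopeSeries(power=shared + rng.uniform(0.5, 1.5, n))
        e2 = EnvelopeSeries(power=shared + rng.uniform(0.5, 1.5, n))
        return e1, e2

    def test_identical_envelopes_give_unit_coherence(self):
        e1, _ = self._envelopes(1.0)
        assert cp.ultraslow_envelope_coherence(e1, e1) == pytest.approx(1.0, abs=1e-9)

    def test_independent_envelopes_near_bias_level(self):
        vals = []
        for seed in range(30):
            e1, e2 = self._envelopes(0.0, seed=seed)
            vals.append(cp.ultraslow_envelope_coherence(e1, e2))
        # 600 s of 0.5 s steps in 50 s segments, 50% overlap -> K ~ 23
        assert np.mean(vals) < 3.0 / 20
        assert np.mean(vals) > 0.005

    def test_shared_modulation_concentrates_in_band(self):
        e1, e2 = self._envelopes(2.0, seed=1)
        fs = e1.sampling_rate
        coh = cp.power_coherence(
            e1.power - e1.power.mean(), e2.power - e2.power.mean(), fs, segment_s=50.0
        )
        in_band = coh.band_value((0.02, 0.5), reducer=np.mean)
        out_band = coh.band_value((0.5, 1.0), reducer=np.mean)
        assert in_band > 2 * out_band


class TestInstantaneousPhase:
    def test_phase_zero_at_peaks_pi_at_troughs(self):
        fs = 250.0
        t = np.arange(int(60 * fs)) / fs
        x = np.cos(2 * np.pi * 2.0 * t)
        phase = cp.instantaneous_phase(x, fs, (1.0, 4.0))
        peaks = (np.arange(5, 115) / 2.0 * fs).astype(int)  # t = k/2
        troughs = ((np.arange(5, 115) / 2.0 + 0.25) * fs).astype(int)
        assert np.all(np.abs(phase.phase[peaks]) < 0.05)
        assert np.all(np.abs(np.abs(phase.phase[troughs]) - np.pi) < 0.05)

    def test_pure_tone_phase_advances_linearly(self):
        fs = 250.0
        t = np.arange(int(30 * fs)) / fs
        phase = cp.instantaneous_phase(np.cos(2 * np.pi * 2.0 * t), fs, (1.0, 4.0))
        mid = slice(int(5 * fs), int(25 * fs))
        rate = np.diff(np.unwrap(phase.phase[mid])) * fs
        assert np.median(rate) == pytest.approx(2 * np.pi * 2.0, rel=0.01)

    def test_wrapping_contract(self):
        rng = np.random.default_rng(0)
        phase = cp.instantaneous_phase(rng.standard_normal(5000), 250.0, (1.0, 4.0))
        assert np.all(phase.phase > -np.pi - 1e-12)
        assert np.all(phase.phase <= np.pi + 1e-12)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError, match="band"):
            cp.instantaneous_phase(np.zeros(1000), 100.0, (30.0, 70.0))

    def test_silent_band_flagged_unreliable(self):
        fs = 250.0
        t = np.arange(int(30 * fs)) / fs
        phase = cp.instantaneous_phase(np.cos(2 * np.pi * 30.0 * t), fs, (1.0, 4.0))
        assert not phase.reliable


class TestLfpPlv:
    def _phase(self, values, fs=100.0):
        return PhaseSeries(phase=np.asarray(values), sampling_rate=fs)

    def test_identical_phases_give_one(self):
        rng = np.random.default_rng(0)
        p = self._phase(rng.uniform(-np.pi, np.pi, 500))
        assert cp.lfp_plv(p, p).plv == pytest.approx(1.0, abs=1e-12)

    def test_constant_offset_gives_one(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(-np.pi, np.pi, 500)
        res = cp.lfp_plv(self._phase(base + 0.7), self._phase(base))
        assert res.plv == pytest.approx(1.0, abs=1e-12)
        assert res.preferred_phase == pytest.approx(0.7, abs=1e-9)

    def test_equally_spaced_differences_give_zero(self):
        n = 360
        diffs = np.linspace(-np.pi, np.pi, n, endpoint=False)
        res = cp.lfp_plv(self._phase(diffs), self._phase(np.zeros(n)))
        assert res.plv == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_formula(self):
        # oracle: direct evaluation of (1/N)|sum exp(i(th1-th2))|
        rng = np.random.default_rng(2)
        for n in (3, 17, 250, 1000):
            th1 = rng.uniform(-np.pi, np.pi, n)
            th2 = rng.uniform(-np.pi, np.pi, n)
            brute = np.abs(np.sum(np.exp(1j * (th1 - th2)))) / n
            res = cp.lfp_plv(self._phase(th1), self._phase(th2))
            assert abs(res.plv - brute) < 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            cp.lfp_plv(self._phase(np.zeros(10)), self._phase(np.zeros(11)))

    def test_common_offset_invariance(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(-np.pi, np.pi, 400)
        b = rng.uniform(-np.pi, np.pi, 400)
        r1 = cp.lfp_plv(self._phase(a), self._phase(b))
        r2 = cp.lfp_plv(self._phase(a + 1.1), self._phase(b + 1.1))
        assert r1.plv == pytest.approx(r2.plv, abs=1e-12)


class TestPlvSignificance:
    FS = 125.0

    def test_identical_tone_significant(self):
        t = np.arange(int(40 * self.FS)) / self.FS
        rng = np.random.default_rng(0)
        x = np.cos(2 * np.pi * 2.0 * t) + 0.1 * rng.standard_normal(t.size)
        res = cp.plv_significance(x, x, self.FS, (1.0, 4.0), n_surrogates=50)
        assert res.significant
        assert res.plv > 0.999

    def test_null_rate_within_tolerance(self):
        hits = 0
        reps = 100
        for rep in range(reps):
            rng = np.random.default_rng(1000 + rep)
            x = rng.standard_normal(int(16 * self.FS))
            y = rng.standard_normal(int(16 * self.FS))
            res = cp.plv_significance(
                x, y, self.FS, (1.0, 4.0), n_surrogates=39, rng_seed=rep
            )
            hits += bool(res.significant)
        assert hits / reps <= 0.075

    def test_plv_below_floor_never_significant(self):
        # weak stochastic common drive: PLV beats the surrogate null but not
        # the 0.1 floor, so the conjunctive rule says not significant
        n = int(240 * self.FS)
        rng = np.random.default_rng(42)
        sos = sp_signal.butter(
            3, [1.0 / 62.5, 4.0 / 62.5], btype="band", output="sos"
        )
        s = sp_signal.sosfiltfilt(sos, rng.standard_normal(n))
        s /= s.std()
        x = 0.08 * s + rng.standard_normal(n)
        y = 0.08 * s + rng.standard_normal(n)
        res = cp.plv_significance(x, y, self.FS, (1.0, 4.0), n_surrogates=50, rng_seed=1)
        assert res.plv > res.surrogate_percentile_95
        assert res.plv < 0.1
        assert res.significant is False

    def test_too_few_surrogates_rejected(self):
        with pytest.raises(ValueError, match="20 surrogates"):
            cp.plv_significance(np.ones(100), np.ones(100), 100.0, (1, 4), n_surrogates=5)

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cp.plv_significance(
                np.ones(10000), np.random.default_rng(0).standard_normal(10000),
                100.0, (1, 4), n_surrogates=20,
            )


class TestPreferredPhaseDifference:
    def test_quarter_cycle_lag(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(-np.pi, np.pi, 1000)
        p1 = PhaseSeries(phase=base + np.pi / 2, sampling_rate=100.0)
        p2 = PhaseSeries(phase=base, sampling_rate=100.0)
        mean, r, ok = cp.preferred_phase_difference(p1, p2)
        assert mean == pytest.approx(np.pi / 2, abs=1e-9)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_zero_lag(self):
        base = np.linspace(-np.pi, np.pi, 500)
        p = PhaseSeries(phase=base, sampling_rate=100.0)
        mean, r, ok = cp.preferred_phase_difference(p, p)
        assert mean == pytest.approx(0.0, abs=1e-12)

    def test_antipodal_mixture_unreliable(self):
        diffs = np.concatenate([np.zeros(500), np.full(500, np.pi)])
        p1 = PhaseSeries(phase=diffs, sampling_rate=100.0)
        p2 = PhaseSeries(phase=np.zeros(1000), sampling_rate=100.0)
        mean, r, ok = cp.preferred_phase_difference(p1, p2)
        assert r < 0.05
        assert not ok

    @pytest.mark.parametrize("lag", [0.0, np.pi / 4, np.pi / 2, np.pi])
    def test_injected_lag_recovery_at_snr_3(self, lag):
        fs = 250.0
        spec = LfpSpec(
            components=[LfpComponent(2.0, 1.0, phase_offsets=(lag, 0.0))],
            noise_sd=0.33,
            duration=120.0,
            sampling_rate=fs,
            n_channels=2,
            rng_seed=17,
        )
        sig = gen_coupled_lfp(spec)
        p1 = cp.instantaneous_phase(sig.samples[0], fs, (1.0, 4.0))
        p2 = cp.instantaneous_phase(sig.samples[1], fs, (1.0, 4.0))
        mean, r, ok = cp.preferred_phase_difference(p1, p2)
        err = np.angle(np.exp(1j * (mean - lag)))
        assert abs(err) < 0.1


class TestSpikePhaseLocking:
    def test_single_phase_gives_one(self):
        fs = 1000.0
        phase = carrier_phase(1.0, 10.0, fs)
        spikes = np.arange(10) + 0.0  # exactly at phase 0
        res, hist, edges = cp.spike_phase_locking(spikes, phase)
        assert res.plv == pytest.approx(1.0, abs=1e-9)

    def test_uniform_grid_gives_zero(self):
        fs = 1000.0
        phase = carrier_phase(1.0, 10.0, fs)
        spikes = np.arange(0, 10, 1.0 / 16)  # 16 equally spaced phases/cycle
        res, _, _ = cp.spike_phase_locking(spikes, phase)
        assert res.plv < 1e-9

    def test_histogram_normalized(self):
        phase = carrier_phase(1.0, 20.0, 1000.0)
        train = gen_vonmises_spikes(phase, 500, 2.0, 0.5, rng_seed=0)
        _, hist, edges = cp.spike_phase_locking(train, phase, n_bins=18)
        assert hist.sum() == pytest.approx(1.0)
        assert np.all(hist >= 0)
        assert edges.size == 19

    def test_fewer_than_two_spikes_rejected(self):
        phase = carrier_phase(1.0, 10.0, 1000.0)
        with pytest.raises(ValueError, match="two spikes"):
            cp.spike_phase_locking(np.array([1.0]), phase)

    def test_plv_monotone_in_kappa(self):
        phase = carrier_phase(2.0, 500.0, 100.0)
        plvs = []
        for kappa in (0.0, 0.5, 2.0, 20.0):
            train = gen_vonmises_spikes(phase, 10_000, kappa, np.pi, rng_seed=5)
            res, _, _ = cp.spike_phase_locking(train, phase)
            plvs.append(res.plv)
        assert np.all(np.diff(plvs) > 0)
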