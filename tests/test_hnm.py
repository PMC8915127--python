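import numpy as np
import pytest
from scipy.signal import butter, lfilter, sosfiltfilt

import cryextract as ce
from cryextract.audio_io import AudioInputError
from cryextract.f0 import F0Track
from cryextract.hnm import (
    HnmFrameResult,
    HnmSegmentResult,
    frame_spectrum_mfcc,
    harmonic_signal,
)

FS = 24_000


def make_frame_result(f0, amps, phases, gain=0.0, lpc=None, mfcc=None):
    amps = np.asarray(amps, dtype=float)
    return HnmFrameResult(
        f0_hz=f0,
        n_harmonics=amps.size,
        harmonic_amplitudes=amps,
        harmonic_phases=np.asarray(phases, dtype=float),
        max_voiced_frequency_hz=750.0,
        noise_gain=gain,
        noise_filter_coeffs=lpc if lpc is not None else np.zeros(20),
        mfcc=mfcc if mfcc is not None else np.zeros(16),
    )


class TestHarmonicFit:
    def test_exact_recovery_of_two_harmonics(self):
        t = np.arange(480) / FS
        x = 0.7 * np.cos(2 * np.pi * 300 * t) + 0.2 * np.cos(2 * np.pi * 600 * t + 1.0)
        amps, phases, K = ce.fit_harmonic_part(x, 300.0, 750.0, FS)
        assert K == 2
        assert np.allclose(amps, [0.7, 0.2], atol=1e-3)
        assert abs(phases[1] - 1.0) < 1e-3

    def test_machine_precision_on_in_model_frames(self, rng):
        # noiseless frame-constant signals are in the least-squares span
        for _ in range(5):
            f0 = rng.uniform(160, 370)
            K_true = int(750 // f0)
            amps_t = rng.uniform(0.05, 0.5, K_true)
            phs_t = rng.uniform(-np.pi, np.pi, K_true)
            x = harmonic_signal(amps_t, phs_t, f0, 600, FS)
            amps, phases, K = ce.fit_harmonic_part(x, f0, 750.0, FS)
            assert K == K_true
            assert np.allclose(amps, amps_t, atol=1e-9)
            dphi = np.angle(np.exp(1j * (phases - phs_t)))
            assert np.allclose(dphi, 0.0, atol=1e-8)

    def test_zero_frame_gives_zero_amplitudes(self):
        amps, _, _ = ce.fit_harmonic_part(np.zeros(480), 300.0, 750.0, FS)
        assert np.allclose(amps, 0.0, atol=1e-12)

    def test_noisy_recovery_within_tolerance(self):
        rng = np.random.default_rng(42)
        t = np.arange(480) / FS
        x = 0.7 * np.cos(2 * np.pi * 300 * t) + 0.2 * np.cos(2 * np.pi * 600 * t + 1.0)
        sigma = np.sqrt(np.mean(x**2) / 10**2)  # 20 dB SNR
        amps, _, _ = ce.fit_harmonic_part(x + sigma * rng.standard_normal(480), 300.0, 750.0, FS)
        assert np.all(np.abs(amps - [0.7, 0.2]) <= 0.05)

    def test_invalid_f0_rejected(self):
        with pytest.raises(AudioInputError):
            ce.fit_harmonic_part(np.zeros(480), 0.0, 750.0, FS)
        with pytest.raises(AudioInputError):
            ce.fit_harmonic_part(np.zeros(480), 800.0, 750.0, FS)


class TestNoiseFit:
    def test_white_noise_gain_and_flat_filter(self):
        rng = np.random.default_rng(0)
        gain, coeffs = ce.fit_noise_part(0.1 * rng.standard_normal(5000))
        assert abs(gain - 0.1) <= 0.01
        assert np.max(np.abs(coeffs)) < 0.1

    def test_ar2_pole_recovery(self):
        rng = np.random.default_rng(1)
        true_a = np.array([1.0, -1.5, 0.7])
        x = lfilter([1.0], true_a, rng.standard_normal(20000))
        _, a = ce.fit_noise_part(x, order=2)
        poles_t = np.roots(true_a)
        poles_e = np.roots(np.concatenate(([1.0], a)))
        poles_e = poles_e[np.argsort(np.angle(poles_e))]
        poles_t = poles_t[np.argsort(np.angle(poles_t))]
        assert np.all(np.abs(np.abs(poles_e) / np.abs(poles_t) - 1) < 0.05)
        assert np.all(np.abs(np.angle(poles_e) - np.angle(poles_t)) < 0.05 * np.abs(np.angle(poles_t)))

    def test_zero_residual_gives_zero_gain(self):
        gain, coeffs = ce.fit_noise_part(np.zeros(500))
        assert gain == 0.0
        assert np.allclose(coeffs, 0.0)

    def test_empty_residual_rejected(self):
        with pytest.raises(AudioInputError):
            ce.fit_noise_part(np.zeros(0))


class TestMfcc:
    def test_deterministic(self):
        a = ce.harmonic_mfcc(np.array([0.7, 0.2]), 300.0)
        b = ce.harmonic_mfcc(np.array([0.7, 0.2]), 300.0)
        assert np.array_equal(a, b)

    def test_amplitude_scaling_shifts_only_c0(self):
        m1 = ce.harmonic_mfcc(np.array([0.7, 0.2, 0.1]), 250.0)
        m2 = ce.harmonic_mfcc(np.array([7.0, 2.0, 1.0]), 250.0)
        assert abs(m2[0] - m1[0]) > 1.0
        assert np.max(np.abs(m2[1:] - m1[1:])) < 1e-9

    def test_flat_envelope_concentrates_in_c0(self):
        m = ce.harmonic_mfcc(np.array([0.5, 0.5, 0.5, 0.5]), 180.0)
        assert np.max(np.abs(m[1:])) < 1e-6 * abs(m[0])

    def test_silence_spectrum_defined_for_k0(self):
        m = ce.harmonic_mfcc(np.zeros(0), 300.0)
        assert m.shape == (16,)
        assert np.all(np.isfinite(m))

    def test_frame_spectrum_mfcc_finite(self, rng):
        m = frame_spectrum_mfcc(0.01 * rng.standard_normal(120), FS)
        assert m.shape == (16,) and np.all(np.isfinite(m))


class TestAnalyzeSegment:
    def _track(self, n, f0=300.0):
        times = (np.arange(n) + 0.5) * 0.005
        return F0Track(times, np.full(n, f0), (150.0, 750.0))

    def test_one_second_gives_200_frames(self):
        x = harmonic_signal(np.array([0.3]), np.zeros(1), 300.0, FS, FS)
        res = ce.analyze_segment(ce.AudioRecording("s", x), self._track(200))
        assert len(res) == 200

    def test_silence_is_unvoiced_with_zero_gain(self):
        track = F0Track((np.arange(100) + 0.5) * 0.005, np.full(100, np.nan), (150.0, 750.0))
        res = ce.analyze_segment(ce.AudioRecording("s", np.zeros(FS // 2)), track)
        assert all(not f.voiced for f in res.frames)
        assert all(f.noise_gain == 0.0 for f in res.frames)

    def test_synthetic_cry_mostly_voiced(self):
        x, _ = ce.gen_cry(duration_s=1.0, f0_base_hz=350, vibrato_hz=10, snr_db=30, seed=2)
        rec = ce.AudioRecording("c", x)
        res = ce.analyze_segment(rec, ce.cwt_f0(rec))
        assert np.mean([f.voiced for f in res.frames]) >= 0.8

    def test_grid_mismatch_rejected(self):
        with pytest.raises(AudioInputError):
            ce.analyze_segment(ce.AudioRecording("s", np.zeros(FS)), self._track(50))


class TestSynthesis:
    def test_roundtrip_band_snr(self):
        # harmonics inside the 750 Hz maximum voiced frequency
        x, _ = ce.gen_cry(duration_s=1.0, f0_base_hz=300, vibrato_hz=0,
                          n_harmonics=2, snr_db=30, seed=3)
        rec = ce.AudioRecording("c", x)
        res = ce.analyze_segment(rec, ce.cwt_f0(rec))
        y = ce.synthesize_hnm(res, seed=0)
        n = len(y)
        sos = butter(4, [150, 740], btype="band", fs=FS, output="sos")
        xb, yb = sosfiltfilt(sos, x[:n]), sosfiltfilt(sos, y)
        snr = 10 * np.log10(np.sum(xb**2) / np.sum((xb - yb) ** 2))
        assert snr >= 20

    def test_energy_approximately_conserved(self):
        x, _ = ce.gen_cry(duration_s=1.0, f0_base_hz=320, vibrato_hz=10,
                          n_harmonics=2, snr_db=20, seed=5)
        rec = ce.AudioRecording("c", x)
        res = ce.analyze_segment(rec, ce.cwt_f0(rec))
        y = ce.synthesize_hnm(res, seed=1)
        e_x, e_y = np.sum(x[: len(y)] ** 2), np.sum(y**2)
        assert abs(e_x - e_y) / e_x <= 0.2

    def test_unvoiced_frames_have_zero_harmonic_part(self):
        frames = HnmSegmentResult(
            [make_frame_result(np.nan, [], [], gain=0.05) for _ in range(20)],
            sample_rate_hz=FS,
        )
        noisy = ce.synthesize_hnm(frames, seed=0)
        silent = ce.synthesize_hnm(
            HnmSegmentResult(
                [make_frame_result(np.nan, [], [], gain=0.0) for _ in range(20)],
                sample_rate_hz=FS,
            ),
            seed=0,
        )
        assert np.all(silent == 0.0)  # no gain, no harmonics -> exact zero
        assert np.sum(noisy**2) > 0

    def test_seeded_noise_is_reproducible(self):
        frames = HnmSegmentResult(
            [make_frame_result(np.nan, [], [], gain=0.05) for _ in range(10)],
            sample_rate_hz=FS,
        )
        assert np.array_equal(ce.synthesize_hnm(frames, seed=7), ce.synthesize_hnm(frames, seed=7))
        assert not np.array_equal(ce.synthesize_hnm(frames, seed=7), ce.synthesize_hnm(frames, seed=8))
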