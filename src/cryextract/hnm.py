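"""Harmonic-plus-noise decomposition of quasi-periodic audio segments.

Each segment is modelled frame by frame (5 ms, no overlap) as

    s(t) = h(t) + n(t)
    h(t) = sum_{k=1}^{K} A_k cos(2*pi*k*F0*t + Phi_k)

with the residual n(t) described as white Gaussian noise shaped by a monic
order-P all-pole filter and a gain, and modulated by a triangular energy
envelope at synthesis time.  F0 comes from the wavelet tracker; the number of
harmonics K is bounded by a maximum voiced frequency (default 750 Hz, the top
of the cry analysis band).  Harmonic amplitudes and phases are obtained by
windowed least squares over a span of a few F0 periods centred on the frame,
which is exact on noiseless in-model frames.

MFCCs are computed from the harmonic part: the harmonic line spectrum is
interpolated into a spectral envelope, passed through an area-normalised mel
filterbank, log-compressed and DCT-transformed.  Unvoiced frames use the
frame's own spectrum instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dct, rfft, rfftfreq
from scipy.linalg import solve_toeplitz
from scipy.signal import get_window, lfilter

from .audio_io import AudioInputError, AudioRecording
from .f0 import F0Track, FRAME_S

MAX_VOICED_FREQUENCY_HZ = 750.0
LPC_ORDER = 20
N_MFCC = 16
N_MEL_FILTERS = 26
LOG_FLOOR = 1e-10
ANALYSIS_PERIODS = 4  # analysis window length in F0 periods


@dataclass
class HnmFrameResult:
    """Fitted HNM parameters and MFCCs for one 5 ms frame."""

    f0_hz: float  # NaN when unvoiced
    n_harmonics: int
    harmonic_amplitudes: np.ndarray
    harmonic_phases: np.ndarray
    max_voiced_frequency_hz: float
    noise_gain: float
    noise_filter_coeffs: np.ndarray
    mfcc: np.ndarray

    @property
    def voiced(self) -> bool:
        return self.n_harmonics > 0


@dataclass
class HnmSegmentResult:
    frames: list[HnmFrameResult]
    frame_len_s: float = FRAME_S
    sample_rate_hz: int = 24_000

    def __len__(self) -> int:
        return len(self.frames)


def fit_harmonic_part(
    frame_audio: np.ndarray,
    f0_hz: float,
    max_voiced_frequency_hz: float = MAX_VOICED_FREQUENCY_HZ,
    sample_rate_hz: int = 24_000,
    window: np.ndarray | None = None,
    t0_offset_samples: int = 0,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Least-squares fit of a harmonic sinusoid bank to one frame.

    Returns ``(amplitudes, phases, K)`` with ``K = floor(MVF / f0)``.  Phases
    are referenced to sample index ``t0_offset_samples`` (0 = first sample of
    ``frame_audio``).  An optional analysis window weights the fit.
    """
    if not 0 < f0_hz <= max_voiced_frequency_hz:
        raise AudioInputError(
            f"f0 {f0_hz} Hz outside (0, {max_voiced_frequency_hz}]"
        )
    x = np.asarray(frame_audio, dtype=np.float64)
    K = int(max_voiced_frequency_hz // f0_hz)
    t = (np.arange(x.size) - t0_offset_samples) / sample_rate_hz
    k = np.arange(1, K + 1)
    arg = 2.0 * np.pi * f0_hz * np.outer(t, k)
    basis = np.concatenate([np.cos(arg), np.sin(arg)], axis=1)
    if window is not None:
        w = np.sqrt(np.maximum(window, 0.0))
        coef, *_ = np.linalg.lstsq(basis * w[:, None], x * w, rcond=None)
    else:
        coef, *_ = np.linalg.lstsq(basis, x, rcond=None)
    c, s = coef[:K], coef[K:]
    # A cos(arg + Phi) = A cos(Phi) cos(arg) - A sin(Phi) sin(arg)
    amplitudes = np.hypot(c, s)
    phases = np.arctan2(-s, c)
    return amplitudes, phases, K


def harmonic_signal(
    amplitudes: np.ndarray,
    phases: np.ndarray,
    f0_hz: float,
    n_samples: int,
    sample_rate_hz: int,
    t0_offset_samples: int = 0,
) -> np.ndarray:
    """Evaluate the fitted harmonic sum over ``n_samples``."""
    t = (np.arange(n_samples) - t0_offset_samples) / sample_rate_hz
    k = np.arange(1, amplitudes.size + 1)
    arg = 2.0 * np.pi * f0_hz * np.outer(t, k) + phases
    return (np.cos(arg) * amplitudes).sum(axis=1)


def fit_noise_part(
    residual: np.ndarray, order: int = LPC_ORDER
) -> tuple[float, np.ndarray]:
    """Autocorrelation-method linear prediction of the noise residual.

    Returns ``(gain, a)`` where the monic all-pole filter is
    ``1 / (1 + sum_i a_i z^-i)`` and gain is the prediction-error standard
    deviation.  A constant (or zero) residual yields zero gain and an
    identity filter.
    """
    x = np.asarray(residual, dtype=np.float64)
    if x.size == 0:
        raise AudioInputError("empty residual")
    n = x.size
    order = min(order, n - 1)
    r = np.correlate(x, x, mode="full")[n - 1 : n + order] / n
    if r[0] <= 0 or np.ptp(x) == 0:
        return 0.0, np.zeros(order)
    r0 = r.copy()
    r0[0] *= 1.0 + 1e-9  # ridge for near-singular autocorrelation
    a = solve_toeplitz((r0[:-1], r0[:-1]), -r[1:])
    err = r[0] + float(np.dot(a, r[1:]))
    gain = float(np.sqrt(max(err, 0.0)))
    return gain, a


def _hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def mel_filterbank(
    n_filters: int, n_freqs: int, sample_rate_hz: int
) -> np.ndarray:
    """Area-normalised triangular mel filterbank over [0, Nyquist]."""
    nyquist = sample_rate_hz / 2.0
    mel_pts = np.linspace(0.0, _hz_to_mel(nyquist), n_filters + 2)
    hz_pts = np.asarray(_mel_to_hz(mel_pts))
    freqs = np.linspace(0.0, nyquist, n_freqs)
    bank = np.zeros((n_filters, n_freqs))
    for m in range(n_filters):
        lo, mid, hi = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        up = (freqs - lo) / max(mid - lo, 1e-12)
        down = (hi - freqs) / max(hi - mid, 1e-12)
        tri = np.maximum(0.0, np.minimum(up, down))
        area = tri.sum()
        if area > 0:
            bank[m] = tri / area
    return bank


_N_ENV = 513  # spectral envelope grid points


def _mfcc_from_power(power: np.ndarray, sample_rate_hz: int, n_coeffs: int) -> np.ndarray:
    bank = mel_filterbank(N_MEL_FILTERS, power.size, sample_rate_hz)
    energies = np.maximum(bank @ power, LOG_FLOOR)
    return dct(np.log10(energies), type=2, norm="ortho")[:n_coeffs]


def harmonic_mfcc(
    amplitudes: np.ndarray,
    f0_hz: float,
    n_coeffs: int = N_MFCC,
    sample_rate_hz: int = 24_000,
) -> np.ndarray:
    """MFCCs of the harmonic part's spectral envelope.

    The line spectrum (k*F0, A_k) is linearly interpolated onto a dense grid
    up to Nyquist, with constant extrapolation beyond the first/last harmonic
    so that a uniform amplitude rescaling shifts only coefficient 0.  K = 0
    gives the MFCC of a silence (floor) spectrum.
    """
    nyquist = sample_rate_hz / 2.0
    grid = np.linspace(0.0, nyquist, _N_ENV)
    amplitudes = np.asarray(amplitudes, dtype=np.float64)
    if amplitudes.size == 0:
        envelope = np.zeros(_N_ENV)
    else:
        harm_f = f0_hz * np.arange(1, amplitudes.size + 1)
        envelope = np.interp(grid, harm_f, amplitudes)
    return _mfcc_from_power(envelope**2, sample_rate_hz, n_coeffs)


def frame_spectrum_mfcc(
    frame_audio: np.ndarray, sample_rate_hz: int, n_coeffs: int = N_MFCC
) -> np.ndarray:
    """MFCCs of a raw frame's magnitude spectrum (unvoiced frames)."""
    x = np.asarray(frame_audio, dtype=np.float64)
    w = get_window("hann", x.size)
    spec = np.abs(rfft(x * w, n=2 * (_N_ENV - 1)))[:_N_ENV]
    return _mfcc_from_power(spec**2, sample_rate_hz, n_coeffs)


def _unvoiced_frame(
    frame: np.ndarray, sample_rate_hz: int, order: int = LPC_ORDER
) -> HnmFrameResult:
    gain, a = fit_noise_part(frame, order)
    return HnmFrameResult(
        f0_hz=float("nan"),
        n_harmonics=0,
        harmonic_amplitudes=np.zeros(0),
        harmonic_phases=np.zeros(0),
        max_voiced_frequency_hz=MAX_VOICED_FREQUENCY_HZ,
        noise_gain=gain,
        noise_filter_coeffs=a,
        mfcc=frame_spectrum_mfcc(frame, sample_rate_hz),
    )


def analyze_segment(
    segment_audio: AudioRecording,
    f0_track: F0Track,
    max_voiced_frequency_hz: float = MAX_VOICED_FREQUENCY_HZ,
) -> HnmSegmentResult:
    """Frame-by-frame HNM analysis of a segment on the 5 ms grid.

    Voiced frames (per the F0 track) get a harmonic fit over a window of
    ``ANALYSIS_PERIODS`` F0 periods centred on the frame, a noise fit on the
    in-frame residual, and harmonic-envelope MFCCs.  Unvoiced frames carry
    only the noise model and full-spectrum MFCCs.
    """
    fs = segment_audio.sample_rate_hz
    x = segment_audio.samples
    hop = int(round(FRAME_S * fs))
    n_frames = x.size // hop
    if n_frames < 1:
        raise AudioInputError("segment shorter than one 5 ms frame")
    if abs(f0_track.f0_hz.size - n_frames) > 1:
        raise AudioInputError(
            f"F0 track has {f0_track.f0_hz.size} frames, segment has {n_frames}"
        )
    f0s = f0_track.f0_hz[:n_frames]
    if f0s.size < n_frames:  # track one frame short: extend with unvoiced
        f0s = np.concatenate([f0s, [np.nan]])
    frames = []
    for i in range(n_frames):
        lo, hi = i * hop, (i + 1) * hop
        frame = x[lo:hi]
        f0 = f0s[i]
        if not np.isfinite(f0) or f0 <= 0 or f0 > max_voiced_frequency_hz:
            frames.append(_unvoiced_frame(frame, fs))
            continue
        half_span = int(round(ANALYSIS_PERIODS / f0 * fs / 2))
        centre = lo + hop // 2
        a0 = max(0, centre - half_span)
        a1 = min(x.size, centre + half_span)
        window = get_window("hann", a1 - a0)
        amps, phases, K = fit_harmonic_part(
            x[a0:a1],
            f0,
            max_voiced_frequency_hz,
            fs,
            window=window,
            t0_offset_samples=lo - a0,
        )
        recon = harmonic_signal(amps, phases, f0, hop, fs)
        residual = frame - recon
        gain, lpc = fit_noise_part(residual)
        frames.append(
            HnmFrameResult(
                f0_hz=float(f0),
                n_harmonics=K,
                harmonic_amplitudes=amps,
                harmonic_phases=phases,
                max_voiced_frequency_hz=max_voiced_frequency_hz,
                noise_gain=gain,
                noise_filter_coeffs=lpc,
                mfcc=harmonic_mfcc(amps, f0, sample_rate_hz=fs),
            )
        )
    return HnmSegmentResult(frames=frames, sample_rate_hz=fs)


def synthesize_hnm(
    frames: HnmSegmentResult,
    sample_rate_hz: int | None = None,
    seed: int | None = 0,
) -> np.ndarray:
    """Resynthesise a segment from its per-frame HNM parameters.

    The harmonic part is evaluated per frame from the fitted amplitudes and
    phases; the noise part filters fresh seeded white Gaussian noise through
    each frame's all-pole filter, scales it by the gain and shapes it with a
    unit-RMS triangular envelope.
    """
    fs = sample_rate_hz or frames.sample_rate_hz
    hop = int(round(frames.frame_len_s * fs))
    rng = np.random.default_rng(seed)
    # triangular envelope, scaled to unit RMS so noise energy is preserved
    tri = 1.0 - np.abs(np.linspace(-1.0, 1.0, hop, endpoint=False) + 1.0 / hop)
    tri /= np.sqrt(np.mean(tri**2))
    out = np.zeros(len(frames) * hop)
    for i, fr in enumerate(frames.frames):
        lo = i * hop
        if fr.voiced:
            out[lo : lo + hop] += harmonic_signal(
                fr.harmonic_amplitudes, fr.harmonic_phases, fr.f0_hz, hop, fs
            )
        if fr.noise_gain > 0:
            # gain is the prediction-error sigma, so driving the monic
            # all-pole filter with gain-scaled white noise reproduces the
            # residual's variance (autocorrelation-method identity)
            u = fr.noise_gain * rng.standard_normal(hop)
            shaped = lfilter(
                [1.0], np.concatenate(([1.0], fr.noise_filter_coeffs)), u
            )
            out[lo : lo + hop] += shaped * tri
    return out
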