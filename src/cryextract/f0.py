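"""Fundamental-frequency tracking by continuous wavelet transform.

The F0 of a segment is estimated per 5 ms frame as the frequency, within an
analysis band (default 150-750 Hz, chosen for newborn cries), whose Morlet
wavelet response magnitude is maximal at the frame centre.  Frames whose
maximal response does not stand out against the band (max < ``voicing_ratio``
times the median magnitude across the band) are marked unvoiced.

The CWT is evaluated in the FFT domain: the analytic Morlet wavelet is a
Gaussian in frequency, so each scale is one spectral windowing plus an
inverse FFT, and only the frame-centre columns of the scalogram are kept.
The segment is first decimated to 4 kHz — the band of interest lies well
below 2 kHz — which keeps long segments cheap to analyse.

Tracks can be re-estimated in a caller-chosen band (cries whose first formant
falls inside the default band need a narrower, cry-specific band) and
median-smoothed; smoothing trims the unreliable frames at the edges of each
voiced run.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.fft import fft, ifft, next_fast_len
from scipy.signal import decimate

from .audio_io import AudioInputError, AudioRecording

DEFAULT_BAND_HZ = (150.0, 750.0)
FRAME_S = 0.005
MORLET_W0 = 6.0  # centre angular frequency of the Morlet mother wavelet
ANALYSIS_RATE_HZ = 4000


@dataclass
class F0Config:
    f0_fmin_hz: float = DEFAULT_BAND_HZ[0]
    f0_fmax_hz: float = DEFAULT_BAND_HZ[1]
    voicing_ratio: float = 3.0
    smooth_window_frames: int = 9
    freq_step_hz: float = 1.0


@dataclass
class F0Track:
    """Per-frame F0 estimates on the 5 ms grid; NaN marks unvoiced frames."""

    times_s: np.ndarray
    f0_hz: np.ndarray
    band_hz: tuple[float, float]
    smoothed: bool = False

    @property
    def voiced(self) -> np.ndarray:
        return ~np.isnan(self.f0_hz)

    @property
    def voiced_fraction(self) -> float:
        return float(np.mean(self.voiced)) if self.f0_hz.size else 0.0

    def voiced_median(self) -> float:
        """Median F0 over voiced frames (NaN if fully unvoiced)."""
        v = self.f0_hz[self.voiced]
        return float(np.median(v)) if v.size else float("nan")


def _morlet_scalogram(
    x: np.ndarray, fs: float, freqs_hz: np.ndarray, cols: np.ndarray
) -> np.ndarray:
    """|CWT| of x at the given frequencies, sampled at columns ``cols``.

    Uses the analytic Morlet wavelet, unit-energy (L2) normalised per scale so
    magnitudes are comparable across frequencies.
    """
    n = x.size
    nfft = next_fast_len(2 * n)  # zero padding keeps the circular conv linear
    X = fft(x, nfft)
    omega = 2.0 * np.pi * np.fft.fftfreq(nfft, d=1.0 / fs)
    out = np.empty((freqs_hz.size, cols.size))
    for i, f in enumerate(freqs_hz):
        scale = MORLET_W0 / (2.0 * np.pi * f)
        psi_hat = np.exp(-0.5 * (scale * omega - MORLET_W0) ** 2)
        psi_hat[omega < 0] = 0.0  # analytic wavelet
        coef = ifft(X * psi_hat * np.sqrt(scale))[:n]
        out[i] = np.abs(coef[cols])
    return out


def cwt_f0(
    segment_audio: AudioRecording,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
    config: F0Config | None = None,
) -> F0Track:
    """Track F0 per 5 ms frame as the band frequency of maximal CWT response.

    ``band_hz`` must satisfy 0 < fmin < fmax < Nyquist.  Frames with
    max/median response ratio below the voicing threshold are unvoiced.
    """
    cfg = config or F0Config()
    fmin, fmax = band_hz
    if not (0 < fmin < fmax < segment_audio.sample_rate_hz / 2):
        raise AudioInputError(f"invalid analysis band {band_hz}")
    x = segment_audio.samples
    fs = segment_audio.sample_rate_hz
    if fs > ANALYSIS_RATE_HZ and fs % ANALYSIS_RATE_HZ == 0:
        q = fs // ANALYSIS_RATE_HZ
        if x.size > 27 * q:  # decimate needs enough samples for its IIR filter
            x = decimate(x, q, zero_phase=True)
            fs = ANALYSIS_RATE_HZ
    hop = int(round(FRAME_S * fs))
    n_frames = max(x.size // hop, 1)
    cols = np.minimum(np.arange(n_frames) * hop + hop // 2, x.size - 1)
    freqs = np.arange(fmin, fmax + cfg.freq_step_hz / 2, cfg.freq_step_hz)
    mag = _morlet_scalogram(x, fs, freqs, cols)
    peak = mag.max(axis=0)
    med = np.median(mag, axis=0)
    argmax = mag.argmax(axis=0)
    f0 = freqs[argmax].astype(np.float64)
    unvoiced = peak < cfg.voicing_ratio * np.maximum(med, 1e-300)
    # a maximum at the band edge means the true F0 lies outside the band
    unvoiced |= (argmax == 0) | (argmax == freqs.size - 1)
    f0[unvoiced] = np.nan
    times = (np.arange(n_frames) + 0.5) * FRAME_S
    return F0Track(times_s=times, f0_hz=f0, band_hz=(fmin, fmax))


def band_adapted_f0(
    segment_audio: AudioRecording,
    band_hz: tuple[float, float],
    config: F0Config | None = None,
) -> F0Track:
    """F0 tracking with a caller-chosen (cry-specific) band.

    A narrower band avoids locking onto the first formant when it dominates
    the default band.
    """
    return cwt_f0(segment_audio, band_hz=band_hz, config=config)


def smooth_f0(track: F0Track, window_frames: int = 9) -> F0Track:
    """Running-median smoothing of the voiced parts of a track.

    Within each contiguous voiced run, frames where the full centred window
    fits take the median of the window; the ``window_frames // 2`` frames at
    each run edge are demoted to unvoiced (so short noisy leaders/trailers
    disappear and runs shorter than the window vanish entirely).  Smoothing
    never voices a previously unvoiced frame.
    """
    if window_frames < 3 or window_frames % 2 == 0:
        raise ValueError("window_frames must be odd and >= 3")
    half = window_frames // 2
    f0 = track.f0_hz.copy()
    voiced = ~np.isnan(f0)
    padded = np.concatenate(([False], voiced, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    out = np.full_like(f0, np.nan)
    for i0, i1 in zip(starts, ends):
        if i1 - i0 < window_frames:
            continue
        for j in range(i0 + half, i1 - half):
            out[j] = np.median(f0[j - half : j + half + 1])
    return F0Track(
        times_s=track.times_s.copy(),
        f0_hz=out,
        band_hz=track.band_hz,
        smoothed=True,
    )
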