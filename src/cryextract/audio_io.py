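"""Audio and manifest I/O.

All pipeline stages operate on :class:`AudioRecording`, a mono float waveform
in [-1, 1] at a canonical 24 kHz sample rate.  WAV files at other rates are
resampled on read; integer PCM is rescaled to float.  Segment annotations
travel as CSV manifests with half-open ``[start_s, end_s)`` intervals and one
of seven labels (the six annotation classes plus ``unknown``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

CANONICAL_RATE_HZ = 24_000

#: Annotation classes: baby sounds (cry, vocalisation, baby_noise) and
#: environment sounds (adult, alarm, background); `unknown` = unannotated.
SEGMENT_LABELS = (
    "cry",
    "vocalisation",
    "baby_noise",
    "adult",
    "alarm",
    "background",
    "unknown",
)

MANIFEST_COLUMNS = ("recording_id", "start_s", "end_s", "label")


class AudioInputError(ValueError):
    """Raised for unreadable, empty or out-of-bounds audio inputs."""


@dataclass
class AudioRecording:
    """A mono waveform with its sample rate and an identifier."""

    recording_id: str
    samples: np.ndarray
    sample_rate_hz: int = CANONICAL_RATE_HZ

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise AudioInputError("samples must be one-dimensional (mono)")
        if self.samples.size == 0:
            raise AudioInputError("recording has no samples")
        if self.sample_rate_hz <= 0:
            raise AudioInputError("sample rate must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz

    def slice_time(self, start_s: float, end_s: float, *, segment_id: str | None = None) -> "AudioRecording":
        """Extract ``[start_s, end_s)`` as a new recording (nearest-sample bounds)."""
        i0 = int(round(start_s * self.sample_rate_hz))
        i1 = int(round(end_s * self.sample_rate_hz))
        if i0 < 0 or i1 > self.samples.size or i1 <= i0:
            raise AudioInputError(
                f"segment [{start_s}, {end_s}) outside recording of {self.duration_s:.3f} s"
            )
        return AudioRecording(
            recording_id=segment_id or f"{self.recording_id}[{start_s:.3f}-{end_s:.3f}]",
            samples=self.samples[i0:i1].copy(),
            sample_rate_hz=self.sample_rate_hz,
        )


@dataclass
class SegmentManifestRow:
    """One annotated (or detected) time interval of a recording."""

    recording_id: str
    start_s: float
    end_s: float
    label: str = "unknown"
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start_s < 0 or self.end_s <= self.start_s:
            raise AudioInputError(
                f"invalid interval [{self.start_s}, {self.end_s})"
            )
        if self.label not in SEGMENT_LABELS and self.label != "cry_overlap":
            raise AudioInputError(f"unknown label {self.label!r}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def _to_float(samples: np.ndarray) -> np.ndarray:
    """Rescale integer PCM to [-1, 1]; pass float through."""
    if np.issubdtype(samples.dtype, np.integer):
        info = np.iinfo(samples.dtype)
        scale = float(max(abs(info.min), info.max))
        out = samples.astype(np.float64) / scale
        if info.min == 0:  # unsigned PCM (8-bit WAV) is offset binary
            out = 2.0 * out - 1.0
        return out
    return samples.astype(np.float64)


def read_recording(
    path: str | os.PathLike,
    *,
    recording_id: str | None = None,
    target_rate_hz: int = CANONICAL_RATE_HZ,
) -> AudioRecording:
    """Read a WAV file as a mono, [-1, 1]-scaled recording at ``target_rate_hz``.

    Multi-channel audio is averaged to mono.  Integer PCM is rescaled to
    float.  Files at other sample rates are polyphase-resampled.
    """
    path = Path(path)
    try:
        rate, samples = wavfile.read(path)
    except Exception as exc:  # scipy raises several types for corrupt files
        raise AudioInputError(f"cannot read WAV file {path}: {exc}") from exc
    if samples.size == 0:
        raise AudioInputError(f"{path} contains no audio samples")
    samples = _to_float(np.asarray(samples))
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    if rate != target_rate_hz:
        g = np.gcd(int(target_rate_hz), int(rate))
        samples = resample_poly(samples, target_rate_hz // g, rate // g)
    np.clip(samples, -1.0, 1.0, out=samples)
    return AudioRecording(
        recording_id=recording_id or path.stem,
        samples=samples,
        sample_rate_hz=target_rate_hz,
    )


def write_recording(path: str | os.PathLike, rec: AudioRecording) -> Path:
    """Write a recording as 16-bit PCM WAV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pcm = np.clip(rec.samples, -1.0, 1.0)
    pcm = np.round(pcm * 32767.0).astype(np.int16)
    wavfile.write(path, rec.sample_rate_hz, pcm)
    return path


def read_manifest(path: str | os.PathLike) -> list[SegmentManifestRow]:
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise AudioInputError(f"manifest {path} missing columns {sorted(missing)}")
    rows = []
    for r in df.itertuples(index=False):
        rows.append(
            SegmentManifestRow(
                recording_id=str(r.recording_id),
                start_s=float(r.start_s),
                end_s=float(r.end_s),
                label=str(r.label),
            )
        )
    return rows


def write_manifest(path: str | os.PathLike, rows: list[SegmentManifestRow]) -> Path:
    """Write rows as CSV; times stored with millisecond precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        [
            {
                "recording_id": r.recording_id,
                "start_s": round(r.start_s, 3),
                "end_s": round(r.end_s, 3),
                "label": r.label,
            }
            for r in rows
        ],
        columns=list(MANIFEST_COLUMNS),
    )
    df.to_csv(path, index=False)
    return path


def write_segment_clips(
    rec: AudioRecording,
    segments: list[SegmentManifestRow],
    out_dir: str | os.PathLike,
) -> Path:
    """Write one WAV clip per segment plus a CSV manifest linking them.

    Returns the manifest path.  The manifest gains a ``clip`` column with the
    clip filename relative to ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for i, seg in enumerate(segments):
        if seg.end_s > rec.duration_s + 1e-9:
            raise AudioInputError(
                f"segment [{seg.start_s}, {seg.end_s}) exceeds recording duration"
            )
        clip = rec.slice_time(seg.start_s, min(seg.end_s, rec.duration_s))
        name = f"{rec.recording_id}_{i:04d}_{seg.label}.wav"
        write_recording(out_dir / name, clip)
        records.append(
            {
                "recording_id": seg.recording_id,
                "start_s": round(seg.start_s, 3),
                "end_s": round(seg.end_s, 3),
                "label": seg.label,
                "clip": name,
            }
        )
    manifest_path = out_dir / "segments.csv"
    pd.DataFrame(records, columns=list(MANIFEST_COLUMNS) + ["clip"]).to_csv(
        manifest_path, index=False
    )
    return manifest_path
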