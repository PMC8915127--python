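"""Unsupervised sound-event segmentation by double Otsu energy thresholding.

A short-frame log-energy track is computed over the recording.  A first Otsu
threshold over all frame energies separates silence from sound; a second Otsu
threshold, estimated only on the above-silence frames, separates weak from
strong activity.  Frames above the high threshold seed events, each extended
to the surrounding contiguous run of above-low frames (seed-and-extend).
Detected segments closer than a small gap are merged, and only segments with
durations in a closed interval (default 0.25-5 s, the plausible range of a
single cry event) are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .audio_io import AudioInputError, AudioRecording, SegmentManifestRow

ENERGY_FLOOR_DB = -120.0


class DegenerateInputError(ValueError):
    """Raised when thresholding is requested on constant data."""


@dataclass
class SegmentationConfig:
    frame_len_s: float = 0.010
    hop_s: float = 0.005
    n_bins: int = 256
    min_dur_s: float = 0.25
    max_dur_s: float = 5.0
    merge_gap_s: float = 0.050
    floor_db: float = ENERGY_FLOOR_DB


@dataclass
class EnergyTrack:
    """Per-frame energy in dB on a regular frame grid."""

    values: np.ndarray
    frame_len_s: float
    hop_s: float

    @property
    def n_frames(self) -> int:
        return self.values.size


@dataclass
class SegmentationResult:
    segments: list[SegmentManifestRow]
    threshold_low: float
    threshold_high: float


def frame_energy(
    rec: AudioRecording,
    frame_len_s: float = 0.010,
    hop_s: float = 0.005,
    floor_db: float = ENERGY_FLOOR_DB,
) -> EnergyTrack:
    """Short-time log energy: ``10*log10(mean(x^2))`` per frame, floored.

    Frames are ``frame_len_s`` long with hop ``hop_s`` (frame_len >= hop).
    """
    if not (frame_len_s >= hop_s > 0):
        raise AudioInputError("require frame_len_s >= hop_s > 0")
    frame_len = int(round(frame_len_s * rec.sample_rate_hz))
    hop = int(round(hop_s * rec.sample_rate_hz))
    if rec.samples.size < frame_len:
        raise AudioInputError("recording shorter than one frame")
    n_frames = (rec.samples.size - frame_len) // hop + 1
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    power = np.mean(rec.samples[idx] ** 2, axis=1)
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(power)
    db = np.maximum(db, floor_db)
    return EnergyTrack(values=db, frame_len_s=frame_len_s, hop_s=hop_s)


def otsu_threshold(values: np.ndarray, n_bins: int = 256) -> float:
    """Otsu's threshold: the bin edge maximising between-class variance.

    Candidate thresholds are the inner edges of an ``n_bins`` histogram; the
    split at edge e is ``v < e`` versus ``v >= e`` and the between-class
    variance is computed from the actual sample moments.  When several edges
    tie (they fall in an empty gap between modes) the plateau midpoint is
    returned.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size < 2 or np.ptp(values) == 0:
        raise DegenerateInputError("Otsu thresholding needs >= 2 distinct values")
    edges = np.histogram_bin_edges(values, bins=n_bins)
    candidates = edges[1:-1]  # inner edges; edge e splits into v < e / v >= e
    v = np.sort(values)
    prefix = np.concatenate(([0.0], np.cumsum(v)))
    n0 = np.searchsorted(v, candidates, side="left").astype(np.float64)
    n1 = v.size - n0
    sum0 = prefix[n0.astype(int)]
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = sum0 / n0
        mu1 = (prefix[-1] - sum0) / n1
        between = n0 * n1 * (mu0 - mu1) ** 2
    between[~np.isfinite(between)] = -np.inf
    # edges falling in an empty gap tie exactly; take the plateau midpoint
    best = np.flatnonzero(between == between.max())
    return float(candidates[best].mean())


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as half-open frame index ranges."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def double_otsu_segment(
    energy: EnergyTrack,
    n_bins: int = 256,
    duration_s: float | None = None,
    recording_id: str = "recording",
) -> SegmentationResult:
    """Two successive Otsu passes: silence/sound, then weak/strong activity.

    Runs of frames above the low threshold that contain at least one frame
    above the high threshold become segments; boundaries fall on frame edges.
    """
    vals = energy.values
    try:
        t_low = otsu_threshold(vals, n_bins)
    except DegenerateInputError:
        return SegmentationResult([], float(vals[0]), float(vals[0]))
    above = vals > t_low
    try:
        t_high = otsu_threshold(vals[above], n_bins)
    except DegenerateInputError:
        t_high = t_low
    seeds = vals > t_high
    segments = []
    for i0, i1 in _runs(above):
        if not seeds[i0:i1].any():
            continue
        start = i0 * energy.hop_s
        end = (i1 - 1) * energy.hop_s + energy.frame_len_s
        if duration_s is not None:
            end = min(end, duration_s)
        segments.append(
            SegmentManifestRow(recording_id, start, end, label="unknown")
        )
    return SegmentationResult(segments, float(t_low), float(t_high))


def merge_close_segments(
    segments: list[SegmentManifestRow], merge_gap_s: float = 0.050
) -> list[SegmentManifestRow]:
    """Merge adjacent segments separated by less than ``merge_gap_s``."""
    if not segments:
        return []
    out = [segments[0]]
    for seg in segments[1:]:
        prev = out[-1]
        if seg.start_s - prev.end_s < merge_gap_s:
            out[-1] = SegmentManifestRow(
                prev.recording_id, prev.start_s, seg.end_s, label=prev.label
            )
        else:
            out.append(seg)
    return out


def duration_filter(
    segments: list[SegmentManifestRow],
    min_s: float = 0.25,
    max_s: float = 5.0,
) -> list[SegmentManifestRow]:
    """Keep segments with min_s <= duration <= max_s (closed interval)."""
    if not min_s < max_s:
        raise ValueError("require min_s < max_s")
    return [s for s in segments if min_s <= s.duration_s <= max_s]


def segment_recording(
    rec: AudioRecording, config: SegmentationConfig | None = None
) -> SegmentationResult:
    """Full segmentation: energy, double Otsu, gap merging, duration filter."""
    cfg = config or SegmentationConfig()
    energy = frame_energy(rec, cfg.frame_len_s, cfg.hop_s, cfg.floor_db)
    result = double_otsu_segment(
        energy, cfg.n_bins, duration_s=rec.duration_s, recording_id=rec.recording_id
    )
    merged = merge_close_segments(result.segments, cfg.merge_gap_s)
    kept = duration_filter(merged, cfg.min_dur_s, cfg.max_dur_s)
    return SegmentationResult(kept, result.threshold_low, result.threshold_high)
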