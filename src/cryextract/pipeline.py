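"""End-to-end cry extraction on long recordings.

The deployment path is: energy segmentation -> duration filter -> per-segment
wavelet F0 tracking + HNM analysis -> 73-feature summary -> schema pruning ->
scaler+PCA projection -> cry/non-cry prediction.  Extracted cries can
optionally be re-segmented when suspiciously long (back-to-back events merge
into one segment) and characterised by their fundamental-frequency
statistics using a cry-specific band and median smoothing.

A per-segment failure (e.g. a degenerate clip) is logged and skipped rather
than aborting the run: a monitoring tool has to survive 8-hour recordings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .audio_io import AudioRecording, SegmentManifestRow
from .classify import (
    CryClassifier,
    EvalReport,
    POSITIVE_LABEL,
    TrainingProtocol,
    evaluate,
    split_train_test,
    tune_and_fit,
)
from .f0 import DEFAULT_BAND_HZ, F0Config, F0Track, band_adapted_f0, cwt_f0, smooth_f0
from .features import FEATURE_NAMES, FeatureMatrix, stack_features, summarise_segment
from .hnm import analyze_segment
from .segmentation import SegmentationConfig, segment_recording

logger = logging.getLogger("cryextract")


@dataclass
class PipelineConfig:
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    f0: F0Config = field(default_factory=F0Config)
    resegment_threshold_s: float = 3.0
    resegment_long_segments: bool = False
    characterise: bool = False
    median_voiced_only: bool = False


@dataclass
class F0Summary:
    median_f0_hz: float  # NaN when fully unvoiced
    iqr_f0_hz: float
    voiced_fraction: float
    band_hz: tuple[float, float]


@dataclass
class ExtractionResult:
    recording_id: str
    segments_all: list[SegmentManifestRow]
    segments_cry: list[SegmentManifestRow]
    f0_summaries: list[F0Summary] = field(default_factory=list)
    threshold_low_db: float = float("nan")
    threshold_high_db: float = float("nan")


def compute_segment_features(
    seg_audio: AudioRecording, config: PipelineConfig | None = None
) -> np.ndarray:
    """The 73-entry feature vector of one segment."""
    cfg = config or PipelineConfig()
    band = (cfg.f0.f0_fmin_hz, cfg.f0.f0_fmax_hz)
    track = cwt_f0(seg_audio, band, cfg.f0)
    frames = analyze_segment(seg_audio, track)
    return summarise_segment(
        frames, seg_audio.samples, seg_audio.duration_s, cfg.median_voiced_only
    )


def build_feature_matrix(
    clips: list[tuple[AudioRecording, str]], config: PipelineConfig | None = None
) -> FeatureMatrix:
    """Feature rows for a labelled clip collection."""
    vectors, labels = [], []
    for rec, label in clips:
        vectors.append(compute_segment_features(rec, config))
        labels.append(label)
    return stack_features(vectors, labels)


def train_cry_model(
    matrix: FeatureMatrix,
    method: str = "knn",
    protocol: TrainingProtocol | None = None,
    final: bool = False,
) -> tuple[CryClassifier, EvalReport | None]:
    """Split, tune under CV, refit, and evaluate on the held-out test set.

    With ``final=True`` the tuned best configuration is refitted on 100% of
    the labelled rows (deployment mode) and no test report is produced.
    """
    protocol = protocol or TrainingProtocol()
    train, test = split_train_test(matrix, protocol)
    model = tune_and_fit(train, method, protocol)
    report = evaluate(model, test)
    if final:
        model = tune_and_fit(
            FeatureMatrix(matrix.values, list(matrix.columns), matrix.labels),
            method,
            protocol,
        )
    return model, report


def characterise_cry(
    seg_audio: AudioRecording, config: PipelineConfig | None = None
) -> F0Summary:
    """F0 statistics of a cry with automatic band refinement and smoothing.

    A first pass with the default band locates the cry's median F0; the band
    is then re-centred one octave either side of that median (clipped to the
    default band) and the refined track is median-smoothed before the
    summary statistics are taken.
    """
    cfg = config or PipelineConfig()
    default_band = (cfg.f0.f0_fmin_hz, cfg.f0.f0_fmax_hz)
    coarse = cwt_f0(seg_audio, default_band, cfg.f0)
    med = coarse.voiced_median()
    band = default_band
    if np.isfinite(med):
        band = (
            max(default_band[0], med / 2.0),
            min(default_band[1], med * 2.0),
        )
        if band[1] - band[0] < 10.0:
            band = default_band
    # the refined pass re-estimates F0 values only; voicing decisions come
    # from the standard-band pass (the peak-to-median voicing statistic is
    # not comparable across bands of different widths)
    refined_cfg = replace(cfg.f0, voicing_ratio=0.0)
    track = band_adapted_f0(seg_audio, band, refined_cfg)
    f0 = np.where(coarse.voiced, track.f0_hz, np.nan)
    track = F0Track(track.times_s, f0, track.band_hz)
    track = smooth_f0(track, cfg.f0.smooth_window_frames)
    voiced = track.f0_hz[track.voiced]
    if voiced.size == 0:
        return F0Summary(float("nan"), float("nan"), 0.0, band)
    q1, q3 = np.percentile(voiced, [25, 75])
    return F0Summary(
        median_f0_hz=float(np.median(voiced)),
        iqr_f0_hz=float(q3 - q1),
        voiced_fraction=track.voiced_fraction,
        band_hz=band,
    )


def _classify_segments(
    rec: AudioRecording,
    segments: list[SegmentManifestRow],
    model: CryClassifier,
    cfg: PipelineConfig,
) -> list[SegmentManifestRow]:
    cries = []
    for seg in segments:
        try:
            clip = rec.slice_time(seg.start_s, seg.end_s)
            vec = compute_segment_features(clip, cfg)
            label, score = model.predict(vec, FEATURE_NAMES)
        except Exception:
            logger.exception(
                "segment [%0.3f, %0.3f) of %s failed; skipping",
                seg.start_s, seg.end_s, rec.recording_id,
            )
            continue
        if label == POSITIVE_LABEL:
            cries.append(
                SegmentManifestRow(
                    rec.recording_id, seg.start_s, seg.end_s, label="cry", score=score
                )
            )
    return cries


def extract_cries(
    rec: AudioRecording,
    model: CryClassifier,
    config: PipelineConfig | None = None,
) -> ExtractionResult:
    """Run the full extraction chain on one recording."""
    cfg = config or PipelineConfig()
    seg_result = segment_recording(rec, cfg.segmentation)
    cries = _classify_segments(rec, seg_result.segments, model, cfg)
    if cfg.resegment_long_segments:
        refined = []
        for seg in cries:
            refined.extend(
                resegment_long(rec, seg, model, cfg, cfg.resegment_threshold_s)
            )
        cries = refined
    summaries = []
    if cfg.characterise:
        for seg in cries:
            try:
                summaries.append(characterise_cry(rec.slice_time(seg.start_s, seg.end_s), cfg))
            except Exception:
                logger.exception("characterisation failed for segment at %0.3f s", seg.start_s)
                summaries.append(F0Summary(float("nan"), float("nan"), 0.0, DEFAULT_BAND_HZ))
    return ExtractionResult(
        recording_id=rec.recording_id,
        segments_all=seg_result.segments,
        segments_cry=cries,
        f0_summaries=summaries,
        threshold_low_db=seg_result.threshold_low,
        threshold_high_db=seg_result.threshold_high,
    )


def resegment_long(
    rec: AudioRecording,
    segment: SegmentManifestRow,
    model: CryClassifier,
    config: PipelineConfig | None = None,
    threshold_s: float = 3.0,
) -> list[SegmentManifestRow]:
    """Re-run segmentation + classification inside one long segment.

    Long segments often hold several back-to-back events (a cry flanked by
    an alarm merges into one interval at the first pass); running the
    extractor on the clip alone recovers the cry-bearing sub-intervals.
    Segments at or below ``threshold_s`` are returned unchanged, and result
    times are mapped back to the parent recording's frame of reference.
    """
    cfg = config or PipelineConfig()
    if segment.duration_s <= threshold_s:
        return [segment]
    clip = rec.slice_time(segment.start_s, segment.end_s)
    sub_result = segment_recording(clip, cfg.segmentation)
    sub_cries = _classify_segments(clip, sub_result.segments, model, cfg)
    out = []
    for sub in sub_cries:
        out.append(
            SegmentManifestRow(
                rec.recording_id,
                segment.start_s + sub.start_s,
                min(segment.start_s + sub.end_s, segment.end_s),
                label="cry",
                score=sub.score,
            )
        )
    return out


def evaluate_extraction(
    truth: list[SegmentManifestRow],
    predicted: list[SegmentManifestRow],
    min_overlap: float = 0.5,
) -> dict[str, float]:
    """Event-level precision/recall of extracted cries against scene truth.

    A true cry (including overlapped cries) counts as recovered when
    predicted cry segments cover at least ``min_overlap`` of it; a predicted
    segment is a true positive when at least ``min_overlap`` of it lies
    inside true cry intervals.
    """
    true_cries = [t for t in truth if t.label in ("cry", "cry_overlap")]

    def overlap(a0, a1, b0, b1):
        return max(0.0, min(a1, b1) - max(a0, b0))

    recovered = 0
    for t in true_cries:
        cov = sum(overlap(t.start_s, t.end_s, p.start_s, p.end_s) for p in predicted)
        if cov >= min_overlap * t.duration_s:
            recovered += 1
    tp = 0
    for p in predicted:
        cov = sum(overlap(p.start_s, p.end_s, t.start_s, t.end_s) for t in true_cries)
        if cov >= min_overlap * p.duration_s:
            tp += 1
    recall = recovered / len(true_cries) if true_cries else float("nan")
    precision = tp / len(predicted) if predicted else float("nan")
    return {
        "precision": precision,
        "recall": recall,
        "n_true_cries": len(true_cries),
        "n_predicted": len(predicted),
    }
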