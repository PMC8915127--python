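"""Per-segment feature assembly.

Each sound segment is summarised by a fixed 73-entry feature vector: the
median over 5 ms frames of every HNM-derived quantity (F0, number of
harmonics, harmonic amplitudes padded to 18 slots, harmonic phases padded to
14 slots, noise gain, 20 all-pole filter coefficients, 16 MFCCs), plus two
time features computed on the raw samples — zero crossing rate and segment
duration.  Feature columns that are exactly zero across a whole training
batch (padding slots above the highest harmonic count ever observed) are
pruned, and the surviving schema is frozen for prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .audio_io import AudioInputError
from .hnm import HnmSegmentResult, LPC_ORDER, N_MFCC

AMP_SLOTS = 18
PHASE_SLOTS = 14


def feature_names() -> list[str]:
    """The fixed 73-column feature schema, in order."""
    names = ["f0_hz", "n_harmonics"]
    names += [f"amp_{k}" for k in range(1, AMP_SLOTS + 1)]
    names += [f"phase_{k}" for k in range(1, PHASE_SLOTS + 1)]
    names += ["gain"]
    names += [f"lpc_{p}" for p in range(1, LPC_ORDER + 1)]
    names += [f"mfcc_{m}" for m in range(1, N_MFCC + 1)]
    names += ["zcr", "duration_s"]
    return names


FEATURE_NAMES = feature_names()
N_FEATURES = len(FEATURE_NAMES)  # 73


@dataclass
class FeatureMatrix:
    """A (segments x features) table with optional per-row labels."""

    values: np.ndarray
    columns: list[str]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column count mismatch")
        if self.labels is not None and len(self.labels) != self.values.shape[0]:
            raise ValueError("label count mismatch")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.columns)
        if self.labels is not None:
            df["label"] = self.labels
        return df

    def select_columns(self, columns: list[str]) -> "FeatureMatrix":
        missing = [c for c in columns if c not in self.columns]
        if missing:
            raise AudioInputError(f"feature columns missing: {missing}")
        idx = [self.columns.index(c) for c in columns]
        return FeatureMatrix(self.values[:, idx], list(columns), self.labels)


def zero_crossing_rate(samples: np.ndarray) -> float:
    """Fraction of adjacent sample pairs whose product is negative.

    ZCR = (1/(T-1)) * sum_i 1[s_i * s_{i-1} < 0]; a zero sample does not
    count as a crossing.
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.size < 2:
        raise AudioInputError("ZCR needs at least 2 samples")
    return float(np.count_nonzero(x[1:] * x[:-1] < 0) / (x.size - 1))


def _padded(arr: np.ndarray, width: int) -> np.ndarray:
    out = np.zeros(width)
    n = min(arr.size, width)
    out[:n] = arr[:n]
    return out


def _frame_row(frame) -> np.ndarray:
    f0 = frame.f0_hz if np.isfinite(frame.f0_hz) else 0.0
    return np.concatenate(
        [
            [f0, frame.n_harmonics],
            _padded(frame.harmonic_amplitudes, AMP_SLOTS),
            _padded(frame.harmonic_phases, PHASE_SLOTS),
            [frame.noise_gain],
            _padded(frame.noise_filter_coeffs, LPC_ORDER),
            _padded(frame.mfcc, N_MFCC),
        ]
    )


def summarise_segment(
    frames: HnmSegmentResult,
    samples: np.ndarray,
    duration_s: float,
    median_voiced_only: bool = False,
) -> np.ndarray:
    """Median-summarise per-frame HNM output and append ZCR and duration.

    By default medians run over all frames, with unvoiced harmonic fields
    contributing zeros (weakly voiced segments are thereby penalised);
    ``median_voiced_only`` restricts the medians to voiced frames.
    """
    if len(frames) == 0:
        raise AudioInputError("cannot summarise an empty frame list")
    rows = [
        _frame_row(f)
        for f in frames.frames
        if not (median_voiced_only and not f.voiced)
    ]
    if not rows:  # voiced-only requested but no voiced frame
        rows = [_frame_row(f) for f in frames.frames]
    medians = np.median(np.stack(rows), axis=0)
    zcr = zero_crossing_rate(samples)
    return np.concatenate([medians, [zcr, duration_s]])


def stack_features(
    vectors: list[np.ndarray], labels: list[str] | None = None
) -> FeatureMatrix:
    return FeatureMatrix(np.stack(vectors), list(FEATURE_NAMES), labels)


def prune_null_columns(matrix: FeatureMatrix) -> tuple[FeatureMatrix, list[str]]:
    """Drop columns that are exactly zero in every row.

    Returns the pruned matrix and the kept column names, which form the
    schema to re-apply at prediction time.
    """
    if matrix.n_rows == 0:
        raise AudioInputError("empty feature matrix")
    keep = ~np.all(matrix.values == 0.0, axis=0)
    kept_names = [c for c, k in zip(matrix.columns, keep) if k]
    return matrix.select_columns(kept_names), kept_names
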