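"""Core record types shared across the pipeline.

A recording is always a 30-second, 50 Hz window, giving exactly 1,500
samples per channel.  Rhythm classes are coded 0 = NSR, 1 = AF,
2 = PAC/PVC throughout the package, including confusion matrices.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

#: sampling rate of every segment, Hz
FS = 50
#: segment duration, seconds
DURATION = 30.0
#: samples per segment
L = int(round(FS * DURATION))

#: physiological instantaneous heart-rate bounds, BPM
HR_MIN = 30.0
HR_MAX = 220.0


class Rhythm(IntEnum):
    """Segment-level rhythm class, coded as used by the classifier."""

    NSR = 0
    AF = 1
    PACPVC = 2


@dataclass
class BeatTrain:
    """Pulse-onset times of one segment with per-beat prematurity flags.

    ``beat_times`` are seconds from segment start, strictly increasing,
    within ``[0, 30)``.  ``premature_flags`` marks beats inserted early
    (short coupling interval); for NSR at most two beats may be flagged,
    for PAC/PVC at least three.
    """

    beat_times: np.ndarray
    premature_flags: np.ndarray
    rhythm: Rhythm

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.premature_flags = np.asarray(self.premature_flags, dtype=bool)
        if self.beat_times.ndim != 1:
            raise ValueError("beat_times must be one-dimensional")
        if self.premature_flags.shape != self.beat_times.shape:
            raise ValueError("premature_flags must match beat_times in length")
        if self.beat_times.size:
            if np.any(np.diff(self.beat_times) <= 0):
                raise ValueError("beat_times must be strictly increasing")
            if self.beat_times[0] < 0 or self.beat_times[-1] >= DURATION:
                raise ValueError("beat_times must lie within [0, 30)")

    @property
    def n_beats(self) -> int:
        return int(self.beat_times.size)

    @property
    def ibis(self) -> np.ndarray:
        """Inter-beat intervals, seconds; length ``n_beats - 1``."""
        return np.diff(self.beat_times)

    @property
    def instantaneous_hr(self) -> np.ndarray:
        """Per-interval heart rate 60/IBI, BPM; length ``n_beats - 1``."""
        return 60.0 / self.ibis


@dataclass
class SegmentRecord:
    """One 30-s multimodal recording with ground truth when synthetic."""

    subject_id: str
    segment_id: str
    ppg: np.ndarray
    acc: np.ndarray
    beats: BeatTrain
    artifact_mask: np.ndarray
    rhythm_label: Rhythm
    source: str = "synthetic"
    fs: int = FS
    duration: float = DURATION

    def __post_init__(self) -> None:
        self.ppg = np.asarray(self.ppg, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        n = int(round(self.fs * self.duration))
        for name, arr in (("ppg", self.ppg), ("acc", self.acc),
                          ("artifact_mask", self.artifact_mask)):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have exactly {n} samples, got {arr.shape}")
        if np.any(self.acc < 0):
            raise ValueError("acc magnitudes must be non-negative")

    @property
    def artifact_seconds(self) -> float:
        """Total artifact-flagged duration, seconds."""
        return float(self.artifact_mask.sum()) / self.fs
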