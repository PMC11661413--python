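"""Rule-based rhythm adjudication of 30-s segments.

The rules operate on machine-readable beat annotations and the artifact
mask:

* a beat is *premature* when its instantaneous HR (60/IBI) differs from
  the preceding interval's HR by at least 10 BPM — a normal sinus beat
  typically varies by less than that;
* **AF**: beat-to-beat irregularity spans the entire segment (here: every
  non-overlapping 5-s window contains at least one >=10 BPM change, or a
  ground-truth span flag);
* **PAC/PVC**: a non-AF segment with three or more premature beats;
* **NSR**: everything else (may contain one or two premature beats);
* a segment is *usable* when it carries at most 5 s of motion artifact.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import DURATION, BeatTrain, Rhythm


def _times(beats) -> np.ndarray:
    if isinstance(beats, BeatTrain):
        return beats.beat_times
    return np.asarray(beats, dtype=float)


@dataclass(frozen=True)
class AdjudicationConfig:
    """Adjudication constants; defaults are the operative clinical rules."""

    premature_delta_bpm: float = 10.0
    min_premature_beats: int = 3
    max_noise_seconds: float = 5.0


DEFAULT_CONFIG = AdjudicationConfig()

#: absolute tolerance on the >= 10 BPM comparison so that HR values which
#: are exact in BPM but inexact after the 60/IBI round trip stay inclusive
_BPM_EPS = 1e-9


def flag_premature_beats(beat_times: np.ndarray,
                         config: AdjudicationConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Flag beats whose instantaneous HR jumps >= 10 BPM from the prior interval.

    Returns one boolean per beat.  Beat ``i`` (i >= 2) is flagged iff
    ``|HR(i) - HR(i-1)| >= 10`` where ``HR(i) = 60 / (t_i - t_{i-1})``;
    the first interval has no predecessor and is never flagged.

    Raises ``ValueError`` if fewer than 3 beats are given (no pair of
    consecutive intervals exists).
    """
    t = _times(beat_times)
    if t.size < 3:
        raise ValueError("insufficient beats: need at least 3 beat times")
    hr = 60.0 / np.diff(t)              # HR per interval, length n-1
    delta = np.abs(np.diff(hr))         # length n-2, delta[k] compares intervals k, k+1
    flags = np.zeros(t.size, dtype=bool)
    flags[2:] = delta >= config.premature_delta_bpm - _BPM_EPS
    return flags


def irregularity_spans_segment(beat_times: np.ndarray,
                               duration: float = DURATION,
                               window_seconds: float = 5.0,
                               config: AdjudicationConfig = DEFAULT_CONFIG) -> bool:
    """Whole-segment irregularity test used when ground truth is absent.

    True iff every non-overlapping ``window_seconds`` window of the
    segment contains at least one consecutive-HR change >= 10 BPM.  The
    change is located at the time of the beat that closes its second
    interval.
    """
    t = _times(beat_times)
    if t.size < 3:
        return False
    hr = 60.0 / np.diff(t)
    delta = np.abs(np.diff(hr))
    jump_times = t[2:][delta >= config.premature_delta_bpm - _BPM_EPS]
    n_windows = int(np.ceil(duration / window_seconds))
    for w in range(n_windows):
        lo, hi = w * window_seconds, (w + 1) * window_seconds
        if not np.any((jump_times >= lo) & (jump_times < hi)):
            return False
    return True


def adjudicate_segment(beat_times: np.ndarray,
                       af_span_flag: bool,
                       config: AdjudicationConfig = DEFAULT_CONFIG) -> Rhythm:
    """Label one segment: AF takes precedence, then PAC/PVC, then NSR."""
    if af_span_flag:
        return Rhythm.AF
    flags = flag_premature_beats(beat_times, config)
    if int(flags.sum()) >= config.min_premature_beats:
        return Rhythm.PACPVC
    return Rhythm.NSR


def noise_gate(artifact_mask: np.ndarray, fs: float,
               config: AdjudicationConfig = DEFAULT_CONFIG) -> bool:
    """True when artifact-flagged duration is at most 5 seconds."""
    mask = np.asarray(artifact_mask, dtype=bool)
    return float(mask.sum()) / fs <= config.max_noise_seconds
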