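"""Raw segment -> aligned (L, d) multimodal input matrix.

Channels, in canonical order:

``PPG``
    30-s PPG band-passed with a 6th-order Butterworth IIR (0.5-20 Hz,
    applied forward-backward for zero phase) and min-max normalized to
    [0, 1] per segment.
``HR``
    Rectangularly interpolated heart rate from detected pulse peaks
    (piecewise-constant 60/IBI), normalized over the fixed [30, 220] BPM
    physiological range so rapid ventricular response stays on scale.
``ACC``
    Accelerometer magnitude clipped to the 0-20 m/s^2 daily-activity
    range and divided by 20.
``MAGHR``
    The same rectangular HR min-max normalized per segment ("magnified"
    HR), preserving small local variations that the fixed range
    compresses.
"""
from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
import numpy as np
from scipy import signal as sps

from .records import FS, HR_MAX, HR_MIN, L, SegmentRecord

__all__ = [
    "NormalizationConstants", "ChannelConfig", "InputMatrix", "HrUndefinedError",
    "SegmentRejected", "bandpass_filter", "normalize_unit", "detect_peaks",
    "compute_hr_series", "normalize_hr_fixed", "normalize_hr_magnified",
    "acc_channel", "resample_to_50hz", "assemble_input",
]


@dataclass(frozen=True)
class NormalizationConstants:
    """Fixed preprocessing constants (physiological bounds and filter design)."""

    hr_min: float = HR_MIN
    hr_max: float = HR_MAX
    acc_max: float = 20.0
    gravity: float = 9.8
    fs: int = FS
    n_samples: int = L
    band: tuple[float, float] = (0.5, 20.0)
    filter_order: int = 6


CONSTANTS = NormalizationConstants()

#: canonical channel order; requests are reordered to this
CANONICAL_CHANNELS = ("PPG", "HR", "ACC", "MAGHR")


class HrUndefinedError(ValueError):
    """Raised when fewer than two pulse peaks exist, so HR has no value."""


class SegmentRejected(ValueError):
    """Raised when a segment cannot supply a requested channel."""


@dataclass(frozen=True)
class ChannelConfig:
    """Ordered choice of model input channels; ``d`` is the channel count."""

    channels: tuple[str, ...] = CANONICAL_CHANNELS

    def __post_init__(self) -> None:
        chans = tuple(c.upper() for c in self.channels)
        unknown = set(chans) - set(CANONICAL_CHANNELS)
        if unknown:
            raise ValueError(f"unknown channels: {sorted(unknown)}")
        if len(chans) != len(set(chans)):
            raise ValueError("duplicate channels requested")
        if not chans:
            raise ValueError("at least one channel is required")
        ordered = tuple(c for c in CANONICAL_CHANNELS if c in chans)
        object.__setattr__(self, "channels", ordered)

    @property
    def d(self) -> int:
        return len(self.channels)


@dataclass
class InputMatrix:
    """(L, d) matrix with entries in [0, 1] plus its channel labels."""

    values: np.ndarray
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != L:
            raise ValueError(f"values must be ({L}, d)")
        if self.values.shape[1] != len(self.channel_names):
            raise ValueError("channel_names must match the number of columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite entries in input matrix")


def _butter_sos(fs: float, constants: NormalizationConstants = CONSTANTS):
    # scipy's N is the prototype order; a bandpass doubles it, so N=3 -> 6th order
    return sps.butter(constants.filter_order // 2, constants.band,
                      btype="bandpass", fs=fs, output="sos")


def bandpass_filter(ppg: np.ndarray, fs: float = FS,
                    constants: NormalizationConstants = CONSTANTS) -> np.ndarray:
    """Zero-phase 6th-order Butterworth band-pass, 0.5-20 Hz.

    Forward-backward application removes phase delay so HR plateaus stay
    aligned with beat times; DC and baseline wander fall outside the
    pass-band and are removed.
    """
    x = np.asarray(ppg, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite samples in PPG input")
    return sps.sosfiltfilt(_butter_sos(fs, constants), x)


def normalize_unit(x: np.ndarray) -> np.ndarray:
    """Per-segment min-max map onto [0, 1]; constant input maps to 0.5."""
    x = np.asarray(x, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return np.full_like(x, 0.5)
    return (x - lo) / (hi - lo)


def detect_peaks(ppg: np.ndarray, fs: float = FS, *,
                 envelope_window: float = 0.3,
                 threshold_fraction: float = 0.4,
                 envelope_floor: float = 0.6,
                 dicrotic_window: float = 0.35,
                 dicrotic_ratio: float = 0.55) -> np.ndarray:
    """Pulse-peak times from filtered PPG via an envelope-guided search.

    A moving-RMS amplitude envelope (0.3 s window) sets a local adaptive
    threshold at 0.4 x envelope, floored at a fraction of the segment RMS
    so baseline noise in diastolic troughs cannot pass; local maxima
    above it are kept subject to a 60/220 s refractory period.  A
    secondary candidate arriving within ``dicrotic_window`` of the last
    accepted peak at under ``dicrotic_ratio`` of its height is discarded
    as a dicrotic wave, leaving one peak per physiological pulse.
    Raises :class:`HrUndefinedError` when fewer than two peaks are found.
    """
    x = np.asarray(ppg, dtype=float)
    win = max(int(round(envelope_window * fs)), 1)
    kernel = np.ones(win) / win
    envelope = np.sqrt(np.convolve(x ** 2, kernel, mode="same"))
    global_rms = float(np.sqrt(np.mean(x ** 2)))
    height = threshold_fraction * np.maximum(envelope, envelope_floor * global_rms)
    refractory = int(np.ceil(60.0 / HR_MAX * fs))
    idx, _ = sps.find_peaks(x, height=height, distance=refractory)
    kept: list[int] = []
    for i in idx:
        if kept and (i - kept[-1]) / fs < dicrotic_window \
                and x[i] < dicrotic_ratio * x[kept[-1]]:
            continue
        kept.append(i)
    if len(kept) < 2:
        raise HrUndefinedError("fewer than two pulse peaks detected")
    return np.asarray(kept, dtype=float) / fs


def compute_hr_series(beat_times: np.ndarray, n_samples: int = L,
                      fs: float = FS) -> np.ndarray:
    """Rectangular (step) interpolation of instantaneous HR, one value per sample.

    Between consecutive beats ``i`` and ``i+1`` the series holds
    ``60 / (t[i+1] - t[i])`` BPM; before the first plateau and after the
    last, the nearest plateau value is held.  Requires >= 2 beats.
    """
    t = np.asarray(beat_times, dtype=float)
    if t.size < 2:
        raise HrUndefinedError("need at least two beat times for an HR series")
    hr = 60.0 / np.diff(t)
    sample_t = np.arange(n_samples) / fs
    # plateau k covers [t[k], t[k+1]); searchsorted gives the enclosing interval
    idx = np.searchsorted(t, sample_t, side="right") - 1
    idx = np.clip(idx, 0, hr.size - 1)
    return hr[idx]


def normalize_hr_fixed(hr: np.ndarray,
                       constants: NormalizationConstants = CONSTANTS) -> np.ndarray:
    """Affine map (hr - 30) / 190 onto [0, 1], clipped at the physiological bounds."""
    hr = np.asarray(hr, dtype=float)
    out = (hr - constants.hr_min) / (constants.hr_max - constants.hr_min)
    return np.clip(out, 0.0, 1.0)


def normalize_hr_magnified(hr: np.ndarray) -> np.ndarray:
    """Per-segment min-max ("magnified") HR; constant series maps to 0.5."""
    return normalize_unit(hr)


def acc_channel(acc: np.ndarray, *, triaxial: bool = False,
                gravitational_units: bool = False,
                constants: NormalizationConstants = CONSTANTS) -> np.ndarray:
    """Normalize ACC magnitude into [0, 1] over the 0-20 m/s^2 activity range.

    Tri-axial input (shape (n, 3)) is reduced to its Euclidean magnitude
    first; input recorded in gravitational units is multiplied by 9.8.
    """
    a = np.asarray(acc, dtype=float)
    if triaxial or (a.ndim == 2 and a.shape[1] == 3):
        a = np.sqrt(np.sum(a * a, axis=1))
    if gravitational_units:
        a = a * constants.gravity
    if np.any(a < 0):
        raise ValueError("ACC magnitudes must be non-negative")
    return np.clip(a, 0.0, constants.acc_max) / constants.acc_max


def resample_to_50hz(x: np.ndarray, fs_in: float) -> np.ndarray:
    """Anti-aliased rational-ratio resampling down to 50 Hz."""
    if fs_in <= 50:
        raise ValueError("resample_to_50hz supports only fs_in > 50")
    frac = Fraction(50, 1) / Fraction(fs_in).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    return sps.resample_poly(np.asarray(x, dtype=float), up, down)


def assemble_input(segment: SegmentRecord,
                   cfg: ChannelConfig = ChannelConfig(), *,
                   constants: NormalizationConstants = CONSTANTS) -> InputMatrix:
    """Build the (L, d) input matrix for one segment.

    PPG is filtered then unit-normalized; HR channels come from peaks
    detected on the filtered PPG; ACC is range-normalized.  Channels are
    emitted in canonical order regardless of request order.  A segment
    whose HR is undefined is rejected with an explicit reason when an HR
    channel is requested.
    """
    need_hr = ("HR" in cfg.channels) or ("MAGHR" in cfg.channels)
    columns: dict[str, np.ndarray] = {}
    filtered = bandpass_filter(segment.ppg, segment.fs, constants)
    if "PPG" in cfg.channels:
        columns["PPG"] = normalize_unit(filtered)
    if need_hr:
        try:
            peaks = detect_peaks(filtered, segment.fs)
            hr = compute_hr_series(peaks, constants.n_samples, segment.fs)
        except HrUndefinedError as exc:
            raise SegmentRejected(
                f"segment {segment.segment_id}: HR undefined ({exc})") from exc
        if "HR" in cfg.channels:
            columns["HR"] = normalize_hr_fixed(hr, constants)
        if "MAGHR" in cfg.channels:
            columns["MAGHR"] = normalize_hr_magnified(hr)
    if "ACC" in cfg.channels:
        columns["ACC"] = acc_channel(segment.acc, constants=constants)
    values = np.column_stack([columns[c] for c in cfg.channels])
    return InputMatrix(values=values, channel_names=cfg.channels)
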