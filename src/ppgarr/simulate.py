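"""Synthetic 30-s wrist-PPG/ACC segment generator.

Emulates the statistical structure of real smartwatch recordings so the
whole classification pipeline is exercisable without any download:

* **NSR** beat trains follow a slowly drifting sinus rate whose
  beat-to-beat HR changes stay below 10 BPM; a fraction of segments may
  carry one late premature beat (segments remain NSR under the labeling
  rules, which allow one to two premature beats).
* **AF** trains draw i.i.d. log-normal instantaneous HR with a given
  coefficient of variation, rejection-sampled until the irregularity
  spans every 5-s window of the segment.
* **PAC/PVC** trains advance selected beats by a coupling fraction of
  the preceding interval (isolated / bigeminy / trigeminy patterns); the
  following normal beat is left in place, giving a fully compensatory
  pause and the characteristic zig-zag rectangular-HR shape.
* PPG waveforms place a two-component pulse template (systolic wave plus
  a smaller dicrotic wave) at every beat; premature pulses are attenuated
  in proportion to their shortened filling time.
* Motion artifacts are band-limited (0.5-10 Hz) noise bursts plus
  amplitude distortion, co-timed with elevated accelerometer magnitude.

All randomness flows from a single seeded :class:`numpy.random.Generator`
threaded through every operation, so a fixed configuration reproduces a
byte-identical dataset.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .records import DURATION, FS, HR_MAX, HR_MIN, BeatTrain, Rhythm, SegmentRecord
from .adjudicate import flag_premature_beats, irregularity_spans_segment

__all__ = [
    "SimulationConfig",
    "generate_rr_nsr",
    "generate_rr_af",
    "generate_rr_pacpvc",
    "synthesize_ppg",
    "synthesize_acc",
    "inject_artifact",
    "generate_dataset",
]


# ---------------------------------------------------------------------------
# configuration

@dataclass
class SimulationConfig:
    """Study-condition knobs for :func:`generate_dataset`.

    The default composition yields roughly a 10:2:1 NSR:AF:PAC/PVC
    segment mix with per-subject rhythm-burden heterogeneity (NSR-only
    subjects contribute no arrhythmic segments at all).
    """

    n_nsr_subjects: int = 16
    n_af_subjects: int = 7
    n_pacpvc_subjects: int = 7
    segments_per_subject: int = 12
    mean_hr_range: tuple[float, float] = (55.0, 95.0)
    af_rr_dispersion: float = 0.2
    af_burden: float = 0.6
    pacpvc_burden: float = 0.4
    pac_pattern: str = "mixed"          # isolated | bigeminy | trigeminy | mixed
    premature_coupling: float = 0.65    # fraction of the preceding RR
    nsr_premature_fraction: float = 0.15
    artifact_burst_rate: float = 0.25   # Poisson bursts per segment
    artifact_total_seconds: float = 3.0
    artifact_noise_scale: float = 3.0   # artifact noise RMS, x clean PPG RMS
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_nsr_subjects", "n_af_subjects", "n_pacpvc_subjects",
                     "segments_per_subject"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 < self.premature_coupling < 1.0):
            raise ValueError("premature_coupling must lie in (0, 1)")
        if not (0.0 <= self.artifact_total_seconds <= DURATION):
            raise ValueError("artifact_total_seconds must lie in [0, 30]")


# ---------------------------------------------------------------------------
# beat-train generators

def _check_mean_hr(mean_hr: float) -> None:
    if not (HR_MIN <= mean_hr <= HR_MAX):
        raise ValueError(f"mean_hr must lie in [{HR_MIN:g}, {HR_MAX:g}] BPM")


def _sinus_hr_walk(mean_hr: float, n: int, rng: np.random.Generator,
                   max_step: float = 3.0, band: float = 8.0) -> np.ndarray:
    """Slowly drifting sinus HR: reflected random walk, steps < 10 BPM."""
    lo = max(mean_hr - band, HR_MIN + 5.0)
    hi = min(mean_hr + band, HR_MAX - 20.0)
    hr = np.empty(n)
    h = rng.uniform(lo, hi)
    for i in range(n):
        h = h + rng.uniform(-max_step, max_step)
        if h < lo:
            h = lo + (lo - h)
        elif h > hi:
            h = hi - (h - hi)
        hr[i] = min(max(h, lo), hi)
    return hr


def _times_from_hr(hr_per_beat: np.ndarray, t0: float, n_seconds: float) -> np.ndarray:
    ibis = 60.0 / hr_per_beat
    t = t0 + np.concatenate(([0.0], np.cumsum(ibis)))
    return t[t < n_seconds]


def generate_rr_nsr(mean_hr: float, n_seconds: float = DURATION, *,
                    rng: np.random.Generator,
                    premature_prob: float = 0.0,
                    coupling: float = 0.65) -> BeatTrain:
    """Normal-sinus beat train; every consecutive-HR change stays < 10 BPM.

    With probability ``premature_prob`` the final beat is advanced to a
    premature position (coupling x preceding RR).  A tail premature beat
    produces at most two flagged beats, keeping the train within the NSR
    labeling rule.
    """
    _check_mean_hr(mean_hr)
    n_est = int(np.ceil(n_seconds * mean_hr / 60.0)) + 8
    hr = _sinus_hr_walk(mean_hr, n_est, rng)
    t = _times_from_hr(hr, rng.uniform(0.0, 0.6), n_seconds)
    flags = np.zeros(t.size, dtype=bool)
    if premature_prob > 0 and t.size >= 6 and rng.uniform() < premature_prob:
        cand = t.copy()
        cand[-1] = cand[-2] + coupling * (cand[-1] - cand[-2])
        cand_flags = flag_premature_beats(cand)
        if int(cand_flags.sum()) <= 2:
            t = cand
            flags[-1] = True
    return BeatTrain(beat_times=t, premature_flags=flags, rhythm=Rhythm.NSR)


def generate_rr_af(mean_hr: float, dispersion: float,
                   n_seconds: float = DURATION, *,
                   rng: np.random.Generator,
                   max_tries: int = 200) -> BeatTrain:
    """AF beat train: i.i.d. log-normal instantaneous HR, no serial correlation.

    The log-normal is placed on instantaneous HR (= 60/RR) with mean
    ``mean_hr`` and coefficient of variation ``dispersion``, so the
    population mean of instantaneous HR matches the request.  Trains are
    rejection-sampled until every 5-s window contains a >=10 BPM
    consecutive-HR change; for small dispersion this post-condition is
    unreachable and a ``RuntimeError`` is raised.
    """
    _check_mean_hr(mean_hr)
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    sigma2 = np.log1p(dispersion ** 2)
    mu = np.log(mean_hr) - sigma2 / 2.0
    n_est = int(np.ceil(n_seconds * mean_hr / 60.0)) + 20
    for _ in range(max_tries):
        hr = np.exp(rng.normal(mu, np.sqrt(sigma2), size=n_est))
        hr = np.clip(hr, HR_MIN + 1.0, HR_MAX - 5.0)
        t = _times_from_hr(hr, rng.uniform(0.0, 0.5), n_seconds)
        if irregularity_spans_segment(t, duration=n_seconds):
            flags = np.zeros(t.size, dtype=bool)
            return BeatTrain(beat_times=t, premature_flags=flags, rhythm=Rhythm.AF)
    raise RuntimeError(
        f"could not generate an AF train whose irregularity spans the segment "
        f"(dispersion={dispersion:g} too small?)")


def generate_rr_pacpvc(mean_hr: float, *, pattern: str = "isolated",
                       n_premature: int = 3, coupling: float = 0.65,
                       rng: np.random.Generator,
                       n_seconds: float = DURATION) -> BeatTrain:
    """Beat train with premature beats in an isolated/bigeminy/trigeminy pattern.

    Each premature event advances one normal beat to ``coupling`` x the
    preceding RR; the next normal beat keeps its grid position, which
    realizes a fully compensatory pause of ``(2 - coupling) x RR``.  Every
    premature beat therefore produces an instantaneous-HR jump >= 10 BPM.
    """
    _check_mean_hr(mean_hr)
    if n_premature < 3:
        raise ValueError("a PAC/PVC train needs n_premature >= 3")
    if not (0.0 < coupling < 0.9):
        raise ValueError("coupling must lie in (0, 0.9)")
    if pattern not in ("isolated", "bigeminy", "trigeminy", "mixed"):
        raise ValueError(f"unknown pattern {pattern!r}")
    if pattern == "mixed":
        pattern = ("isolated", "bigeminy", "trigeminy")[rng.integers(3)]

    n_est = int(np.ceil(n_seconds * mean_hr / 60.0)) + 8
    hr = _sinus_hr_walk(mean_hr, n_est, rng)
    t = _times_from_hr(hr, rng.uniform(0.0, 0.5), n_seconds)
    n = t.size
    step = {"isolated": 3, "bigeminy": 2, "trigeminy": 3}[pattern]
    # candidate indices leave the first beat and the last grid beat normal
    candidates = np.arange(2, n - 1, step)
    if candidates.size < n_premature:
        raise ValueError(
            f"cannot place {n_premature} premature beats with pattern "
            f"{pattern!r} in a {n}-beat train")
    if pattern == "isolated":
        idx = rng.choice(candidates, size=n_premature, replace=False)
    else:
        start = rng.integers(0, max(candidates.size - n_premature, 0) + 1)
        idx = candidates[start:start + n_premature]
    flags = np.zeros(n, dtype=bool)
    t = t.copy()
    for k in np.sort(idx):
        t[k] = t[k - 1] + coupling * (t[k] - t[k - 1])
        flags[k] = True
    return BeatTrain(beat_times=t, premature_flags=flags, rhythm=Rhythm.PACPVC)


# ---------------------------------------------------------------------------
# waveform synthesis

#: systolic rise/fall time constants and dicrotic-wave geometry, seconds
_SYS_RISE = 0.055
_SYS_FALL = 0.095
_DIC_DELAY = 0.25
_DIC_WIDTH = 0.07
_DIC_AMP = 0.40


def pulse_template(t: np.ndarray) -> np.ndarray:
    """Asymmetric systolic bell plus a dicrotic sub-wave; maximum ~1 at t=0."""
    t = np.asarray(t, dtype=float)
    sys_w = np.where(t < 0,
                     np.exp(-0.5 * (t / _SYS_RISE) ** 2),
                     np.exp(-0.5 * (t / _SYS_FALL) ** 2))
    dic_w = _DIC_AMP * np.exp(-0.5 * ((t - _DIC_DELAY) / _DIC_WIDTH) ** 2)
    return sys_w + dic_w


def synthesize_ppg(beats: BeatTrain, fs: float = FS, *,
                   rng: np.random.Generator,
                   noise_sd: float = 0.03,
                   wander_amp: float = 0.15,
                   duration: float = DURATION) -> np.ndarray:
    """Clean PPG trace: one pulse per beat plus baseline noise and wander.

    Premature pulses are attenuated by their relative filling time
    (preceding IBI over the local median IBI), mimicking the reduced
    stroke volume of an early beat.
    """
    n = int(round(fs * duration))
    tgrid = np.arange(n) / fs
    out = np.zeros(n)
    times = beats.beat_times
    if times.size:
        ibis = np.diff(times)
        med_ibi = float(np.median(ibis)) if ibis.size else 0.8
        for k, bt in enumerate(times):
            amp = 1.0 + rng.uniform(-0.05, 0.05)
            if beats.premature_flags[k] and k >= 1:
                ratio = (times[k] - times[k - 1]) / med_ibi
                amp *= float(np.clip(ratio, 0.3, 1.0))
            lo = max(int(np.floor((bt - 0.35) * fs)), 0)
            hi = min(int(np.ceil((bt + 0.60) * fs)) + 1, n)
            out[lo:hi] += amp * pulse_template(tgrid[lo:hi] - bt)
    if wander_amp > 0:
        f_w = rng.uniform(0.15, 0.35)
        out += wander_amp * np.sin(2 * np.pi * f_w * tgrid + rng.uniform(0, 2 * np.pi))
    out += rng.normal(0.0, noise_sd, size=n)
    return out


def _merge_windows(windows: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    win = sorted((float(a), float(b)) for a, b in windows if b > a)
    merged: list[tuple[float, float]] = []
    for a, b in win:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def windows_to_mask(windows: Sequence[tuple[float, float]], fs: float = FS,
                    duration: float = DURATION) -> np.ndarray:
    """Boolean per-sample mask; sample i is inside iff a <= i/fs < b."""
    n = int(round(fs * duration))
    mask = np.zeros(n, dtype=bool)
    for a, b in _merge_windows(windows):
        lo = max(int(np.ceil(a * fs - 1e-9)), 0)
        hi = min(int(np.ceil(b * fs - 1e-9)), n)
        mask[lo:hi] = True
    return mask


def _bandlimited_noise(n: int, fs: float, rng: np.random.Generator,
                       band: tuple[float, float] = (0.5, 10.0)) -> np.ndarray:
    sos = sps.butter(2, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n + 100))[100:]
    sd = float(x.std())
    return x / sd if sd > 0 else x


def synthesize_acc(artifact_windows: Sequence[tuple[float, float]],
                   fs: float = FS, *, rng: np.random.Generator,
                   rest_value: float = 9.8, rest_sd: float = 0.05,
                   burst_amp: float = 6.0,
                   duration: float = DURATION) -> np.ndarray:
    """ACC magnitude: ~9.8 m/s^2 at rest, elevated bursts inside windows."""
    n = int(round(fs * duration))
    acc = rest_value + rng.normal(0.0, rest_sd, size=n)
    mask = windows_to_mask(artifact_windows, fs, duration)
    if mask.any():
        burst = np.abs(_bandlimited_noise(n, fs, rng)) * burst_amp
        acc[mask] += burst[mask] + 0.5
    return np.clip(acc, 0.0, 20.0)


def inject_artifact(ppg: np.ndarray,
                    windows: Sequence[tuple[float, float]], *,
                    rng: np.random.Generator,
                    noise_scale: float = 3.0,
                    fs: float = FS) -> tuple[np.ndarray, np.ndarray]:
    """Corrupt PPG inside the windows; outside samples are bit-identical.

    Corruption is multiplicative amplitude distortion plus additive
    band-limited (0.5-10 Hz) noise at ``noise_scale`` x the clean RMS.
    Returns ``(ppg_corrupted, artifact_mask)``.
    """
    ppg = np.asarray(ppg, dtype=float)
    duration = ppg.size / fs
    mask = windows_to_mask(windows, fs, duration)
    out = ppg.copy()
    if mask.any():
        clean_rms = float(np.sqrt(np.mean(ppg ** 2))) or 1.0
        noise = _bandlimited_noise(ppg.size, fs, rng) * noise_scale * clean_rms
        gain = rng.uniform(0.2, 0.7)
        out[mask] = ppg[mask] * gain + noise[mask]
    return out, mask


# ---------------------------------------------------------------------------
# dataset assembly

def _draw_artifact_windows(rng: np.random.Generator, rate: float,
                           total_seconds: float, fs: float = FS,
                           duration: float = DURATION) -> list[tuple[float, float]]:
    """0 or more non-overlapping bursts totalling ``total_seconds`` exactly.

    Burst bounds are snapped to the sample grid so the mask duration
    equals the request to within one sample period.
    """
    if total_seconds <= 0 or rate <= 0:
        return []
    k = int(rng.poisson(rate))
    if k == 0:
        return []
    k = min(k, max(int(total_seconds / 0.5), 1))
    total_samples = int(round(total_seconds * fs))
    # random composition of k burst lengths, each >= 0.5 s
    min_len = int(0.5 * fs)
    free = total_samples - k * min_len
    if free < 0:
        k, free = 1, total_samples - min_len
    cuts = np.sort(rng.integers(0, free + 1, size=k - 1)) if k > 1 else np.array([], int)
    parts = np.diff(np.concatenate(([0], cuts, [free]))) + min_len
    # place bursts without overlap via random gaps
    n = int(round(fs * duration))
    slack = n - int(parts.sum())
    gaps = np.floor(rng.dirichlet(np.ones(k + 1)) * slack).astype(int)
    starts = np.empty(k, dtype=int)
    pos = 0
    for i in range(k):
        pos += gaps[i]
        starts[i] = pos
        pos += parts[i]
    return [(s / fs, (s + p) / fs) for s, p in zip(starts, parts)]


def _make_segment(subject_id: str, seg_idx: int, rhythm: Rhythm,
                  mean_hr: float, cfg: SimulationConfig,
                  rng: np.random.Generator) -> SegmentRecord:
    if rhythm == Rhythm.NSR:
        beats = generate_rr_nsr(mean_hr, rng=rng,
                                premature_prob=cfg.nsr_premature_fraction,
                                coupling=cfg.premature_coupling)
    elif rhythm == Rhythm.AF:
        beats = generate_rr_af(mean_hr, cfg.af_rr_dispersion, rng=rng)
    else:
        n_prem = int(rng.integers(3, 9))
        beats = generate_rr_pacpvc(mean_hr, pattern=cfg.pac_pattern,
                                   n_premature=n_prem,
                                   coupling=cfg.premature_coupling, rng=rng)
    ppg = synthesize_ppg(beats, rng=rng)
    windows = _draw_artifact_windows(rng, cfg.artifact_burst_rate,
                                     cfg.artifact_total_seconds)
    ppg, mask = inject_artifact(ppg, windows, rng=rng,
                                noise_scale=cfg.artifact_noise_scale)
    acc = synthesize_acc(windows, rng=rng)
    return SegmentRecord(subject_id=subject_id,
                         segment_id=f"{subject_id}_seg{seg_idx:03d}",
                         ppg=ppg, acc=acc, beats=beats, artifact_mask=mask,
                         rhythm_label=rhythm, source="synthetic")


def generate_dataset(config: SimulationConfig
                     ) -> tuple[list[SegmentRecord], pd.DataFrame]:
    """Generate the full labeled dataset plus its manifest.

    Subjects are of three kinds: NSR-only (contribute no arrhythmic
    segments), AF subjects (per-subject AF burden drawn around
    ``af_burden``) and PAC/PVC subjects (likewise).  Deterministic under
    ``config.rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    records: list[SegmentRecord] = []
    rows = []
    roles = (["nsr"] * config.n_nsr_subjects
             + ["af"] * config.n_af_subjects
             + ["pacpvc"] * config.n_pacpvc_subjects)
    for s_idx, role in enumerate(roles):
        subject_id = f"S{s_idx:03d}"
        base_hr = rng.uniform(*config.mean_hr_range)
        if role == "af":
            burden = float(rng.beta(4 * config.af_burden,
                                    4 * (1 - config.af_burden)))
        elif role == "pacpvc":
            burden = float(rng.beta(4 * config.pacpvc_burden,
                                    4 * (1 - config.pacpvc_burden)))
        else:
            burden = 0.0
        for g in range(config.segments_per_subject):
            if role == "af" and rng.uniform() < burden:
                rhythm, hr = Rhythm.AF, min(base_hr + 8.0, 140.0)
            elif role == "pacpvc" and rng.uniform() < burden:
                rhythm, hr = Rhythm.PACPVC, base_hr
            else:
                rhythm, hr = Rhythm.NSR, base_hr
            hr = float(np.clip(hr + rng.normal(0.0, 2.0), 40.0, 180.0))
            rec = _make_segment(subject_id, g, rhythm, hr, config, rng)
            records.append(rec)
            rows.append({
                "subject_id": subject_id,
                "segment_id": rec.segment_id,
                "rhythm_label": rec.rhythm_label.name,
                "n_premature_beats": int(rec.beats.premature_flags.sum()),
                "artifact_seconds": rec.artifact_seconds,
                "path": "",
            })
    manifest = pd.DataFrame(rows, columns=["subject_id", "segment_id",
                                           "rhythm_label", "n_premature_beats",
                                           "artifact_seconds", "path"])
    return records, manifest
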