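"""Readers and writers: per-subject HDF5 containers, manifests, CSV adapter.

The on-disk layout of a dataset directory is::

    <dir>/manifest.csv            subject_id, segment_id, rhythm_label, ...
    <dir>/S000.h5                 one file per subject
        /<segment_id>/ppg         float array, 1500 samples
        /<segment_id>/acc         float array, m/s^2
        /<segment_id>/artifact_mask
        /<segment_id>/beat_times  seconds (ground truth when synthetic)
        /<segment_id>/premature_flags
        attrs: fs, duration, rhythm_label, source
"""
from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

from .preprocess import ChannelConfig, SegmentRejected, assemble_input, resample_to_50hz
from .records import L, BeatTrain, Rhythm, SegmentRecord
from .training import ArrayDataset

__all__ = ["write_segments", "read_segments", "read_manifest", "write_manifest",
           "read_csv_segment", "dataset_to_arrays"]


def write_manifest(manifest: pd.DataFrame, path: Path | str) -> None:
    manifest.to_csv(path, index=False)


def read_manifest(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path)


def write_segments(directory: Path | str, records: Sequence[SegmentRecord],
                   manifest: pd.DataFrame | None = None) -> pd.DataFrame:
    """Write one HDF5 container per subject plus the manifest CSV.

    Returns the manifest with its ``path`` column filled in.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    by_subject: dict[str, list[SegmentRecord]] = {}
    for rec in records:
        by_subject.setdefault(rec.subject_id, []).append(rec)
    paths: dict[str, str] = {}
    for subject_id, recs in by_subject.items():
        fname = directory / f"{subject_id}.h5"
        with h5py.File(fname, "w") as f:
            for rec in recs:
                g = f.create_group(rec.segment_id)
                g.create_dataset("ppg", data=rec.ppg)
                g.create_dataset("acc", data=rec.acc)
                g.create_dataset("artifact_mask", data=rec.artifact_mask)
                g.create_dataset("beat_times", data=rec.beats.beat_times)
                g.create_dataset("premature_flags", data=rec.beats.premature_flags)
                g.attrs["fs"] = rec.fs
                g.attrs["duration"] = rec.duration
                g.attrs["rhythm_label"] = rec.rhythm_label.name
                g.attrs["source"] = rec.source
        paths[subject_id] = str(fname)
    if manifest is None:
        manifest = pd.DataFrame({"subject_id": [r.subject_id for r in records],
                                 "segment_id": [r.segment_id for r in records]})
    manifest = manifest.copy()
    manifest["path"] = manifest["subject_id"].map(paths)
    write_manifest(manifest, directory / "manifest.csv")
    return manifest


def _read_subject_file(path: Path) -> list[SegmentRecord]:
    out = []
    with h5py.File(path, "r") as f:
        for seg_id in sorted(f.keys()):
            g = f[seg_id]
            rhythm = Rhythm[g.attrs["rhythm_label"]]
            beats = BeatTrain(beat_times=g["beat_times"][()],
                              premature_flags=g["premature_flags"][()],
                              rhythm=rhythm)
            out.append(SegmentRecord(
                subject_id=path.stem, segment_id=seg_id,
                ppg=g["ppg"][()], acc=g["acc"][()], beats=beats,
                artifact_mask=g["artifact_mask"][()], rhythm_label=rhythm,
                source=str(g.attrs.get("source", "synthetic")),
                fs=int(g.attrs["fs"]), duration=float(g.attrs["duration"])))
    return out


def read_segments(path: Path | str, source: str = "synthetic"
                  ) -> list[SegmentRecord]:
    """Read a dataset directory (or a single subject file / CSV segment)."""
    path = Path(path)
    if source == "synthetic":
        if path.is_dir():
            manifest = read_manifest(path / "manifest.csv")
            records = []
            for sub_path in sorted(set(manifest["path"])):
                records.extend(_read_subject_file(Path(sub_path)))
            return records
        return _read_subject_file(path)
    if source == "csv":
        return [read_csv_segment(path)]
    raise ValueError(f"unknown source {source!r} (use 'synthetic' or 'csv')")


def read_csv_segment(path: Path | str, *, rhythm: Rhythm = Rhythm.NSR,
                     gravitational_units: bool = False) -> SegmentRecord:
    """Adapter for plain-text segments: columns time, ppg[, accx, accy, accz].

    The sampling rate is inferred from the time column; rates above
    50 Hz are resampled down.  Missing accelerometer columns yield the
    constant 9.8 m/s^2 convention; tri-axial columns are reduced to
    their Euclidean magnitude (x 9.8 if recorded in gravitational units).
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "time" not in df.columns or "ppg" not in df.columns:
        raise ValueError(f"{path.name}: need at least columns 'time' and 'ppg'")
    t = df["time"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path.name}: field 'time' has fewer than 2 samples")
    fs_in = 1.0 / float(np.median(np.diff(t)))
    ppg = df["ppg"].to_numpy(dtype=float)
    if not np.all(np.isfinite(ppg)):
        raise ValueError(f"{path.name}: field 'ppg' contains non-finite values")
    acc_cols = [c for c in ("accx", "accy", "accz") if c in df.columns]
    if acc_cols:
        acc = np.sqrt((df[acc_cols].to_numpy(dtype=float) ** 2).sum(axis=1))
        if gravitational_units:
            acc = acc * 9.8
    else:
        acc = np.full(ppg.size, 9.8)
    if fs_in > 50.5:
        ppg = resample_to_50hz(ppg, fs_in)
        acc = resample_to_50hz(acc, fs_in)
    for name, arr in (("ppg", ppg), ("acc", acc)):
        if arr.size < L:
            raise ValueError(f"{path.name}: field '{name}' shorter than 30 s "
                             f"at 50 Hz ({arr.size} < {L})")
    ppg, acc = ppg[:L], np.clip(acc[:L], 0.0, None)
    beats = BeatTrain(beat_times=np.empty(0), premature_flags=np.empty(0, bool),
                      rhythm=rhythm)
    return SegmentRecord(subject_id=path.stem, segment_id=path.stem,
                         ppg=ppg, acc=acc, beats=beats,
                         artifact_mask=np.zeros(L, dtype=bool),
                         rhythm_label=rhythm, source="csv")


def dataset_to_arrays(records: Iterable[SegmentRecord],
                      cfg: ChannelConfig = ChannelConfig()
                      ) -> tuple[ArrayDataset, list[tuple[str, str]]]:
    """Preprocess records into a model-ready :class:`ArrayDataset`.

    Segments whose requested channels cannot be computed (e.g. HR
    undefined) are dropped; their ids and reasons are returned alongside.
    """
    xs, ys, subs, ids = [], [], [], []
    rejected: list[tuple[str, str]] = []
    for rec in records:
        try:
            matrix = assemble_input(rec, cfg)
        except SegmentRejected as exc:
            rejected.append((rec.segment_id, str(exc)))
            continue
        xs.append(matrix.values.astype(np.float32))
        ys.append(int(rec.rhythm_label))
        subs.append(rec.subject_id)
        ids.append(rec.segment_id)
    x = np.stack(xs) if xs else np.empty((0, L, cfg.d), dtype=np.float32)
    return ArrayDataset(x=x, y=np.asarray(ys, dtype=np.int64),
                        subjects=np.asarray(subs), segment_ids=np.asarray(ids)), rejected
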