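"""Stable on-disk formats for recordings, labels, segment sets and manifests.

Formats
-------
* recording: CSV with header ``time_s,eda,ecg,emg`` (one row per sample,
  constant time step); a ``column_map`` adapts foreign dialects.
* labels: CSV with header ``subject_id,trial_index,level,onset_s``; onsets
  are stored in seconds so resampling never invalidates them.
* segment set: ``.npz`` array container plus a JSON metadata sidecar
  (``<path>.json``) describing modality, sampling rate and window layout.
* manifest: JSON listing per-subject file pairs.

Writers use fixed field order and fixed numeric formatting, so identical
inputs produce byte-identical files.  Readers validate rather than coerce.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError, ValidationError
from .synthetic import LEVELS, MultiModalRecording

__all__ = [
    "TrialLabel",
    "SegmentSet",
    "DatasetManifest",
    "write_recording",
    "read_recording",
    "write_labels",
    "read_labels",
    "write_segments",
    "read_segments",
    "write_manifest",
    "read_manifest",
]

RECORDING_COLUMNS = ("time_s", "eda", "ecg", "emg")
LABEL_COLUMNS = ("subject_id", "trial_index", "level", "onset_s")

_FLOAT_FMT = "%.12g"  # >= 9 significant digits round-trip, incl. the time base


@dataclass(frozen=True)
class TrialLabel:
    """One elicitation: who, which trial, what level, when."""

    subject_id: str
    trial_index: int
    level: str
    onset_s: float

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValidationError(
                f"unknown level {self.level!r}; expected one of {LEVELS}"
            )
        if self.onset_s < 0:
            raise ValidationError("onset_s must be >= 0")


@dataclass
class SegmentSet:
    """Fixed-length model-input windows for one modality.

    ``data`` has shape ``(n_windows, window_len, 1)``; parallel per-window
    arrays carry the pain level, the source subject, the source trial and an
    augmentation flag (augmented windows are training-only material).
    """

    modality: str
    data: np.ndarray
    labels: np.ndarray  # level strings, shape (n,)
    subject_ids: np.ndarray  # shape (n,)
    is_augmented: np.ndarray  # bool, shape (n,)
    trial_indices: np.ndarray  # int, shape (n,)
    fs_hz: float
    window_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[:, :, None]
        if self.data.ndim != 3 or self.data.shape[-1] != 1:
            raise ValidationError(
                f"segment data must have shape (n, window_len, 1); got {self.data.shape}"
            )
        n = self.data.shape[0]
        for name in ("labels", "subject_ids", "is_augmented", "trial_indices"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValidationError(f"{name} must have shape ({n},); got {arr.shape}")
            setattr(self, name, arr)

    @property
    def n_windows(self) -> int:
        return self.data.shape[0]

    @property
    def window_len(self) -> int:
        return self.data.shape[1]

    def select(self, mask: np.ndarray) -> "SegmentSet":
        return SegmentSet(
            modality=self.modality,
            data=self.data[mask],
            labels=self.labels[mask],
            subject_ids=self.subject_ids[mask],
            is_augmented=self.is_augmented[mask],
            trial_indices=self.trial_indices[mask],
            fs_hz=self.fs_hz,
            window_s=self.window_s,
        )


@dataclass
class DatasetManifest:
    """Index of a written cohort: (subject_id, recording_file, label_file)."""

    root: Path
    subjects: tuple[tuple[str, str, str], ...]
    fs_hz: float
    created_with: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.root = Path(self.root)
        ids = [s[0] for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValidationError("subject_ids in manifest must be unique")

    @property
    def subject_ids(self) -> list[str]:
        return [s[0] for s in self.subjects]


# --------------------------------------------------------------------------
# recordings


def write_recording(rec: MultiModalRecording, path: str | Path) -> Path:
    path = Path(path)
    n = rec.n_samples
    df = pd.DataFrame(
        {
            "time_s": np.arange(n) / rec.fs_hz,
            "eda": rec.eda,
            "ecg": rec.ecg,
            "emg": rec.emg,
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")
    return path


def read_recording(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    unit_scale: Mapping[str, float] | None = None,
    subject_id: str | None = None,
    dt_rtol: float = 1e-5,
) -> MultiModalRecording:
    """Load a recording CSV; ``column_map`` renames foreign columns
    (e.g. ``{"gsr": "eda"}``) and ``unit_scale`` rescales them after renaming.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    t = df["time_s"].to_numpy(float)
    if len(t) < 2:
        raise FormatError(f"{path}: need at least two samples")
    dt = np.diff(t)
    dt0 = float(np.median(dt))
    if dt0 <= 0 or np.any(np.abs(dt - dt0) > dt_rtol * dt0 + 1e-12):
        raise FormatError(f"{path}: non-uniform time step")
    scale = dict(unit_scale or {})
    arrays = {
        m: df[m].to_numpy(float) * float(scale.get(m, 1.0)) for m in ("eda", "ecg", "emg")
    }
    return MultiModalRecording(
        subject_id=subject_id if subject_id is not None else path.stem,
        fs_hz=1.0 / dt0,
        **arrays,
    )


# --------------------------------------------------------------------------
# labels


def write_labels(labels: Sequence[TrialLabel], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "subject_id": [l.subject_id for l in labels],
            "trial_index": [l.trial_index for l in labels],
            "level": [l.level for l in labels],
            "onset_s": [l.onset_s for l in labels],
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")
    return path


def read_labels(path: str | Path) -> list[TrialLabel]:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    labels = [
        TrialLabel(
            subject_id=str(row.subject_id),
            trial_index=int(row.trial_index),
            level=str(row.level),
            onset_s=float(row.onset_s),
        )
        for row in df.itertuples(index=False)
    ]
    labels.sort(key=lambda l: l.onset_s)
    seen: dict[str, set[int]] = {}
    for l in labels:
        if l.trial_index in seen.setdefault(l.subject_id, set()):
            raise ValidationError(
                f"{path}: duplicate trial_index {l.trial_index} for {l.subject_id}"
            )
        seen[l.subject_id].add(l.trial_index)
    return labels


# --------------------------------------------------------------------------
# segment sets


def write_segments(segments: SegmentSet, path: str | Path) -> Path:
    path = Path(path)
    np.savez(
        path,
        data=segments.data,
        labels=segments.labels.astype(str),
        subject_ids=segments.subject_ids.astype(str),
        is_augmented=segments.is_augmented.astype(bool),
        trial_indices=segments.trial_indices.astype(np.int64),
    )
    path = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    sidecar = {
        "modality": segments.modality,
        "fs_hz": segments.fs_hz,
        "window_s": segments.window_s,
        "n_windows": int(segments.n_windows),
        "window_len": int(segments.window_len),
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def read_segments(path: str | Path) -> SegmentSet:
    path = Path(path)
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing metadata sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    with np.load(path, allow_pickle=False) as npz:
        seg = SegmentSet(
            modality=meta["modality"],
            data=npz["data"],
            labels=npz["labels"],
            subject_ids=npz["subject_ids"],
            is_augmented=npz["is_augmented"],
            trial_indices=npz["trial_indices"],
            fs_hz=float(meta["fs_hz"]),
            window_s=float(meta["window_s"]),
        )
    if seg.n_windows != meta["n_windows"] or seg.window_len != meta["window_len"]:
        raise FormatError(
            f"{path}: sidecar shape ({meta['n_windows']}, {meta['window_len']}) "
            f"does not match stored arrays {seg.data.shape[:2]}"
        )
    return seg


# --------------------------------------------------------------------------
# manifests


def write_manifest(manifest: DatasetManifest, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "fs_hz": manifest.fs_hz,
        "subjects": [list(s) for s in manifest.subjects],
        "created_with": manifest.created_with,
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def read_manifest(path: str | Path, check_files: bool = True) -> DatasetManifest:
    path = Path(path)
    payload = json.loads(path.read_text())
    manifest = DatasetManifest(
        root=path.parent,
        subjects=tuple(tuple(s) for s in payload["subjects"]),
        fs_hz=float(payload["fs_hz"]),
        created_with=payload.get("created_with", {}),
    )
    if check_files:
        signals = manifest.created_with.get("signals_written", True)
        for sid, rec_file, label_file in manifest.subjects:
            if not (manifest.root / label_file).exists():
                raise FormatError(f"manifest references missing file {label_file}")
            if signals and not (manifest.root / rec_file).exists():
                raise FormatError(f"manifest references missing file {rec_file}")
    return manifest
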