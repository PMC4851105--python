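"""Domain types and dataset I/O.

One :class:`EmgRecording` holds the eight-channel surface-EMG trace of a
single golf shot plus shot metadata (subject, sex, club head speed, ball
carry distance).  A :class:`ShotDataset` is an ordered collection of
recordings grouped by subject; per-subject effectiveness labels for the
detection task are derived from it.

Channel order is fixed throughout the package::

    1 right FCR        2 right EDC       3 left FCR        4 left EDC
    5 right rhomboideus  6 right trapezius  7 left rhomboideus  8 left trapezius

(FCR = flexor carpi radialis, EDC = extensor digitorum communis.)  Channel 8,
the left trapezius, is the reference muscle for activation timing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

N_CHANNELS = 8

#: Canonical channel names, index 0 = channel 1.
CHANNEL_NAMES: tuple[str, ...] = (
    "right_fcr",
    "right_edc",
    "left_fcr",
    "left_edc",
    "right_rhomboideus",
    "right_trapezius",
    "left_rhomboideus",
    "left_trapezius",
)

#: Index (0-based) of the reference channel (left trapezius, channel 8).
REFERENCE_CHANNEL = 7

METADATA_COLUMNS = ("shot_id", "subject_id", "sex", "speed", "distance")


@dataclass
class EmgRecording:
    """Eight-channel surface-EMG trace of one golf shot.

    Parameters
    ----------
    shot_id, subject_id : str
        Identifiers; several shots share a subject.
    sex : int
        0 = woman, 1 = man.
    signal : ndarray of shape (8, T)
        Raw amplitudes in arbitrary voltage units (may be signed).
    fs : float
        Sampling rate in Hz (1000 for the reference hardware).
    speed, distance : float or None
        Target attributes: club head speed and ball carry distance.
    """

    shot_id: str
    subject_id: str
    sex: int
    signal: np.ndarray
    fs: float = 1000.0
    speed: float | None = None
    distance: float | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2 or self.signal.shape[0] != N_CHANNELS:
            raise ValueError(
                f"shot {self.shot_id!r}: signal must be {N_CHANNELS} x T, "
                f"got shape {self.signal.shape}"
            )
        if self.fs <= 0:
            raise ValueError(f"shot {self.shot_id!r}: fs must be positive")
        if self.signal.shape[1] < self.fs:
            raise ValueError(
                f"shot {self.shot_id!r}: need at least 1 s of signal "
                f"({int(self.fs)} samples), got {self.signal.shape[1]}"
            )
        if self.sex not in (0, 1):
            raise ValueError(f"shot {self.shot_id!r}: sex must be 0 or 1")
        for name in ("speed", "distance"):
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise ValueError(f"shot {self.shot_id!r}: {name} must be > 0")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs


@dataclass
class ShotDataset:
    """Ordered collection of shot recordings grouped by subject."""

    recordings: list[EmgRecording] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.recordings = list(self.recordings)
        counts: dict[str, int] = {}
        seen: set[str] = set()
        for rec in self.recordings:
            if rec.shot_id in seen:
                raise ValueError(f"duplicate shot_id {rec.shot_id!r}")
            seen.add(rec.shot_id)
            counts[rec.subject_id] = counts.get(rec.subject_id, 0) + 1
        for subject, n in counts.items():
            if n < 2:
                raise ValueError(
                    f"subject {subject!r} needs >=2 shots for a personal "
                    f"average, has {n}"
                )

    def __len__(self) -> int:
        return len(self.recordings)

    def __iter__(self) -> Iterator[EmgRecording]:
        return iter(self.recordings)

    def __getitem__(self, i: int) -> EmgRecording:
        return self.recordings[i]

    @property
    def shot_ids(self) -> list[str]:
        return [r.shot_id for r in self.recordings]

    @property
    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.recordings]

    @property
    def subjects(self) -> list[str]:
        """Unique subject ids in first-appearance order."""
        out: list[str] = []
        for r in self.recordings:
            if r.subject_id not in out:
                out.append(r.subject_id)
        return out

    def metadata(self) -> pd.DataFrame:
        """Per-shot metadata table (shot_id, subject_id, sex, speed, distance)."""
        return pd.DataFrame(
            {
                "shot_id": self.shot_ids,
                "subject_id": self.subject_ids,
                "sex": [r.sex for r in self.recordings],
                "speed": [r.speed for r in self.recordings],
                "distance": [r.distance for r in self.recordings],
            }
        )


def effectiveness_labels(ds: ShotDataset, target: str) -> np.ndarray:
    """Binary per-shot effectiveness labels for the detection task.

    A shot is *effective* (label 1) iff its target value is strictly above
    the shooting subject's own mean for that attribute; ties and values at
    or below the personal average are *ineffective* (label 0).

    Parameters
    ----------
    ds : ShotDataset
    target : {"speed", "distance"}

    Returns
    -------
    ndarray of int, shape (n_shots,)
    """
    if target not in ("speed", "distance"):
        raise ValueError(f"target must be 'speed' or 'distance', got {target!r}")
    values = np.array(
        [getattr(r, target) if getattr(r, target) is not None else np.nan
         for r in ds],
        dtype=float,
    )
    if np.isnan(values).any():
        missing = [r.shot_id for r, v in zip(ds, values) if np.isnan(v)]
        raise ValueError(f"missing {target} for shots: {missing}")
    subjects = np.asarray(ds.subject_ids)
    labels = np.zeros(len(ds), dtype=int)
    for subject in np.unique(subjects):
        mask = subjects == subject
        labels[mask] = (values[mask] > values[mask].mean()).astype(int)
    return labels


# ---------------------------------------------------------------------------
# Readers / writers.  Canonical on-disk dialect: "csv-wide" = one CSV per
# shot (8 named columns, one row per sample) plus a metadata CSV.

def _signal_path(root: Path, shot_id: str) -> Path:
    return root / f"{shot_id}.csv"


def write_dataset(ds: ShotDataset, path: str | Path, format: str = "csv-wide") -> None:
    """Write a dataset to disk in the canonical csv-wide layout.

    ``path`` becomes a directory holding ``metadata.csv`` plus one
    ``<shot_id>.csv`` per shot with the 8 channel columns.
    """
    if format != "csv-wide":
        raise ValueError(f"unsupported write format {format!r}")
    if len(ds) == 0:
        raise ValueError("refusing to write an empty dataset")
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    meta = ds.metadata()
    meta.to_csv(root / "metadata.csv", index=False)
    fs_map = {r.shot_id: r.fs for r in ds}
    (root / "sampling.json").write_text(json.dumps(fs_map, indent=0))
    for rec in ds:
        df = pd.DataFrame(rec.signal.T, columns=list(CHANNEL_NAMES))
        df.to_csv(_signal_path(root, rec.shot_id), index=False,
                  float_format="%.17g")


def read_dataset(path: str | Path, format: str = "csv-wide") -> ShotDataset:
    """Read a dataset from the canonical csv-wide layout.

    Channel columns may appear in any order; they are normalized to the
    fixed channel map by header name.
    """
    if format != "csv-wide":
        raise ValueError(f"unsupported read format {format!r}")
    root = Path(path)
    meta_path = root / "metadata.csv"
    if not meta_path.exists():
        raise FileNotFoundError(f"no metadata.csv under {root}")
    meta = pd.read_csv(meta_path, dtype={"shot_id": str, "subject_id": str})
    for col in METADATA_COLUMNS:
        if col not in meta.columns:
            raise ValueError(f"metadata.csv missing column {col!r}")
    fs_path = root / "sampling.json"
    fs_map = json.loads(fs_path.read_text()) if fs_path.exists() else {}
    recs = []
    for row in meta.itertuples(index=False):
        sig_path = _signal_path(root, row.shot_id)
        if not sig_path.exists():
            raise FileNotFoundError(f"shot {row.shot_id!r}: no signal file {sig_path}")
        df = pd.read_csv(sig_path, float_precision="round_trip")
        missing = [c for c in CHANNEL_NAMES if c not in df.columns]
        if missing:
            raise ValueError(f"shot {row.shot_id!r}: missing channel(s) {missing}")
        try:
            signal = df[list(CHANNEL_NAMES)].to_numpy(dtype=float).T
        except ValueError as exc:
            raise ValueError(f"shot {row.shot_id!r}: non-numeric samples: {exc}") from exc
        recs.append(
            EmgRecording(
                shot_id=str(row.shot_id),
                subject_id=str(row.subject_id),
                sex=int(row.sex),
                signal=signal,
                fs=float(fs_map.get(str(row.shot_id), 1000.0)),
                speed=None if pd.isna(row.speed) else float(row.speed),
                distance=None if pd.isna(row.distance) else float(row.distance),
            )
        )
    return ShotDataset(recs)


def validate_dataset(ds: ShotDataset) -> list[str]:
    """Return a list of human-readable validation notes (empty = clean)."""
    notes: list[str] = []
    for rec in ds:
        if not np.isfinite(rec.signal).all():
            notes.append(f"shot {rec.shot_id}: non-finite samples")
        if rec.speed is None or rec.distance is None:
            notes.append(f"shot {rec.shot_id}: missing target attribute(s)")
    return notes
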