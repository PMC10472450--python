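"""Core data containers for BCG/ECG signal processing.

Sample indices are 0-based throughout; a sample index ``i`` corresponds to
time ``start_time + i / fs`` seconds.  The containers validate their
invariants at construction so that downstream stages never see malformed
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SignalRecord",
    "PeakList",
    "BeatAnnotations",
    "read_record",
    "write_record",
    "read_annotations",
    "write_annotations",
]


class RecordError(ValueError):
    """Raised for malformed records, peak lists or annotations."""


@dataclass
class SignalRecord:
    """Uniformly sampled multichannel time series.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz (positive).
    channels : dict of str -> ndarray
        Ordered map of channel label to sample vector.  All vectors must
        have the same length and contain only finite values.  The channel
        ``"bcg"`` is required for beat detection; ``"ecg"`` is optional and
        only used as an evaluation reference.
    start_time : float
        Time offset of sample 0, in seconds.
    meta : dict
        Free-form provenance (device, subject id, simulation config, ...).
    """

    fs: float
    channels: dict
    start_time: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise RecordError(f"sampling rate must be positive, got {self.fs}")
        if not self.channels:
            raise RecordError("record must contain at least one channel")
        clean: dict[str, np.ndarray] = {}
        n = None
        for label, samples in self.channels.items():
            arr = np.asarray(samples, dtype=float)
            if arr.ndim != 1 or arr.size < 1:
                raise RecordError(f"channel {label!r} must be a non-empty 1-D vector")
            if not np.all(np.isfinite(arr)):
                bad = int(np.flatnonzero(~np.isfinite(arr))[0])
                raise RecordError(f"channel {label!r} has non-finite sample at index {bad}")
            if n is None:
                n = arr.size
            elif arr.size != n:
                raise RecordError(
                    f"channel {label!r} has length {arr.size}, expected {n}"
                )
            clean[str(label)] = arr
        self.channels = clean

    @property
    def n_samples(self) -> int:
        return next(iter(self.channels.values())).size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.channels[label]
        except KeyError:
            raise RecordError(f"record has no channel {label!r}") from None

    def with_channel(self, label: str, samples: np.ndarray) -> "SignalRecord":
        """Return a copy with one channel replaced (or added)."""
        channels = dict(self.channels)
        channels[label] = np.asarray(samples, dtype=float)
        return SignalRecord(self.fs, channels, self.start_time, dict(self.meta))


@dataclass
class PeakList:
    """Detected peak positions with amplitudes.

    ``source`` tags where the peaks came from: ``"stft"`` for band-energy
    candidates, ``"imf"`` for low-threshold mode peaks, ``"raw"`` for peaks
    on the (filtered) raw signal such as ECG R waves.
    """

    indices: np.ndarray
    amplitudes: np.ndarray
    source: str = "raw"
    threshold_used: float = float("nan")

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.indices.size != self.amplitudes.size:
            raise RecordError("indices and amplitudes must have equal length")
        if self.indices.size > 1 and not np.all(np.diff(self.indices) > 0):
            raise RecordError("peak indices must be strictly increasing")
        if self.source not in ("stft", "imf", "raw"):
            raise RecordError(f"unknown peak source {self.source!r}")

    def __len__(self) -> int:
        return int(self.indices.size)


# Sentinel for an absent I or K wave inside a beat tuple.
MISSING = -1


@dataclass
class BeatAnnotations:
    """Per-beat I/J/K sample indices with validity flags.

    ``beats`` is a sequence of ``(i_idx, j_idx, k_idx)`` integer triples;
    an absent I or K wave is encoded as ``None`` (stored internally as -1).
    ``valid`` marks beats usable for morphology: interpolated, edge-trimmed
    or incomplete beats carry ``valid=False`` but keep their J for rate
    estimation where sensible.
    """

    beats: Sequence
    valid: Sequence
    fs: float
    min_gap_s: float = 0.3

    def __post_init__(self) -> None:
        rows = []
        for b, beat in enumerate(self.beats):
            i_idx, j_idx, k_idx = beat
            i_idx = MISSING if i_idx is None else int(i_idx)
            k_idx = MISSING if k_idx is None else int(k_idx)
            j_idx = int(j_idx)
            if i_idx != MISSING and i_idx >= j_idx:
                raise RecordError(f"beat {b}: I index {i_idx} not before J {j_idx}")
            if k_idx != MISSING and k_idx <= j_idx:
                raise RecordError(f"beat {b}: K index {k_idx} not after J {j_idx}")
            rows.append((i_idx, j_idx, k_idx))
        arr = np.asarray(rows, dtype=np.int64).reshape(-1, 3)
        valid = np.asarray(self.valid, dtype=bool)
        if valid.size != arr.shape[0]:
            raise RecordError("valid flags must match number of beats")
        if self.fs <= 0:
            raise RecordError("fs must be positive")
        j = arr[:, 1]
        if j.size > 1:
            gaps = np.diff(j)
            if np.any(gaps <= 0):
                raise RecordError("J indices must be strictly increasing")
            min_gap = self.min_gap_s * self.fs
            if np.any(gaps < min_gap):
                bad = int(np.flatnonzero(gaps < min_gap)[0])
                raise RecordError(
                    f"beats {bad} and {bad + 1} are {gaps[bad] / self.fs:.3f} s apart, "
                    f"below the {self.min_gap_s} s physiological floor"
                )
        self._arr = arr
        self.valid = valid

    @property
    def n_beats(self) -> int:
        return int(self._arr.shape[0])

    def __len__(self) -> int:
        return self.n_beats

    @property
    def i_indices(self) -> np.ndarray:
        """I sample indices; -1 where absent."""
        return self._arr[:, 0]

    @property
    def j_indices(self) -> np.ndarray:
        return self._arr[:, 1]

    @property
    def k_indices(self) -> np.ndarray:
        """K sample indices; -1 where absent."""
        return self._arr[:, 2]

    def beat_tuples(self) -> list:
        """Beats as (i, j, k) with ``None`` for absent waves."""
        out = []
        for i_idx, j_idx, k_idx in self._arr:
            out.append(
                (None if i_idx == MISSING else int(i_idx),
                 int(j_idx),
                 None if k_idx == MISSING else int(k_idx))
            )
        return out

    def jj_intervals_s(self) -> np.ndarray:
        """Successive J-J intervals in seconds."""
        return np.diff(self._arr[:, 1]) / self.fs


def read_record(path, fs: float, column_map: Mapping[str, str] | None = None) -> SignalRecord:
    """Read a delimited-text record file into a :class:`SignalRecord`.

    The file must have a header row naming each column; every column except
    an optional leading time column (named ``t`` or ``time``, ignored — the
    supplied ``fs`` is authoritative) becomes a channel.  ``column_map``
    optionally renames file columns to channel labels.
    """
    path = Path(path)
    if not path.exists():
        raise RecordError(f"record file not found: {path}")
    if fs <= 0:
        raise RecordError(f"sampling rate must be positive, got {fs}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # ragged rows, empty file, ...
        raise RecordError(f"cannot parse record file {path}: {exc}") from exc
    channels: dict[str, np.ndarray] = {}
    for col in df.columns:
        if col.lower() in ("t", "time"):
            continue
        label = column_map.get(col, col) if column_map else col
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            row = int(np.flatnonzero(~np.isfinite(vals))[0])
            raise RecordError(
                f"non-numeric or non-finite cell in column {col!r}, data row {row} of {path}"
            )
        channels[label] = vals
    if not channels:
        raise RecordError(f"no numeric signal columns in {path}")
    return SignalRecord(fs=fs, channels=channels, meta={"path": str(path)})


def write_record(record: SignalRecord, path, include_time: bool = True) -> None:
    """Write a record as CSV with a header row, one column per channel."""
    path = Path(path)
    data = {}
    if include_time:
        n = record.n_samples
        data["t"] = record.start_time + np.arange(n) / record.fs
    data.update({label: v for label, v in record.channels.items()})
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")


def write_annotations(ann: BeatAnnotations, path) -> None:
    """Write beat annotations as CSV with columns beat,i,j,k,valid.

    Absent I/K waves are written as empty fields so the round trip
    preserves absence.
    """
    path = Path(path)
    rows = []
    for b, (i_idx, j_idx, k_idx) in enumerate(ann.beat_tuples()):
        rows.append(
            {
                "beat": b,
                "i": "" if i_idx is None else i_idx,
                "j": j_idx,
                "k": "" if k_idx is None else k_idx,
                "valid": int(ann.valid[b]),
            }
        )
    pd.DataFrame(rows, columns=["beat", "i", "j", "k", "valid"]).to_csv(path, index=False)


def read_annotations(path, fs: float) -> BeatAnnotations:
    """Read a beat-annotation CSV written by :func:`write_annotations`."""
    path = Path(path)
    if not path.exists():
        raise RecordError(f"annotation file not found: {path}")
    df = pd.read_csv(path, dtype={"i": "Int64", "j": "Int64", "k": "Int64", "valid": "Int64"})
    required = {"beat", "i", "j", "k", "valid"}
    if not required.issubset(df.columns):
        raise RecordError(f"annotation file {path} missing columns {sorted(required - set(df.columns))}")
    beats = []
    valid = []
    for row_no, row in df.iterrows():
        if pd.isna(row["j"]) or pd.isna(row["valid"]):
            raise RecordError(f"malformed annotation row {row_no} in {path}")
        beats.append(
            (None if pd.isna(row["i"]) else int(row["i"]),
             int(row["j"]),
             None if pd.isna(row["k"]) else int(row["k"]))
        )
        valid.append(bool(row["valid"]))
    return BeatAnnotations(beats=beats, valid=valid, fs=fs)
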