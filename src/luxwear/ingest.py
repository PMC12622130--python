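"""Reading, validating and labelling chest-worn light-logger recordings.

The device exports one row per minute with photopic illuminance (lux),
melanopic equivalent daylight illuminance (mEDI, lux), an accelerometer
time-above-threshold count (TAT) and an orientation code:

* ``2``  — hanging upright as a pendant (the worn position),
* ``16`` — lying face up,
* ``32`` — lying face down.

Other codes are permitted and treated as "other" downstream. A light diary
supplies ground-truth intervals describing how the device was actually used;
``label_stream`` converts those intervals into the three modelling outcomes
(wear, non-wear, appropriate night placement).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

ORIENTATION_UPRIGHT = 2
ORIENTATION_FACE_UP = 16
ORIENTATION_FACE_DOWN = 32

#: Device photometric operating range, lux.
LUX_MIN = 0.0
LUX_MAX = 100_000.0


class Condition(str, Enum):
    """Diary wear-condition categories (the nine tester conditions)."""

    WEAR_ACTIVE = "WEAR_ACTIVE"
    WEAR_SEDENTARY = "WEAR_SEDENTARY"
    WEAR_INDOOR = "WEAR_INDOOR"
    WEAR_OUTDOOR = "WEAR_OUTDOOR"
    NIGHT_FACE_UP = "NIGHT_FACE_UP"
    NIGHT_FACE_DOWN = "NIGHT_FACE_DOWN"
    NONWEAR_STATIONARY_LIGHT = "NONWEAR_STATIONARY_LIGHT"
    NONWEAR_STATIONARY_DARK = "NONWEAR_STATIONARY_DARK"
    NONWEAR_MOBILE_DARK = "NONWEAR_MOBILE_DARK"


class WearClass(str, Enum):
    """Per-minute modelling outcome."""

    WEAR = "WEAR"
    NONWEAR = "NONWEAR"
    NIGHT_OK = "NIGHT_OK"
    UNKNOWN = "UNKNOWN"


#: Diary condition -> ground-truth class. Night placement face down is
#: non-adherent use, so it maps to NONWEAR; the third outcome is reserved for
#: *appropriate* night placement (face up).
CONDITION_CLASS: dict[Condition, WearClass] = {
    Condition.WEAR_ACTIVE: WearClass.WEAR,
    Condition.WEAR_SEDENTARY: WearClass.WEAR,
    Condition.WEAR_INDOOR: WearClass.WEAR,
    Condition.WEAR_OUTDOOR: WearClass.WEAR,
    Condition.NIGHT_FACE_UP: WearClass.NIGHT_OK,
    Condition.NIGHT_FACE_DOWN: WearClass.NONWEAR,
    Condition.NONWEAR_STATIONARY_LIGHT: WearClass.NONWEAR,
    Condition.NONWEAR_STATIONARY_DARK: WearClass.NONWEAR,
    Condition.NONWEAR_MOBILE_DARK: WearClass.NONWEAR,
}

#: Canonical field -> default CSV column name.
DEFAULT_DIALECT: dict[str, str] = {
    "timestamp": "timestamp",
    "photopic_lux": "photopic_lux",
    "medi_lux": "medi_lux",
    "tat": "tat",
    "orientation": "orientation",
}


@dataclass(frozen=True)
class Gap:
    """A break in minute sampling: ``minutes`` missing before ``index``."""

    index: int
    minutes: int


@dataclass
class RecordingStream:
    """Minute-indexed light-logger time series for one participant.

    Timestamps are timezone-naive local clock time, strictly increasing, and
    spaced exactly one minute apart within a contiguous segment; larger
    whole-minute gaps between segments are allowed and flagged in ``gaps``.
    """

    participant_id: str
    timestamps: pd.DatetimeIndex
    photopic_lux: np.ndarray
    medi_lux: np.ndarray
    tat_count: np.ndarray
    orientation_code: np.ndarray
    gaps: list[Gap] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.photopic_lux = np.asarray(self.photopic_lux, dtype=float)
        self.medi_lux = np.asarray(self.medi_lux, dtype=float)
        self.tat_count = np.asarray(self.tat_count, dtype=np.int64)
        self.orientation_code = np.asarray(self.orientation_code, dtype=np.int64)

        n = len(self.timestamps)
        if n == 0:
            raise DataError("empty recording stream")
        for name in ("photopic_lux", "medi_lux", "tat_count", "orientation_code"):
            if len(getattr(self, name)) != n:
                raise DataError(
                    f"{name} length {len(getattr(self, name))} != {n} timestamps"
                )
        diffs_s = np.diff(self.timestamps.asi8) / 1e9
        bad = np.where(diffs_s <= 0)[0]
        if bad.size:
            i = int(bad[0]) + 1
            raise DataError(
                f"timestamps not strictly increasing at position {i} "
                f"({self.timestamps[i]})"
            )
        frac = np.where(np.mod(diffs_s, 60.0) != 0)[0]
        if frac.size:
            i = int(frac[0]) + 1
            raise DataError(
                f"non-whole-minute sampling interval before position {i}"
            )
        for name in ("photopic_lux", "medi_lux"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                raise DataError(f"{name} contains non-finite values")
            if np.any(arr < 0):
                raise DataError(f"{name} contains negative values")
        if np.any(self.tat_count < 0):
            raise DataError("tat_count contains negative values")

        self.gaps = [
            Gap(index=int(i) + 1, minutes=int(diffs_s[i] // 60))
            for i in np.where(diffs_s > 60)[0]
        ]

    def __len__(self) -> int:
        return len(self.timestamps)

    def subset(self, mask: np.ndarray) -> "RecordingStream":
        """New stream restricted to ``mask`` (gaps are recomputed)."""
        mask = np.asarray(mask)
        return RecordingStream(
            participant_id=self.participant_id,
            timestamps=self.timestamps[mask],
            photopic_lux=self.photopic_lux[mask],
            medi_lux=self.medi_lux[mask],
            tat_count=self.tat_count[mask],
            orientation_code=self.orientation_code[mask],
        )

    def day_mask(self, day) -> np.ndarray:
        """Mask of minutes falling on calendar date ``day``."""
        return np.asarray(self.timestamps.normalize() == pd.Timestamp(day))

    @property
    def dates(self) -> list[pd.Timestamp]:
        return list(self.timestamps.normalize().unique())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.timestamps,
                "photopic_lux": self.photopic_lux,
                "medi_lux": self.medi_lux,
                "tat": self.tat_count,
                "orientation": self.orientation_code,
            }
        )


@dataclass(frozen=True)
class DiaryInterval:
    """Half-open diary interval [start, end) with a wear condition."""

    start: pd.Timestamp
    end: pd.Timestamp
    condition: Condition

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise DataError(f"diary interval end {self.end} <= start {self.start}")

    @property
    def duration_minutes(self) -> float:
        return (self.end - self.start).total_seconds() / 60.0


@dataclass
class LabeledStream:
    """A RecordingStream with per-minute ground-truth classes."""

    stream: RecordingStream
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="U8")
        if len(self.labels) != len(self.stream):
            raise DataError("label length differs from stream length")
        valid = {c.value for c in WearClass}
        unknown = set(np.unique(self.labels)) - valid
        if unknown:
            raise DataError(f"invalid class labels: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.stream)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.stream.timestamps

    def subset(self, mask: np.ndarray) -> "LabeledStream":
        mask = np.asarray(mask)
        return LabeledStream(self.stream.subset(mask), self.labels[mask])


def _resolve_dialect(dialect: Mapping[str, str] | None) -> dict[str, str]:
    d = dict(DEFAULT_DIALECT)
    if dialect:
        extra = set(dialect) - set(DEFAULT_DIALECT)
        if extra:
            raise ConfigurationError(f"unknown dialect keys: {sorted(extra)}")
        d.update(dialect)
    return d


def read_device_csv(
    path,
    dialect: Mapping[str, str] | None = None,
    participant_id: str | None = None,
) -> RecordingStream:
    """Read a device export CSV into a validated :class:`RecordingStream`.

    ``dialect`` maps canonical field names (``timestamp``, ``photopic_lux``,
    ``medi_lux``, ``tat``, ``orientation``) to the column names in the file.
    Rows whose timestamp cannot be parsed are dropped with a warning listing
    the offending file rows; non-monotonic timestamps raise :class:`DataError`
    naming the first offending row.
    """
    path = Path(path)
    d = _resolve_dialect(dialect)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [col for col in d.values() if col not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path.name}: mapped columns missing from file: {missing}"
        )
    ts = pd.to_datetime(df[d["timestamp"]], errors="coerce")
    bad = ts.isna()
    if bad.any():
        rows = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        warnings.warn(
            f"{path.name}: rejected {int(bad.sum())} rows with unparseable "
            f"timestamps (file rows {rows[:10]}{'...' if len(rows) > 10 else ''})",
            stacklevel=2,
        )
        df = df.loc[~bad]
        ts = ts.loc[~bad]
    if df.empty:
        raise DataError(f"{path.name}: no parseable rows")
    tsi = pd.DatetimeIndex(ts)
    nonmono = np.where(np.diff(tsi.asi8) <= 0)[0]
    if nonmono.size:
        row = int(df.index[int(nonmono[0]) + 1]) + 2
        raise DataError(
            f"{path.name}: non-monotonic timestamp at file row {row}"
        )
    return RecordingStream(
        participant_id=participant_id or path.stem,
        timestamps=tsi,
        photopic_lux=df[d["photopic_lux"]].to_numpy(dtype=float),
        medi_lux=df[d["medi_lux"]].to_numpy(dtype=float),
        tat_count=df[d["tat"]].to_numpy(dtype=np.int64),
        orientation_code=df[d["orientation"]].to_numpy(dtype=np.int64),
    )


def write_device_csv(stream: RecordingStream, path, dialect=None) -> None:
    """Write a stream back to CSV (inverse of :func:`read_device_csv`)."""
    d = _resolve_dialect(dialect)
    df = stream.to_frame()
    df.columns = [d[c] if c in d else c for c in
                  ("timestamp", "photopic_lux", "medi_lux", "tat", "orientation")]
    df.to_csv(path, index=False)


def read_diary(path) -> list[DiaryInterval]:
    """Read a diary CSV (columns start, end, condition) into sorted intervals.

    Conditions are matched case-insensitively against :class:`Condition`;
    overlapping intervals and unknown conditions raise :class:`DataError`.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("start", "end", "condition"):
        if col not in df.columns:
            raise ConfigurationError(f"{path.name}: diary misses column '{col}'")
    intervals = []
    for i, row in df.iterrows():
        name = str(row["condition"]).strip().upper()
        try:
            cond = Condition(name)
        except ValueError:
            raise DataError(
                f"{path.name} row {i + 2}: unknown condition '{row['condition']}'"
            ) from None
        intervals.append(
            DiaryInterval(
                start=pd.Timestamp(row["start"]),
                end=pd.Timestamp(row["end"]),
                condition=cond,
            )
        )
    return validate_diary(intervals)


def validate_diary(intervals: Iterable[DiaryInterval]) -> list[DiaryInterval]:
    """Sort intervals by start and reject overlapping pairs."""
    out = sorted(intervals, key=lambda iv: iv.start)
    for a, b in zip(out, out[1:]):
        if b.start < a.end:
            raise DataError(
                f"overlapping diary intervals: [{a.start}, {a.end}) "
                f"{a.condition.value} and [{b.start}, {b.end}) {b.condition.value}"
            )
    return out


def write_diary(intervals: Sequence[DiaryInterval], path) -> None:
    pd.DataFrame(
        {
            "start": [iv.start for iv in intervals],
            "end": [iv.end for iv in intervals],
            "condition": [iv.condition.value for iv in intervals],
        }
    ).to_csv(path, index=False)


def label_stream(
    stream: RecordingStream, diary: Iterable[DiaryInterval]
) -> LabeledStream:
    """Assign each minute its ground-truth class from the diary.

    Minutes inside an interval receive the mapped class (all WEAR_* map to
    WEAR, NIGHT_FACE_UP to NIGHT_OK, NIGHT_FACE_DOWN and all NONWEAR_* to
    NONWEAR); minutes outside every interval are UNKNOWN. Intervals are
    half-open so adjacent intervals never double-label a minute.
    """
    diary = validate_diary(diary)
    labels = np.full(len(stream), WearClass.UNKNOWN.value, dtype="U8")
    ts = stream.timestamps
    for iv in diary:
        mask = (ts >= iv.start) & (ts < iv.end)
        labels[np.asarray(mask)] = CONDITION_CLASS[iv.condition].value
    return LabeledStream(stream, labels)
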