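"""Day/night adherence scoring from per-minute predicted classes.

Adherence is at least 80% appropriate use inside a fixed clock window:
wear between 10:00 and 20:00 for days, appropriate (face-up) night placement
between 00:00 and 06:00 for nights. The fixed windows deliberately ignore the
weekday/weekend distinction. Minutes missing from the recording are excluded
from the denominator and reported, rather than counted as non-target; a
window with no recorded minutes yields a flagged-undefined fraction, not 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._time import ClockWindow, time_of_day_minutes
from .errors import ConfigurationError, DataError
from .ingest import WearClass

#: Participant-level preset mirroring an observed usable-week pattern
#: (at least 6 usable days and 3 usable nights).
USABLE_WEEK_PRESET = {"min_days": 6, "min_nights": 3}


@dataclass(frozen=True)
class AdherenceWindows:
    day: ClockWindow = field(default_factory=lambda: ClockWindow(600, 1200))
    night: ClockWindow = field(default_factory=lambda: ClockWindow(0, 360))
    threshold: float = 0.80

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold <= 1.0:
            raise ConfigurationError("adherence threshold must be in (0, 1]")


@dataclass(frozen=True)
class WindowFraction:
    """Fraction of recorded window minutes carrying the target class."""

    fraction: float | None
    n_target: int
    n_present: int
    n_expected: int
    defined: bool

    @property
    def n_missing(self) -> int:
        return self.n_expected - self.n_present


@dataclass
class AdherenceSummary:
    day_fractions: np.ndarray
    night_fractions: np.ndarray
    adherent_day: np.ndarray
    adherent_night: np.ndarray
    n_adherent_days: int
    n_adherent_nights: int
    included: bool


def window_fraction(
    timestamps: pd.DatetimeIndex,
    classes: np.ndarray,
    window: ClockWindow,
    target: str | WearClass,
) -> WindowFraction:
    """Fraction of window minutes classified as ``target``.

    ``n_expected`` counts the window length once per calendar day touched by
    the series; the denominator is only the minutes actually recorded.
    """
    target = WearClass(target).value
    timestamps = pd.DatetimeIndex(timestamps)
    classes = np.asarray(classes, dtype="U8")
    if len(classes) != len(timestamps):
        raise DataError("classes length differs from timestamps length")
    tod = time_of_day_minutes(timestamps)
    in_window = window.contains(tod)
    n_present = int(in_window.sum())
    n_days = len(timestamps.normalize().unique())
    n_expected = window.duration_minutes * n_days
    if n_present == 0:
        return WindowFraction(
            fraction=None, n_target=0, n_present=0,
            n_expected=n_expected, defined=False,
        )
    n_target = int((classes[in_window] == target).sum())
    return WindowFraction(
        fraction=n_target / n_present,
        n_target=n_target,
        n_present=n_present,
        n_expected=n_expected,
        defined=True,
    )


def summarize_days(
    timestamps: pd.DatetimeIndex,
    classes: np.ndarray,
    windows: AdherenceWindows | None = None,
    night_target: str = WearClass.NIGHT_OK.value,
) -> pd.DataFrame:
    """Per calendar-day adherence table.

    Columns: day_fraction, night_fraction (NaN where undefined),
    adherent_day, adherent_night. The night window of a given date is the
    early morning of that same date. Night adherence counts ``night_target``
    minutes only (NIGHT_OK by default; callers may widen it).
    """
    windows = windows or AdherenceWindows()
    timestamps = pd.DatetimeIndex(timestamps)
    classes = np.asarray(classes, dtype="U8")
    rows = []
    for date in timestamps.normalize().unique():
        mask = np.asarray(timestamps.normalize() == date)
        ts_d, cl_d = timestamps[mask], classes[mask]
        day = window_fraction(ts_d, cl_d, windows.day, WearClass.WEAR)
        night = window_fraction(ts_d, cl_d, windows.night, night_target)
        rows.append(
            {
                "date": date,
                "day_fraction": np.nan if day.fraction is None else day.fraction,
                "night_fraction": (
                    np.nan if night.fraction is None else night.fraction
                ),
                "adherent_day": bool(
                    day.defined and day.fraction >= windows.threshold
                ),
                "adherent_night": bool(
                    night.defined and night.fraction >= windows.threshold
                ),
            }
        )
    return pd.DataFrame(rows).set_index("date")


def summarize_participant(
    day_fractions: Sequence[float],
    night_fractions: Sequence[float] | None = None,
    windows: AdherenceWindows | None = None,
    min_days: int = 1,
    min_nights: int = 0,
) -> AdherenceSummary:
    """Participant-level inclusion from per-day adherence fractions.

    A day (night) is adherent when its fraction is at least the threshold
    (strict >=); undefined fractions (None/NaN) are never adherent. The
    participant is included when the adherent-day count reaches ``min_days``
    and the adherent-night count reaches ``min_nights``.
    """
    windows = windows or AdherenceWindows()
    day = np.asarray(
        [np.nan if f is None else f for f in day_fractions], dtype=float
    )
    if day.size == 0:
        raise DataError("summarize_participant requires at least 1 day")
    if night_fractions is None:
        night = np.full_like(day, np.nan)
    else:
        night = np.asarray(
            [np.nan if f is None else f for f in night_fractions], dtype=float
        )
    with np.errstate(invalid="ignore"):
        adherent_day = np.where(np.isnan(day), False, day >= windows.threshold)
        adherent_night = np.where(
            np.isnan(night), False, night >= windows.threshold
        )
    n_days = int(adherent_day.sum())
    n_nights = int(adherent_night.sum())
    return AdherenceSummary(
        day_fractions=day,
        night_fractions=night,
        adherent_day=adherent_day.astype(bool),
        adherent_night=adherent_night.astype(bool),
        n_adherent_days=n_days,
        n_adherent_nights=n_nights,
        included=(n_days >= min_days) and (n_nights >= min_nights),
    )
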