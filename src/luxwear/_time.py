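"""Clock-time helpers shared across modules."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError

MINUTES_PER_DAY = 1440


def time_of_day_minutes(timestamps: pd.DatetimeIndex) -> np.ndarray:
    """Minutes since local midnight, in [0, 1440)."""
    ts = pd.DatetimeIndex(timestamps)
    return (
        ts.hour.to_numpy() * 60.0
        + ts.minute.to_numpy()
        + ts.second.to_numpy() / 60.0
    )


@dataclass(frozen=True)
class ClockWindow:
    """Half-open daily clock window [start_minute, end_minute).

    A window with ``start_minute >= end_minute`` wraps across midnight.
    """

    start_minute: int
    end_minute: int

    def __post_init__(self) -> None:
        for v in (self.start_minute, self.end_minute):
            if not 0 <= v <= MINUTES_PER_DAY:
                raise ConfigurationError(f"window bound {v} outside [0, 1440]")
        if self.start_minute == self.end_minute:
            raise ConfigurationError("empty clock window")

    @property
    def duration_minutes(self) -> int:
        if self.start_minute < self.end_minute:
            return self.end_minute - self.start_minute
        return MINUTES_PER_DAY - self.start_minute + self.end_minute

    def contains(self, tod_minutes: np.ndarray) -> np.ndarray:
        """Boolean mask of time-of-day values falling inside the window."""
        tod = np.asarray(tod_minutes, dtype=float)
        if self.start_minute < self.end_minute:
            return (tod >= self.start_minute) & (tod < self.end_minute)
        return (tod >= self.start_minute) | (tod < self.end_minute)

    def overlaps(self, other: "ClockWindow") -> bool:
        grid = np.arange(MINUTES_PER_DAY)
        return bool(np.any(self.contains(grid) & other.contains(grid)))
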