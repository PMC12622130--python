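"""Daily light-exposure metrics and 24-hour profile analysis.

Intensity is summarized as photopic luminous exposure (the 24-hour time
integral of photopic illuminance, in kilolux-hours) and as minutes per day in
bright light (photopic illuminance strictly above 1,000 lux). Timing is the
percent of time inside recommended mEDI bands for melatonin regulation: at
least 250 lux mEDI 07:00-17:00, at most 10 lux 20:00-23:00, and 1 lux or
less 00:00-06:00.

The 24-hour pattern is the per-minute mean of log10(lux + 1) across days with
a bootstrap CI over days, and an individual profile is compared to a
reference by the circular shift within +/-200 minutes that maximizes Pearson
correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._time import MINUTES_PER_DAY, ClockWindow, time_of_day_minutes
from .errors import ConfigurationError, DataError
from .ingest import RecordingStream


@dataclass(frozen=True)
class RecommendationSpec:
    """mEDI recommendation windows and limits (lux)."""

    day_window: ClockWindow = field(default_factory=lambda: ClockWindow(420, 1020))
    day_min_medi: float = 250.0
    evening_window: ClockWindow = field(
        default_factory=lambda: ClockWindow(1200, 1380)
    )
    evening_max_medi: float = 10.0
    night_window: ClockWindow = field(default_factory=lambda: ClockWindow(0, 360))
    night_max_medi: float = 1.0

    def __post_init__(self) -> None:
        if min(self.day_min_medi, self.evening_max_medi, self.night_max_medi) <= 0:
            raise ConfigurationError("recommendation limits must be > 0")
        wins = (self.day_window, self.evening_window, self.night_window)
        for i, a in enumerate(wins):
            for b in wins[i + 1:]:
                if a.overlaps(b):
                    raise ConfigurationError(
                        "recommendation windows must not overlap"
                    )


@dataclass(frozen=True)
class RecommendationCompliance:
    """Percent of recorded window minutes meeting each limit (None = no data)."""

    pct_day_ok: float | None
    pct_evening_ok: float | None
    pct_night_ok: float | None


@dataclass(frozen=True)
class LightMetrics:
    luminous_exposure_klxh: float
    bright_minutes: int
    pct_day_ok: float | None
    pct_evening_ok: float | None
    pct_night_ok: float | None


@dataclass
class DailyProfile:
    """1440-bin mean log10-illuminance profile with bootstrap CI."""

    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_days: int


@dataclass(frozen=True)
class ProfileShift:
    """Circular shift (minutes) applied to a profile that best aligns it
    with the reference, and the correlation achieved there.

    By this convention ``profile_shift(roll(p, s), p)`` returns ``-s``; a
    profile *delayed* relative to the reference therefore yields a negative
    value (the shift needed to pull it back into register).
    """

    shift_minutes: int
    peak_correlation: float


def _day_values(stream: RecordingStream, day, field_name: str) -> np.ndarray:
    mask = stream.day_mask(day)
    if not mask.any():
        raise DataError(f"no minutes recorded on {day}")
    n = int(mask.sum())
    if n < MINUTES_PER_DAY:
        warnings.warn(
            f"{stream.participant_id} {pd.Timestamp(day).date()}: "
            f"{MINUTES_PER_DAY - n} missing minutes contribute 0",
            stacklevel=3,
        )
    return getattr(stream, field_name)[mask]


def luminous_exposure(stream: RecordingStream, day) -> float:
    """Photopic luminous exposure on ``day`` in kilolux-hours.

    Each minute contributes lux / 60 lux-hours; missing minutes contribute 0
    (reported via a warning).
    """
    lux = _day_values(stream, day, "photopic_lux")
    return float(lux.sum() / 60.0 / 1000.0)


def bright_minutes(
    stream: RecordingStream, day, threshold_lux: float = 1000.0
) -> int:
    """Minutes on ``day`` with photopic illuminance strictly above threshold."""
    lux = _day_values(stream, day, "photopic_lux")
    return int((lux > threshold_lux).sum())


def _window_pct(tod, values, window: ClockWindow, ok) -> float | None:
    mask = window.contains(tod)
    if not mask.any():
        return None
    return float(100.0 * ok(values[mask]).mean())


def recommendation_compliance(
    stream: RecordingStream, spec: RecommendationSpec | None = None
) -> RecommendationCompliance:
    """Percent time within each recommended mEDI band over the whole stream.

    Boundaries follow the recommendation wording: at least 250 lux (>=),
    at most 10 lux (<=), 1 lux or less (<=). Windows with no recorded
    minutes are flagged as None.
    """
    spec = spec or RecommendationSpec()
    tod = time_of_day_minutes(stream.timestamps)
    medi = stream.medi_lux
    return RecommendationCompliance(
        pct_day_ok=_window_pct(
            tod, medi, spec.day_window, lambda v: v >= spec.day_min_medi
        ),
        pct_evening_ok=_window_pct(
            tod, medi, spec.evening_window, lambda v: v <= spec.evening_max_medi
        ),
        pct_night_ok=_window_pct(
            tod, medi, spec.night_window, lambda v: v <= spec.night_max_medi
        ),
    )


def day_metrics(
    stream: RecordingStream,
    day,
    spec: RecommendationSpec | None = None,
    bright_threshold_lux: float = 1000.0,
) -> LightMetrics:
    """All per-day exposure metrics for one calendar date."""
    sub = stream.subset(stream.day_mask(day))
    comp = recommendation_compliance(sub, spec)
    return LightMetrics(
        luminous_exposure_klxh=luminous_exposure(stream, day),
        bright_minutes=bright_minutes(stream, day, bright_threshold_lux),
        pct_day_ok=comp.pct_day_ok,
        pct_evening_ok=comp.pct_evening_ok,
        pct_night_ok=comp.pct_night_ok,
    )


def profile_matrix(
    stream: RecordingStream, field_name: str = "photopic_lux"
) -> tuple[list, np.ndarray]:
    """(dates, (n_days, 1440) array) of minute-of-day values, NaN = missing."""
    dates = stream.dates
    out = np.full((len(dates), MINUTES_PER_DAY), np.nan)
    tod = time_of_day_minutes(stream.timestamps).astype(int)
    values = getattr(stream, field_name)
    norm = stream.timestamps.normalize()
    for i, date in enumerate(dates):
        mask = np.asarray(norm == date)
        out[i, tod[mask]] = values[mask]
    return dates, out


def mean_log_profile(
    days: Sequence[np.ndarray] | np.ndarray,
    offset: float = 1.0,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> DailyProfile:
    """Mean log10(lux + offset) per minute-of-day with a bootstrap CI.

    ``days`` is a list/array of per-day 1440-minute lux vectors (NaN allowed
    for missing minutes). The CI resamples whole days with replacement; with
    a single day the interval is degenerate.
    """
    arr = np.asarray(days, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[1] != MINUTES_PER_DAY:
        raise DataError(f"day vectors must have {MINUTES_PER_DAY} minutes")
    if np.nanmin(arr) < 0:
        raise DataError("negative illuminance in profile input")
    logs = np.log10(arr + offset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(logs, axis=0)
        n_days = arr.shape[0]
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n_days, size=(n_boot, n_days))
        boots = np.nanmean(logs[idx], axis=1)  # (n_boot, 1440)
        alpha = (1.0 - level) / 2.0
        ci_low, ci_high = np.nanquantile(boots, [alpha, 1.0 - alpha], axis=0)
    return DailyProfile(mean=mean, ci_low=ci_low, ci_high=ci_high, n_days=n_days)


def smooth_profile(profile: np.ndarray, window_minutes: int) -> np.ndarray:
    """Optional circular moving-average smoothing (off by default upstream)."""
    if window_minutes < 1:
        raise ConfigurationError("window_minutes must be >= 1")
    kernel = np.ones(window_minutes) / window_minutes
    padded = np.r_[profile[-(window_minutes - 1):], profile] if window_minutes > 1 \
        else np.asarray(profile, dtype=float)
    return np.convolve(padded, kernel, mode="valid")


def profile_shift(
    profile: np.ndarray, reference: np.ndarray, max_shift: int = 200
) -> ProfileShift:
    """Best circular alignment of ``profile`` to ``reference``.

    Scans every integer shift s in [-max_shift, max_shift], correlating the
    circularly shifted profile with the reference, and returns the argmax.
    Ties are broken toward the smallest |s|, then the negative s. Profiles
    wrap across midnight (24-h periodicity). Constant inputs have undefined
    correlation and raise :class:`DataError`.
    """
    p = np.asarray(profile, dtype=float)
    r = np.asarray(reference, dtype=float)
    if p.shape != r.shape or p.ndim != 1:
        raise DataError("profile and reference must be equal-length vectors")
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(r))):
        raise DataError("profiles must be finite (fill missing minutes first)")
    pc = p - p.mean()
    rc = r - r.mean()
    pn = np.linalg.norm(pc)
    rn = np.linalg.norm(rc)
    if pn == 0.0 or rn == 0.0:
        raise DataError("constant profile: correlation undefined")
    best_s = 0
    best_corr = -np.inf
    # (|s|, s) ordering puts smaller |s| first and -s before +s
    for s in sorted(range(-max_shift, max_shift + 1), key=lambda v: (abs(v), v)):
        corr = float(np.dot(np.roll(pc, s), rc) / (pn * rn))
        if corr > best_corr:
            best_corr = corr
            best_s = s
    return ProfileShift(shift_minutes=best_s, peak_correlation=best_corr)
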