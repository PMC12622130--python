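"""Per-minute predictors for the wear/non-wear model.

Five predictors are derived from the raw stream:

* ``movement``  — accelerometer time-above-threshold count > 0,
* ``upright``   — orientation code 2 (device hanging as a pendant),
* ``face_down`` — orientation code 32,
* ``dark``      — photopic illuminance of 1 lux or less,
* ``tod_minutes`` — time of day as raw minutes since local midnight.

Face-up orientation (code 16) is deliberately not a predictor: any
non-face-down orientation can measure light and therefore counts as adherent
placement at night. Binary features can be re-binned to coarser epochs (5, 10,
20, 30 minutes) by majority vote for epoch-length comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._time import MINUTES_PER_DAY, time_of_day_minutes
from .errors import ConfigurationError, DataError
from .ingest import ORIENTATION_FACE_DOWN, ORIENTATION_UPRIGHT, RecordingStream

#: Predictor column order used throughout the classifier.
PREDICTORS = ("movement", "upright", "face_down", "dark", "tod_minutes")

ALLOWED_EPOCHS = (1, 5, 10, 20, 30)


@dataclass
class FeatureSeries:
    """Per-epoch binary predictors plus continuous time of day."""

    timestamps: pd.DatetimeIndex
    movement: np.ndarray
    upright: np.ndarray
    face_down: np.ndarray
    dark: np.ndarray
    tod_minutes: np.ndarray
    epoch_minutes: int = 1

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        for name in ("movement", "upright", "face_down", "dark"):
            arr = np.asarray(getattr(self, name), dtype=np.uint8)
            if not np.isin(arr, (0, 1)).all():
                raise DataError(f"{name} must be binary")
            setattr(self, name, arr)
        self.tod_minutes = np.asarray(self.tod_minutes, dtype=float)
        if np.any((self.tod_minutes < 0) | (self.tod_minutes >= MINUTES_PER_DAY)):
            raise DataError("tod_minutes outside [0, 1440)")
        if self.epoch_minutes not in ALLOWED_EPOCHS:
            raise ConfigurationError(
                f"epoch_minutes {self.epoch_minutes} not in {ALLOWED_EPOCHS}"
            )
        n = len(self.timestamps)
        for name in ("movement", "upright", "face_down", "dark", "tod_minutes"):
            if len(getattr(self, name)) != n:
                raise DataError(f"{name} length != {n}")

    def __len__(self) -> int:
        return len(self.timestamps)

    def subset(self, mask: np.ndarray) -> "FeatureSeries":
        mask = np.asarray(mask)
        return FeatureSeries(
            timestamps=self.timestamps[mask],
            movement=self.movement[mask],
            upright=self.upright[mask],
            face_down=self.face_down[mask],
            dark=self.dark[mask],
            tod_minutes=self.tod_minutes[mask],
            epoch_minutes=self.epoch_minutes,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.timestamps,
                "movement": self.movement,
                "upright": self.upright,
                "face_down": self.face_down,
                "dark": self.dark,
                "tod_minutes": self.tod_minutes,
            }
        )


def derive_features(
    stream: RecordingStream,
    dark_threshold_lux: float = 1.0,
    movement_threshold: int = 0,
) -> FeatureSeries:
    """Derive the five predictors, one row per stream minute.

    ``movement = tat > movement_threshold``; ``dark = photopic <=
    dark_threshold_lux`` (1 lux or less by default); ``upright`` and
    ``face_down`` test the orientation codes 2 and 32. Pure function of the
    stream.
    """
    return FeatureSeries(
        timestamps=stream.timestamps,
        movement=(stream.tat_count > movement_threshold).astype(np.uint8),
        upright=(stream.orientation_code == ORIENTATION_UPRIGHT).astype(np.uint8),
        face_down=(stream.orientation_code == ORIENTATION_FACE_DOWN).astype(np.uint8),
        dark=(stream.photopic_lux <= dark_threshold_lux).astype(np.uint8),
        tod_minutes=time_of_day_minutes(stream.timestamps),
        epoch_minutes=1,
    )


def rebin(features: FeatureSeries, epoch_minutes: int) -> FeatureSeries:
    """Aggregate 1-minute features into hour-aligned coarser epochs.

    Each binary becomes the majority vote within the epoch, with ties
    resolved to 1 (presence of signal); ``tod_minutes`` becomes the epoch
    midpoint. ``epoch_minutes`` must be one of 5, 10, 20, 30.
    """
    if epoch_minutes not in (5, 10, 20, 30):
        raise ConfigurationError(
            f"epoch_minutes must be one of (5, 10, 20, 30), got {epoch_minutes}"
        )
    if features.epoch_minutes != 1:
        raise ConfigurationError("rebin expects 1-minute input features")
    key = features.timestamps.floor(f"{epoch_minutes}min")
    df = features.to_frame().drop(columns="timestamp")
    df.index = key
    grouped = df.groupby(level=0, sort=True)
    means = grouped[["movement", "upright", "face_down", "dark"]].mean()
    binaries = (means >= 0.5).astype(np.uint8)  # mean == 0.5 tie -> 1
    epoch_starts = pd.DatetimeIndex(means.index)
    tod = np.mod(
        time_of_day_minutes(epoch_starts) + epoch_minutes / 2.0, MINUTES_PER_DAY
    )
    return FeatureSeries(
        timestamps=epoch_starts,
        movement=binaries["movement"].to_numpy(),
        upright=binaries["upright"].to_numpy(),
        face_down=binaries["face_down"].to_numpy(),
        dark=binaries["dark"].to_numpy(),
        tod_minutes=tod,
        epoch_minutes=epoch_minutes,
    )


def concat_features(parts: Sequence[FeatureSeries]) -> FeatureSeries:
    """Concatenate feature series with identical epoch length."""
    if not parts:
        raise DataError("no feature series to concatenate")
    epochs = {f.epoch_minutes for f in parts}
    if len(epochs) != 1:
        raise ConfigurationError(f"mixed epoch lengths {sorted(epochs)}")
    return FeatureSeries(
        timestamps=pd.DatetimeIndex(
            np.concatenate([f.timestamps.asi8 for f in parts])
        ),
        movement=np.concatenate([f.movement for f in parts]),
        upright=np.concatenate([f.upright for f in parts]),
        face_down=np.concatenate([f.face_down for f in parts]),
        dark=np.concatenate([f.dark for f in parts]),
        tod_minutes=np.concatenate([f.tod_minutes for f in parts]),
        epoch_minutes=parts[0].epoch_minutes,
    )
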