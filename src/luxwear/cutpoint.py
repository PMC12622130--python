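"""Indoor vs outdoor illuminance cut-points from labelled observations.

Each labelled environment observation (at least 5 minutes of recording) is
summarized by the geometric mean of its photopic and mEDI illuminance; the
geometric mean is the right central tendency for multiplicative lux data.
Zeros occur indoors, so the mean is computed as ``exp(mean(log(x + 1))) - 1``
(the +1 lux offset is at the device floor and removed after exponentiation).

The indoor/outdoor cut-point is the Youden-optimal threshold of an ROC with
OUTDOOR as the positive class, evaluated on the midpoints between adjacent
sorted observation values. Above-ground transport observations sit between
the two regimes and are excluded from fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError, DataError
from .evaluation import roc_curve
from .ingest import RecordingStream

INDOOR = "INDOOR"
OUTDOOR = "OUTDOOR"
TRANSPORT = "TRANSPORT"
ENV_LABELS = (INDOOR, OUTDOOR, TRANSPORT)

MIN_OBSERVATION_MINUTES = 5


@dataclass(frozen=True)
class EnvironmentObservation:
    """A labelled >=5-minute segment summarized by geometric means."""

    label: str
    duration_minutes: float
    gm_photopic: float
    gm_medi: float

    def __post_init__(self) -> None:
        if self.label not in ENV_LABELS:
            raise DataError(f"unknown environment label '{self.label}'")
        if self.duration_minutes < MIN_OBSERVATION_MINUTES:
            raise DataError(
                f"observation shorter than {MIN_OBSERVATION_MINUTES} minutes"
            )
        if not (np.isfinite(self.gm_photopic) and np.isfinite(self.gm_medi)):
            raise DataError("non-finite geometric mean")


@dataclass(frozen=True)
class CutpointResult:
    channel: str
    threshold_lux: float
    auc: float
    sensitivity: float
    specificity: float
    j: float
    n_indoor: int
    n_outdoor: int
    n_excluded_transport: int


def geometric_mean(values, offset: float = 1.0) -> float:
    """Offset geometric mean exp(mean(log(x + offset))) - offset.

    Finite for any non-negative input, equals the plain geometric mean when
    offset = 0, and never exceeds the arithmetic mean.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise DataError("geometric_mean of empty input")
    if np.any(v < 0) or not np.all(np.isfinite(v)):
        raise DataError("geometric_mean requires finite non-negative values")
    return float(np.exp(np.mean(np.log(v + offset))) - offset)


def summarize_observation(
    segment: RecordingStream, label: str, offset: float = 1.0
) -> EnvironmentObservation:
    """Summarize a recording slice as one environment observation."""
    if len(segment) < MIN_OBSERVATION_MINUTES:
        raise DataError(
            f"segment has {len(segment)} minutes; need >= {MIN_OBSERVATION_MINUTES}"
        )
    return EnvironmentObservation(
        label=label,
        duration_minutes=float(len(segment)),
        gm_photopic=geometric_mean(segment.photopic_lux, offset),
        gm_medi=geometric_mean(segment.medi_lux, offset),
    )


def _channel_values(obs: Sequence[EnvironmentObservation], channel: str):
    if channel == "photopic":
        return np.array([o.gm_photopic for o in obs], dtype=float)
    if channel == "medi":
        return np.array([o.gm_medi for o in obs], dtype=float)
    raise ConfigurationError(f"channel must be 'photopic' or 'medi', got '{channel}'")


def optimal_cutpoint(
    observations: Iterable[EnvironmentObservation], channel: str = "photopic"
) -> CutpointResult:
    """Youden-optimal indoor/outdoor threshold on observation geometric means.

    TRANSPORT observations are excluded automatically. A minute/observation
    above the returned threshold reads as OUTDOOR (strict >). Candidate
    thresholds are the midpoints between adjacent sorted distinct values;
    ties in J go to the higher (more outdoor-specific) threshold.
    """
    observations = list(observations)
    n_transport = sum(1 for o in observations if o.label == TRANSPORT)
    kept = [o for o in observations if o.label != TRANSPORT]
    y = np.array([o.label == OUTDOOR for o in kept], dtype=bool)
    if y.sum() == 0 or (~y).sum() == 0:
        raise DataError("need at least one INDOOR and one OUTDOOR observation")
    values = _channel_values(kept, channel)
    auc = roc_curve(values, y.astype(int)).auc

    uniq = np.unique(values)
    if uniq.size < 2:
        raise DataError("all observations identical: no cut-point exists")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    best = None
    for t in candidates[::-1]:  # descending: first strict max = higher threshold
        sens = float(np.mean(values[y] > t))
        spec = float(np.mean(values[~y] <= t))
        j = sens + spec - 1.0
        if best is None or j > best[0]:
            best = (j, t, sens, spec)
    j, t, sens, spec = best
    return CutpointResult(
        channel=channel,
        threshold_lux=float(t),
        auc=float(auc),
        sensitivity=sens,
        specificity=spec,
        j=float(j),
        n_indoor=int((~y).sum()),
        n_outdoor=int(y.sum()),
        n_excluded_transport=n_transport,
    )


def apply_cutpoint(
    stream: RecordingStream, threshold_lux: float, channel: str = "photopic"
) -> np.ndarray:
    """Per-minute INDOOR/OUTDOOR labels: OUTDOOR iff value > threshold."""
    if threshold_lux <= 0:
        raise ConfigurationError("threshold_lux must be > 0")
    if channel == "photopic":
        values = stream.photopic_lux
    elif channel == "medi":
        values = stream.medi_lux
    else:
        raise ConfigurationError(f"unknown channel '{channel}'")
    return np.where(values > threshold_lux, OUTDOOR, INDOOR).astype("U9")
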