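"""Seeded simulator for labelled light-logger recordings.

The generator emulates the tester protocol used to build and validate the
wear model: a daily episode schedule drawn from the nine wear/non-wear
conditions, minute-resolution sampling, the 0-100,000 lux operating range,
and lognormal indoor/outdoor illuminance regimes centered on geometric means
of 202 lux (indoor) and 10,241 lux (outdoor). Each condition imposes a
sensor signature:

==========================  ===========  ==========  ==================
condition                   orientation  movement    photopic lux
==========================  ===========  ==========  ==================
WEAR_ACTIVE                 2            Bern(0.9)   indoor regime
WEAR_SEDENTARY              2            Bern(0.15)  indoor regime
WEAR_INDOOR                 2            Bern(0.5)   indoor regime
WEAR_OUTDOOR                2            Bern(0.6)   outdoor regime
NIGHT_FACE_UP               16           0           dim ambient
NIGHT_FACE_DOWN             32           0           <= 1 lux
NONWEAR_STATIONARY_LIGHT    16           0           indoor regime
NONWEAR_STATIONARY_DARK     16 or 32     0           <= 1 lux
NONWEAR_MOBILE_DARK         random       > 0         <= 1 lux
==========================  ===========  ==========  ==================

Illuminance is drawn hierarchically: an episode-level lognormal level
(between-episode log-SD) modulated by minute noise (within log-SD), then
clipped to the device range. mEDI is a per-environment multiplicative
fraction of photopic illuminance with small lognormal jitter. A single
``overlap`` dial corrupts a fraction of minutes with a signature drawn from
a different condition, degrading class separability for robustness studies.

All randomness flows from one generator seeded once per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


import numpy as np
import pandas as pd

from .cutpoint import EnvironmentObservation, INDOOR, OUTDOOR, TRANSPORT, geometric_mean
from .errors import ConfigurationError
from .ingest import (
    Condition,
    DiaryInterval,
    LUX_MAX,
    ORIENTATION_FACE_DOWN,
    ORIENTATION_FACE_UP,
    ORIENTATION_UPRIGHT,
    RecordingStream,
)

MINUTES_PER_DAY = 1440

#: Daily tester schedule exercising all nine conditions (the 00:00-06:00
#: night slot is flipped to NIGHT_FACE_DOWN on ``face_down_nights`` days).
TESTER_SCHEDULE: tuple = (
    (0, 360, Condition.NIGHT_FACE_UP),
    (360, 420, Condition.NONWEAR_STATIONARY_DARK),
    (420, 540, Condition.WEAR_INDOOR),
    (540, 600, Condition.WEAR_ACTIVE),
    (600, 720, Condition.WEAR_OUTDOOR),
    (720, 840, Condition.WEAR_SEDENTARY),
    (840, 900, Condition.NONWEAR_MOBILE_DARK),
    (900, 1080, Condition.WEAR_INDOOR),
    (1080, 1140, Condition.NONWEAR_STATIONARY_LIGHT),
    (1140, 1440, Condition.WEAR_INDOOR),
)

#: A mostly-adherent free-living week: worn through the day with short
#: off-body episodes (morning routine, exercise shower, bedtime), device on
#: the nightstand overnight.
PARTICIPANT_SCHEDULE: tuple = (
    (0, 360, Condition.NIGHT_FACE_UP),
    (360, 390, Condition.NONWEAR_STATIONARY_LIGHT),
    (390, 600, Condition.WEAR_INDOOR),
    (600, 660, Condition.WEAR_OUTDOOR),
    (660, 1020, Condition.WEAR_INDOOR),
    (1020, 1080, Condition.WEAR_ACTIVE),
    (1080, 1110, Condition.NONWEAR_STATIONARY_LIGHT),
    (1110, 1380, Condition.WEAR_SEDENTARY),
    (1380, 1440, Condition.NONWEAR_STATIONARY_LIGHT),
)


@dataclass(frozen=True)
class EnvModel:
    """Lognormal illuminance regime: geometric mean and log-SDs (natural log).

    ``between_log_sd`` spreads episode/observation levels; ``within_log_sd``
    is minute-to-minute noise around the episode level. The overall
    geometric mean stays at ``gm_lux``.
    """

    gm_lux: float
    between_log_sd: float = 1.0
    within_log_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.gm_lux <= 0:
            raise ConfigurationError("gm_lux must be > 0")
        if self.between_log_sd < 0 or self.within_log_sd < 0:
            raise ConfigurationError("log-SDs must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    days: int = 7
    start: str = "2025-01-06"
    participant_id: str = "SIM"
    schedule: tuple = TESTER_SCHEDULE
    #: day indices whose night slot becomes NIGHT_FACE_DOWN (non-adherent).
    face_down_nights: frozenset = frozenset({1, 4})
    indoor: EnvModel = field(default_factory=lambda: EnvModel(202.0))
    outdoor: EnvModel = field(default_factory=lambda: EnvModel(10_241.0))
    dim: EnvModel = field(default_factory=lambda: EnvModel(0.3, 0.8, 0.3))
    medi_ratio_indoor: float = 0.8
    medi_ratio_outdoor: float = 0.9
    medi_log_jitter: float = 0.05
    p_move_active: float = 0.9
    p_move_sedentary: float = 0.15
    p_move_wear: float = 0.5
    p_move_outdoor: float = 0.6
    #: minutes between fresh draws of the episode illuminance level.
    env_redraw_minutes: int = 30
    #: per-minute probability of replacing the sensor signature with one
    #: drawn from a different condition (0 = fully separable signatures).
    overlap: float = 0.0

    def __post_init__(self) -> None:
        if self.days < 1:
            raise ConfigurationError("days must be >= 1")
        for name in ("medi_ratio_indoor", "medi_ratio_outdoor"):
            if not 0 < getattr(self, name) <= 1:
                raise ConfigurationError(f"{name} must be in (0, 1]")
        for name in (
            "p_move_active", "p_move_sedentary", "p_move_wear",
            "p_move_outdoor", "overlap",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.env_redraw_minutes < 1:
            raise ConfigurationError("env_redraw_minutes must be >= 1")
        _validate_schedule(self.schedule)


def _validate_schedule(schedule) -> None:
    entries = sorted(schedule, key=lambda e: e[0])
    for start, end, cond in entries:
        if not (0 <= start < end <= MINUTES_PER_DAY):
            raise ConfigurationError(f"bad schedule window ({start}, {end})")
        Condition(cond)
    for (s0, e0, c0), (s1, e1, c1) in zip(entries, entries[1:]):
        if s1 < e0:
            raise ConfigurationError(
                f"overlapping schedule windows ({s0},{e0},{c0}) and "
                f"({s1},{e1},{c1})"
            )


_WEAR_MOVE = {
    Condition.WEAR_ACTIVE: "p_move_active",
    Condition.WEAR_SEDENTARY: "p_move_sedentary",
    Condition.WEAR_INDOOR: "p_move_wear",
    Condition.WEAR_OUTDOOR: "p_move_outdoor",
}

_ENV_OF = {
    Condition.WEAR_ACTIVE: "indoor",
    Condition.WEAR_SEDENTARY: "indoor",
    Condition.WEAR_INDOOR: "indoor",
    Condition.WEAR_OUTDOOR: "outdoor",
    Condition.NONWEAR_STATIONARY_LIGHT: "indoor",
    Condition.NIGHT_FACE_UP: "dim",
    Condition.NIGHT_FACE_DOWN: "dark",
    Condition.NONWEAR_STATIONARY_DARK: "dark",
    Condition.NONWEAR_MOBILE_DARK: "dark",
}

_OTHER_ORIENTATIONS = np.array([ORIENTATION_UPRIGHT, 4, 8, ORIENTATION_FACE_UP,
                                ORIENTATION_FACE_DOWN])


def _env_lux(model: EnvModel, n: int, rng, redraw: int) -> np.ndarray:
    """Hierarchical lognormal minutes: episode level redrawn every ``redraw``."""
    n_levels = int(np.ceil(n / redraw))
    mu = np.log(model.gm_lux) + rng.normal(0.0, model.between_log_sd, n_levels)
    level = np.repeat(mu, redraw)[:n]
    lux = np.exp(level + rng.normal(0.0, model.within_log_sd, n))
    return np.clip(lux, 0.0, LUX_MAX)


def _episode_sensors(cond: Condition, n: int, rng, cfg: SimulationConfig):
    """(lux, tat, orientation) arrays for one contiguous episode."""
    env = _ENV_OF[cond]
    if env == "dark":
        lux = rng.uniform(0.0, 1.0, n)
    else:
        lux = _env_lux(getattr(cfg, env), n, rng, cfg.env_redraw_minutes)

    if cond in _WEAR_MOVE:
        p = getattr(cfg, _WEAR_MOVE[cond])
        moving = rng.random(n) < p
        tat = np.where(moving, 1 + rng.poisson(2.0, n), 0)
        orientation = np.full(n, ORIENTATION_UPRIGHT)
    elif cond is Condition.NONWEAR_MOBILE_DARK:
        tat = 1 + rng.poisson(2.0, n)  # always moving
        orientation = rng.choice(_OTHER_ORIENTATIONS, n)
    else:
        tat = np.zeros(n, dtype=np.int64)
        if cond is Condition.NIGHT_FACE_UP:
            orientation = np.full(n, ORIENTATION_FACE_UP)
        elif cond is Condition.NIGHT_FACE_DOWN:
            orientation = np.full(n, ORIENTATION_FACE_DOWN)
        elif cond is Condition.NONWEAR_STATIONARY_LIGHT:
            orientation = np.full(n, ORIENTATION_FACE_UP)
        else:  # NONWEAR_STATIONARY_DARK: one resting pose per episode
            pose = rng.choice([ORIENTATION_FACE_UP, ORIENTATION_FACE_DOWN])
            orientation = np.full(n, pose)
    return lux, tat, orientation


def _medi_from_lux(lux, env: str, rng, cfg: SimulationConfig) -> np.ndarray:
    ratio = cfg.medi_ratio_outdoor if env == "outdoor" else cfg.medi_ratio_indoor
    medi = lux * ratio * np.exp(rng.normal(0.0, cfg.medi_log_jitter, len(lux)))
    return np.clip(medi, 0.0, LUX_MAX)


def simulate_recording(
    config: SimulationConfig | None = None,
) -> tuple[RecordingStream, list[DiaryInterval]]:
    """Generate a labelled recording under the configured episode schedule.

    Returns the minute stream plus the ground-truth diary (one interval per
    contiguous episode). Scheduled gaps in the daily template, if any, are
    simulated as sedentary indoor wear but left out of the diary, so they
    label as UNKNOWN downstream. Deterministic for a fixed seed.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    start = pd.Timestamp(cfg.start)
    n_total = cfg.days * MINUTES_PER_DAY
    timestamps = start + pd.to_timedelta(np.arange(n_total), unit="min")

    # per-minute condition (None outside the schedule)
    conditions = np.full(n_total, None, dtype=object)
    in_diary = np.zeros(n_total, dtype=bool)
    for day in range(cfg.days):
        base = day * MINUTES_PER_DAY
        for s, e, cond in cfg.schedule:
            cond = Condition(cond)
            if cond is Condition.NIGHT_FACE_UP and day in cfg.face_down_nights:
                cond = Condition.NIGHT_FACE_DOWN
            conditions[base + s: base + e] = cond
            in_diary[base + s: base + e] = True
    unscheduled = conditions == None  # noqa: E711 - elementwise object compare
    conditions[unscheduled] = Condition.WEAR_SEDENTARY

    lux = np.empty(n_total)
    tat = np.empty(n_total, dtype=np.int64)
    orientation = np.empty(n_total, dtype=np.int64)
    medi = np.empty(n_total)

    # iterate contiguous runs of the same condition
    change = np.r_[True, conditions[1:] != conditions[:-1]]
    starts = np.flatnonzero(change)
    ends = np.r_[starts[1:], n_total]
    for i0, i1 in zip(starts, ends):
        cond = conditions[i0]
        ep_lux, ep_tat, ep_orient = _episode_sensors(cond, i1 - i0, rng, cfg)
        lux[i0:i1] = ep_lux
        tat[i0:i1] = ep_tat
        orientation[i0:i1] = ep_orient
        medi[i0:i1] = _medi_from_lux(ep_lux, _ENV_OF[cond], rng, cfg)

    if cfg.overlap > 0.0:
        corrupt = np.flatnonzero(rng.random(n_total) < cfg.overlap)
        all_conditions = list(Condition)
        for i in corrupt:
            others = [c for c in all_conditions if c is not conditions[i]]
            alt = others[int(rng.integers(len(others)))]
            l1, t1, o1 = _episode_sensors(alt, 1, rng, cfg)
            lux[i], tat[i], orientation[i] = l1[0], t1[0], o1[0]
            medi[i] = _medi_from_lux(l1, _ENV_OF[alt], rng, cfg)[0]

    stream = RecordingStream(
        participant_id=cfg.participant_id,
        timestamps=pd.DatetimeIndex(timestamps),
        photopic_lux=lux,
        medi_lux=medi,
        tat_count=tat,
        orientation_code=orientation,
    )

    diary: list[DiaryInterval] = []
    for i0, i1 in zip(starts, ends):
        if not in_diary[i0]:
            continue
        diary.append(
            DiaryInterval(
                start=timestamps[i0],
                end=timestamps[i1 - 1] + pd.Timedelta(minutes=1),
                condition=conditions[i0],
            )
        )
    return stream, diary


def simulate_environment_observations(
    config: SimulationConfig | None = None,
    n_indoor: int = 45,
    n_outdoor: int = 21,
    n_transport: int = 0,
    seed: int | None = None,
) -> list[EnvironmentObservation]:
    """Simulate labelled >=5-minute environment observations.

    Defaults mirror the observation-count pattern of the cut-point study
    (45 indoor, 21 outdoor). Transport observations draw from the outdoor
    regime, consistent with above-ground transport reading like outdoor
    light. Each observation lasts 5-30 minutes.
    """
    cfg = config or SimulationConfig()
    if min(n_indoor, n_outdoor, n_transport) < 0:
        raise ConfigurationError("observation counts must be >= 0")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    jobs = (
        [(INDOOR, cfg.indoor)] * n_indoor
        + [(OUTDOOR, cfg.outdoor)] * n_outdoor
        + [(TRANSPORT, cfg.outdoor)] * n_transport
    )
    out = []
    for label, model in jobs:
        n = int(rng.integers(MIN_OBS_MINUTES, 31))
        mu = np.log(model.gm_lux) + rng.normal(0.0, model.between_log_sd)
        lux = np.clip(
            np.exp(mu + rng.normal(0.0, model.within_log_sd, n)), 0.0, LUX_MAX
        )
        env = "outdoor" if label != INDOOR else "indoor"
        medi = _medi_from_lux(lux, env, rng, cfg)
        out.append(
            EnvironmentObservation(
                label=label,
                duration_minutes=float(n),
                gm_photopic=geometric_mean(lux),
                gm_medi=geometric_mean(medi),
            )
        )
    return out


MIN_OBS_MINUTES = 5


def sample_environment_minutes(
    model: EnvModel, n: int, rng, episode_minutes: int = 5
) -> np.ndarray:
    """Minute illuminance from an environment regime, episode level redrawn
    every ``episode_minutes`` (for large-sample geometric-mean checks)."""
    return _env_lux(model, n, rng, episode_minutes)


def perturbed_configs(
    base: SimulationConfig, n: int, seed: int | None = None
) -> list[SimulationConfig]:
    """Configs for ``n`` testers: distinct seeds, mildly perturbed rates.

    Movement probabilities and environment geometric means are jittered by
    +/-10% so validation testers differ from the training tester without
    changing the condition grammar.
    """
    rng = np.random.default_rng(base.seed if seed is None else seed)
    out = []
    for i in range(n):
        u = lambda: float(rng.uniform(0.9, 1.1))  # noqa: E731
        cfg = replace(
            base,
            seed=int(rng.integers(0, 2**31 - 1)),
            participant_id=f"{base.participant_id}-T{i + 1}",
            indoor=replace(base.indoor, gm_lux=base.indoor.gm_lux * u()),
            outdoor=replace(base.outdoor, gm_lux=base.outdoor.gm_lux * u()),
            p_move_active=min(1.0, base.p_move_active * u()),
            p_move_sedentary=min(1.0, base.p_move_sedentary * u()),
            p_move_wear=min(1.0, base.p_move_wear * u()),
            p_move_outdoor=min(1.0, base.p_move_outdoor * u()),
        )
        out.append(cfg)
    return out


def participant_config(
    seed: int,
    days: int = 7,
    participant_id: str = "P",
    face_down_nights: frozenset = frozenset({2, 5}),
) -> SimulationConfig:
    """Free-living participant preset: mostly adherent days, two face-down
    nights per week."""
    return SimulationConfig(
        seed=seed,
        days=days,
        participant_id=participant_id,
        schedule=PARTICIPANT_SCHEDULE,
        face_down_nights=face_down_nights,
    )
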