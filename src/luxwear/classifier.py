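"""Three-outcome wear / non-wear / night-placement classifier.

The model is three one-vs-rest binary logistic regressions over the five
predictors (movement, upright, face-down, dark, time of day), one per outcome
class, fitted by iteratively reweighted least squares. Per-class scores are
required because model quality is reported as per-class AUC / sensitivity /
specificity; a single label is recovered by argmax of the threshold-shifted
probabilities, with each class threshold set at the Youden-optimal point of
its training ROC.

Complete or quasi-separation (common on cleanly simulated data, where e.g.
the upright orientation identifies wear exactly) is detected and handled by
refitting with a small ridge penalty (1e-6 on slopes, never the intercept);
the affected class is flagged in the model metadata.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field


import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigurationError, DataError
from .evaluation import roc_curve, youden_optimal
from .features import FeatureSeries
from .ingest import LabeledStream, WearClass

#: Outcome classes, in reporting order.
CLASSES = (WearClass.WEAR.value, WearClass.NONWEAR.value, WearClass.NIGHT_OK.value)

#: Tie-break priority for classify(): prefer the rarer, time-gated class.
CLASS_PRIORITY = (WearClass.NIGHT_OK.value, WearClass.WEAR.value, WearClass.NONWEAR.value)

_SEPARATION_RIDGE = 1e-6
#: |linear predictor| beyond which fitted probabilities are numerically 0/1.
_SATURATION_ETA = 30.0


@dataclass(frozen=True)
class SplitPlan:
    """Train/validation split by whole contiguous day blocks."""

    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError("train_fraction must be in (0, 1)")


@dataclass(frozen=True)
class FitConfig:
    epoch_minutes: int = 1
    seed: int = 0
    tod_encoding: str = "linear"  # or "cyclic" (sine/cosine), opt-in
    tol: float = 1e-8
    max_iter: int = 100

    def __post_init__(self) -> None:
        if self.tod_encoding not in ("linear", "cyclic"):
            raise ConfigurationError("tod_encoding must be 'linear' or 'cyclic'")


@dataclass
class IRLSResult:
    beta: np.ndarray
    converged: bool
    n_iter: int
    separation: bool = False


@dataclass
class WearModel:
    """Fitted one-vs-rest logistic model with per-class decision thresholds."""

    feature_names: tuple
    coefficients: dict  # class -> np.ndarray over feature_names
    thresholds: dict  # class -> probability threshold in (0, 1)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arities = {len(v) for v in self.coefficients.values()}
        if arities != {len(self.feature_names)}:
            raise ConfigurationError("coefficient arity mismatch")
        for c, t in self.thresholds.items():
            if not 0.0 < t < 1.0:
                raise ConfigurationError(f"threshold for {c} outside (0, 1)")

    def to_json(self) -> str:
        return json.dumps(
            {
                "classes": list(self.coefficients),
                "feature_names": list(self.feature_names),
                "coefficients": {
                    c: [float(v) for v in b] for c, b in self.coefficients.items()
                },
                "thresholds": {c: float(t) for c, t in self.thresholds.items()},
                "metadata": self.metadata,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "WearModel":
        doc = json.loads(text)
        return cls(
            feature_names=tuple(doc["feature_names"]),
            coefficients={c: np.asarray(b, dtype=float)
                          for c, b in doc["coefficients"].items()},
            thresholds=dict(doc["thresholds"]),
            metadata=doc.get("metadata", {}),
        )


def design_matrix(
    features: FeatureSeries, tod_encoding: str = "linear"
) -> tuple[np.ndarray, tuple]:
    """Design matrix with intercept; tod enters raw or as sine/cosine pair."""
    cols = [
        np.ones(len(features)),
        features.movement.astype(float),
        features.upright.astype(float),
        features.face_down.astype(float),
        features.dark.astype(float),
    ]
    names = ["intercept", "movement", "upright", "face_down", "dark"]
    if tod_encoding == "linear":
        cols.append(features.tod_minutes)
        names.append("tod_minutes")
    elif tod_encoding == "cyclic":
        phase = 2.0 * np.pi * features.tod_minutes / 1440.0
        cols.extend([np.sin(phase), np.cos(phase)])
        names.extend(["tod_sin", "tod_cos"])
    else:
        raise ConfigurationError(f"unknown tod_encoding '{tod_encoding}'")
    return np.column_stack(cols), tuple(names)


def log_likelihood(
    X: np.ndarray, y: np.ndarray, beta: np.ndarray, ridge: float = 0.0
) -> float:
    """Bernoulli log-likelihood (ridge-penalized on slopes if requested)."""
    eta = X @ beta
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    if ridge:
        ll -= 0.5 * ridge * float(np.sum(beta[1:] ** 2))
    return ll


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = 0.0,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> IRLSResult:
    """Maximum-likelihood logistic fit by IRLS (Newton) with step halving.

    Converged when the sup-norm of the (penalized) score drops below ``tol``.
    The ridge penalty, when non-zero, applies to slopes only (column 0 is the
    intercept).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    R = np.zeros(p)
    R[1:] = ridge
    beta = np.zeros(p)
    ll = log_likelihood(X, y, beta, ridge)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(X @ beta)
        g = X.T @ (y - mu) - R * beta
        if np.max(np.abs(g)) < tol:
            converged = True
            break
        W = mu * (1.0 - mu)
        H = (X * W[:, None]).T @ X + np.diag(R)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        new_beta = beta + step
        new_ll = log_likelihood(X, y, new_beta, ridge)
        halvings = 0
        while not np.isfinite(new_ll) or new_ll < ll - 1e-12:
            step *= 0.5
            new_beta = beta + step
            new_ll = log_likelihood(X, y, new_beta, ridge)
            halvings += 1
            if halvings > 40:
                break
        beta = new_beta
        ll = new_ll
    else:
        mu = expit(X @ beta)
        g = X.T @ (y - mu) - R * beta
        converged = bool(np.max(np.abs(g)) < tol)
    return IRLSResult(beta=beta, converged=converged, n_iter=it)


def _fit_one_class(X, y, config: FitConfig) -> IRLSResult:
    res = fit_logistic(X, y, ridge=0.0, tol=config.tol, max_iter=config.max_iter)
    eta = X @ res.beta
    if not res.converged or np.max(np.abs(eta)) > _SATURATION_ETA:
        res = fit_logistic(
            X, y, ridge=_SEPARATION_RIDGE, tol=config.tol, max_iter=config.max_iter
        )
        res.separation = True
    return res


def _train_hash(X: np.ndarray, labels: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.asarray(labels, dtype="U8").tobytes())
    return h.hexdigest()[:16]


def fit(
    features: FeatureSeries,
    labels: np.ndarray,
    config: FitConfig | None = None,
) -> WearModel:
    """Fit the three one-vs-rest logistic models and their decision thresholds.

    UNKNOWN rows are excluded. At least two outcome classes must be present;
    a class absent from training receives a large negative intercept and a
    flag instead of a fit. Each class threshold is the Youden-optimal point
    of its training ROC.
    """
    config = config or FitConfig()
    labels = np.asarray(labels, dtype="U8")
    if len(labels) != len(features):
        raise DataError("labels length differs from features length")
    keep = labels != WearClass.UNKNOWN.value
    feats = features.subset(keep)
    labels = labels[keep]
    present = set(np.unique(labels))
    if len(present & set(CLASSES)) < 2:
        raise DataError("fit requires at least 2 outcome classes present")

    X, names = design_matrix(feats, config.tod_encoding)
    coefficients: dict[str, np.ndarray] = {}
    thresholds: dict[str, float] = {}
    eta_thresholds: dict[str, float] = {}
    separation_flags: dict[str, bool] = {}
    absent: list[str] = []
    for cls in CLASSES:
        y = (labels == cls).astype(float)
        if cls not in present:
            beta = np.zeros(len(names))
            beta[0] = -20.0  # probability ~ 0 everywhere
            coefficients[cls] = beta
            thresholds[cls] = 0.5
            eta_thresholds[cls] = 0.0
            separation_flags[cls] = False
            absent.append(cls)
            continue
        res = _fit_one_class(X, y, config)
        if res.separation:
            warnings.warn(
                f"complete/quasi-separation for class {cls}; "
                f"refit with ridge {_SEPARATION_RIDGE} on slopes",
                stacklevel=2,
            )
        coefficients[cls] = res.beta
        separation_flags[cls] = res.separation
        # Youden on the log-odds scale (rank-identical, saturation-free);
        # the exact log-odds cut is kept alongside the probability threshold
        # because expit() collapses extreme cuts to exactly 0/1.
        eta = X @ res.beta
        eta_thr = youden_optimal(roc_curve(eta, y.astype(int))).threshold
        eta_thresholds[cls] = float(eta_thr)
        thresholds[cls] = float(np.clip(expit(eta_thr), 1e-9, 1.0 - 1e-9))

    metadata = {
        "epoch_minutes": config.epoch_minutes,
        "seed": config.seed,
        "tod_encoding": config.tod_encoding,
        "train_hash": _train_hash(X, labels),
        "n_train": int(len(labels)),
        "separation": separation_flags,
        "absent_classes": absent,
        "eta_thresholds": eta_thresholds,
    }
    return WearModel(
        feature_names=names,
        coefficients=coefficients,
        thresholds=thresholds,
        metadata=metadata,
    )


def decision_scores(model: WearModel, features: FeatureSeries) -> pd.DataFrame:
    """Per-epoch one-vs-rest linear predictors (log-odds), one column per class.

    Monotone in the class probability but free of the floating-point
    saturation that collapses extreme probabilities to exactly 0/1, so this
    is the right scale for ranking-based evaluation (ROC/AUC) of strongly
    separated fits.
    """
    X, names = design_matrix(
        features, model.metadata.get("tod_encoding", "linear")
    )
    if names != tuple(model.feature_names):
        raise ConfigurationError(
            f"feature arity mismatch: model {model.feature_names}, data {names}"
        )
    out = {}
    for cls, beta in model.coefficients.items():
        out[cls] = X @ np.asarray(beta, dtype=float)
    return pd.DataFrame(out, index=features.timestamps)


def predict_proba(model: WearModel, features: FeatureSeries) -> pd.DataFrame:
    """Per-epoch one-vs-rest probabilities, one column per class.

    The three scores are independent one-vs-rest probabilities and need not
    sum to 1.
    """
    scores = decision_scores(model, features)
    return scores.apply(expit)


def classify(model: WearModel, features: FeatureSeries) -> np.ndarray:
    """Single label per epoch: argmax of (probability - class threshold).

    The margin is evaluated on the log-odds scale, as
    ``expit(eta - eta_threshold) - 0.5`` (same sign as probability minus
    threshold but immune to expit() rounding extreme log-odds to exactly
    0/1, which would erase strongly separated training cuts). Exact ties are
    broken by the fixed priority NIGHT_OK > WEAR > NONWEAR.
    """
    scores = decision_scores(model, features)
    eta_thr = model.metadata.get("eta_thresholds")
    order = [c for c in CLASS_PRIORITY if c in scores.columns]
    margins = np.column_stack([
        expit(
            scores[c].to_numpy()
            - (eta_thr[c] if eta_thr else _logit(model.thresholds[c]))
        ) - 0.5
        for c in order
    ])
    idx = np.argmax(margins, axis=1)  # first max wins -> priority order
    return np.asarray(order, dtype="U8")[idx]


def _logit(p: float) -> float:
    return float(np.log(p) - np.log1p(-p))


def _day_blocks(data: LabeledStream) -> pd.DatetimeIndex:
    return pd.DatetimeIndex(data.timestamps.normalize().unique())


def split_train_validate(
    data: LabeledStream, plan: SplitPlan | None = None
) -> tuple[LabeledStream, LabeledStream]:
    """Disjoint train/validation partition by whole calendar days.

    Days (not minutes) are sampled without replacement so that temporally
    adjacent minutes never straddle the split; the train share is within one
    day of ``plan.train_fraction``. Deterministic under a fixed seed.
    """
    plan = plan or SplitPlan()
    days = _day_blocks(data)
    if len(days) < 2:
        raise DataError("split requires at least 2 day blocks")
    n_train = int(round(plan.train_fraction * len(days)))
    n_train = min(max(n_train, 1), len(days) - 1)
    rng = np.random.default_rng(plan.seed)
    perm = rng.permutation(len(days))
    train_days = set(days[perm[:n_train]])
    norm = data.timestamps.normalize()
    train_mask = np.asarray(norm.isin(train_days))
    return data.subset(train_mask), data.subset(~train_mask)
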