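"""ROC analysis, Youden-optimal thresholds and percentile bootstrap CIs.

The ROC is built over all distinct score values (predicted positive when
``score >= threshold``) plus a ``+inf`` sentinel where nothing is positive.
AUC is the trapezoidal rule accumulated on the integer (FP, TP) lattice and
divided once by ``2 * n_pos * n_neg``, which makes it identical — bit for bit
— to the Mann-Whitney pair count with half credit for tied pairs.

Discrimination bands follow the usual epidemiological reading: AUC in
[0.8, 0.9) is good, 0.9 and above excellent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigurationError, DataError


@dataclass
class ROCResult:
    """ROC over distinct thresholds (descending, ``+inf`` sentinel first).

    ``tp``/``fp`` keep the integer counts behind sensitivity/specificity so
    downstream selections (Youden) can compare operating points exactly.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    tp: np.ndarray | None = None
    fp: np.ndarray | None = None


@dataclass(frozen=True)
class YoudenPoint:
    threshold: float
    sensitivity: float
    specificity: float
    j: float


def roc_curve(scores, labels) -> ROCResult:
    """ROC curve and trapezoidal AUC for binary ``labels`` (1 = positive)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise DataError("scores and labels must be equal-length 1-d arrays")
    y = labels.astype(bool)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DataError("roc_curve requires both classes present")

    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    yy = y[order].astype(np.int64)
    # last index of each tie group of equal scores
    last = np.r_[s[1:] != s[:-1], True]
    tp = np.cumsum(yy)[last]
    fp = np.cumsum(1 - yy)[last]
    thresholds = np.r_[np.inf, s[last]]
    tp = np.r_[0, tp]
    fp = np.r_[0, fp]
    # integer trapezoid: sum of dFP * (TP_i + TP_{i-1}) over steps
    num = np.sum((fp[1:] - fp[:-1]) * (tp[1:] + tp[:-1]))
    auc = float(num) / (2.0 * n_pos * n_neg)
    return ROCResult(
        thresholds=thresholds,
        sensitivity=tp / n_pos,
        specificity=1.0 - fp / n_neg,
        auc=auc,
        n_pos=n_pos,
        n_neg=n_neg,
        tp=tp,
        fp=fp,
    )


def discrimination_band(auc: float) -> str:
    """Classify an AUC as poor (<0.8), good ([0.8, 0.9)) or excellent (>=0.9)."""
    if auc >= 0.9:
        return "excellent"
    if auc >= 0.8:
        return "good"
    return "poor"


def youden_optimal(roc: ROCResult) -> YoudenPoint:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Ties are broken toward the higher (more specific) threshold. The ``+inf``
    sentinel (classify everything negative) is never returned.
    """
    if roc.tp is not None and roc.fp is not None:
        # exact integer comparison: J = (tp*n_neg - fp*n_pos) / (n_pos*n_neg)
        j_num = roc.tp * roc.n_neg - roc.fp * roc.n_pos
        j = j_num / (roc.n_pos * roc.n_neg)
    else:
        j = roc.sensitivity + roc.specificity - 1.0
        j_num = j
    # skip sentinel at index 0; thresholds descend, so argmax takes the
    # highest threshold among ties
    k = 1 + int(np.argmax(j_num[1:]))
    return YoudenPoint(
        threshold=float(roc.thresholds[k]),
        sensitivity=float(roc.sensitivity[k]),
        specificity=float(roc.specificity[k]),
        j=float(j[k]),
    )


def bootstrap_ci(
    statistic: Callable,
    data: Sequence[float] | np.ndarray,
    n_reps: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Seeded percentile bootstrap interval for ``statistic`` of ``data``.

    Resamples rows with replacement ``n_reps`` times and returns the central
    ``level`` percentile interval. ``statistic`` is called as
    ``statistic(resamples, axis=1)`` on an ``(n_reps, n)`` array when it
    supports an ``axis`` keyword (fast path), else per resample.
    """
    data = np.asarray(data, dtype=float)
    if data.size == 0:
        raise DataError("bootstrap_ci: empty data")
    if n_reps < 100:
        raise ConfigurationError("bootstrap_ci: n_reps must be >= 100")
    if not 0 < level < 1:
        raise ConfigurationError("bootstrap_ci: level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = data.shape[0]
    idx = rng.integers(0, n, size=(n_reps, n))
    try:
        stats = np.asarray(statistic(data[idx], axis=1), dtype=float)
        if stats.shape != (n_reps,):
            raise TypeError
    except TypeError:
        stats = np.array([statistic(data[row]) for row in idx], dtype=float)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
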