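"""Classification metrics for predictor benchmarking.

The central ranking statistic is the *coverage-weighted normalized MCC*:
the Matthews correlation coefficient computed over the variants a tool
actually scored, rescaled from [-1, 1] to [0, 1], and multiplied by the
tool's coverage (the fraction of presented variants it scored).  A tool is
therefore penalized both for wrong calls and for silence.

Missing scores never enter arithmetic: they are excluded from the confusion
matrix but counted in ``n_total``, so they depress coverage.  Ratio metrics
with a zero denominator carry an explicit undefined marker (NaN), never 0;
ranking code must order undefined below defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .registry import HIGHER, LOWER, STRICT_GREATER, STRICT_LESS

#: Marker for metrics whose defining ratio has a zero denominator.
UNDEFINED = math.nan


def is_defined(x: float) -> bool:
    return not math.isnan(x)


def mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient.

    Defined as 0 (chance level) when any marginal of the confusion matrix is
    zero, so that downstream coverage weighting stays defined for degenerate
    tools.
    """
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def normalized_mcc(mcc_value: float) -> float:
    """Rescale MCC from [-1, 1] to [0, 1]."""
    return (mcc_value + 1.0) / 2.0


def weighted_norm_mcc(mcc_value: float, coverage: float) -> float:
    """Coverage-weighted normalized MCC: ``coverage * (mcc + 1) / 2``."""
    if not -1.0 <= mcc_value <= 1.0:
        raise ValueError("mcc must lie in [-1, 1]")
    if not 0.0 <= coverage <= 1.0:
        raise ValueError("coverage must lie in [0, 1]")
    return coverage * normalized_mcc(mcc_value)


def f_beta(precision: float, recall: float, beta: float) -> float:
    """F-beta score: ``(1 + b^2) P R / (b^2 P + R)``; 0 when P = R = 0.

    beta > 1 favors recall (sensitivity), beta < 1 favors precision;
    beta = 1 is the F1 score.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must lie in [0, 1]")
    b2 = beta * beta
    denom = b2 * precision + recall
    if denom == 0.0:
        return 0.0
    return (1.0 + b2) * precision * recall / denom


def f_beta_from_counts(tp: int, fp: int, fn: int, beta: float) -> float:
    """F-beta directly from counts; 0 when no positives exist or are called."""
    b2 = beta * beta
    denom = (1.0 + b2) * tp + b2 * fn + fp
    if denom == 0.0:
        return 0.0
    return (1.0 + b2) * tp / denom


@dataclass(frozen=True)
class ConfusionSummary:
    """Confusion matrix at one threshold plus coverage-aware derived metrics."""

    tp: int
    tn: int
    fp: int
    fn: int
    n_total: int
    n_scored: int
    coverage: float
    mcc: float
    normalized_mcc: float
    weighted_norm_mcc: float
    sensitivity: float
    specificity: float
    precision: float

    @classmethod
    def from_counts(
        cls, tp: int, tn: int, fp: int, fn: int, n_total: int | None = None
    ) -> "ConfusionSummary":
        n_scored = tp + tn + fp + fn
        if n_total is None:
            n_total = n_scored
        if n_total < n_scored:
            raise ValueError("n_total cannot be smaller than the scored count")
        cov = n_scored / n_total if n_total else 0.0
        m = mcc(tp, tn, fp, fn)
        sens = tp / (tp + fn) if (tp + fn) else UNDEFINED
        spec = tn / (tn + fp) if (tn + fp) else UNDEFINED
        prec = tp / (tp + fp) if (tp + fp) else UNDEFINED
        return cls(
            tp=tp, tn=tn, fp=fp, fn=fn,
            n_total=n_total, n_scored=n_scored, coverage=cov,
            mcc=m, normalized_mcc=normalized_mcc(m),
            weighted_norm_mcc=cov * normalized_mcc(m),
            sensitivity=sens, specificity=spec, precision=prec,
        )


def _as_bool_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype == bool:
        return arr
    out = np.empty(arr.shape, dtype=bool)
    for i, v in enumerate(arr.ravel()):
        if v in ("pathogenic", 1, True):
            out.ravel()[i] = True
        elif v in ("benign", 0, False):
            out.ravel()[i] = False
        else:
            raise ValueError(
                f"label {v!r} is not binary; only pathogenic/benign records may "
                "enter a confusion matrix"
            )
    return out


def confusion_at_threshold(
    scores, labels, threshold: float, comparator: str
) -> ConfusionSummary:
    """Confusion matrix of strict-comparator calls at one threshold.

    ``scores`` may contain NaN for missing predictions; those variants are
    excluded from the counts but included in ``n_total`` (they reduce
    coverage).  ``labels`` are 'pathogenic'/'benign' strings or booleans
    (True = pathogenic).
    """
    s = np.asarray(scores, dtype=float)
    y = _as_bool_labels(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels must be aligned")
    if s.size == 0:
        raise ValueError("at least one labeled variant is required")
    mask = ~np.isnan(s)
    if comparator == STRICT_GREATER:
        called = s[mask] > threshold
    elif comparator == STRICT_LESS:
        called = s[mask] < threshold
    else:
        raise ValueError(f"unknown comparator {comparator!r}")
    truth = y[mask]
    tp = int(np.sum(called & truth))
    fp = int(np.sum(called & ~truth))
    fn = int(np.sum(~called & truth))
    tn = int(np.sum(~called & ~truth))
    return ConfusionSummary.from_counts(tp, tn, fp, fn, n_total=int(s.size))


def rank_transform(scores, direction: str = HIGHER) -> np.ndarray:
    """Map scores to [0, 1] by fractional rank, oriented pathogenic-high.

    Lower-is-pathogenic scales are sign-inverted first, so the output is
    always monotone increasing in pathogenicity.  Ties receive their mean
    rank; missing entries stay missing.  A single scored variant maps to 0.5.
    """
    s = np.asarray(scores, dtype=float)
    mask = ~np.isnan(s)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("rank_transform requires at least one non-missing score")
    vals = s[mask]
    if direction == LOWER:
        vals = -vals
    elif direction != HIGHER:
        raise ValueError(f"unknown direction {direction!r}")
    out = np.full(s.shape, np.nan)
    if n == 1:
        out[mask] = 0.5
    else:
        out[mask] = (rankdata(vals, method="average") - 1.0) / (n - 1.0)
    return out


@dataclass(frozen=True)
class RocSummary:
    """ROC curve (sensitivity vs 1-specificity) and its trapezoidal area."""

    points: tuple  # ordered ((fpr, tpr), ...)
    auroc: float
    n_scored: int
    n_pos: int
    n_neg: int


def roc_and_auroc(scores, labels) -> RocSummary:
    """ROC curve over scored variants only, with tie-grouped cutpoints.

    The trapezoidal area equals the Mann-Whitney concordance probability
    P(score_path > score_benign) + 0.5 P(tie).  Requires both classes among
    the scored variants.
    """
    s = np.asarray(scores, dtype=float)
    y = _as_bool_labels(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels must be aligned")
    mask = ~np.isnan(s)
    s, y = s[mask], y[mask]
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes among scored variants")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    # roc_curve's first point sits at (0, 0) with an infinite threshold and
    # the last at (1, 1); ties share one cutpoint.
    auroc = float(np.trapezoid(tpr, fpr))
    points = tuple((float(a), float(b)) for a, b in zip(fpr, tpr))
    return RocSummary(
        points=points, auroc=auroc, n_scored=int(n_pos + n_neg),
        n_pos=n_pos, n_neg=n_neg,
    )
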