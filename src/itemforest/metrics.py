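"""Diagnostic-accuracy metrics and the paired McNemar test.

Positive class is ASD throughout. AUC is the rank-based (Mann-Whitney)
two-sample statistic with midranks for ties — vote-fraction scores from small
tree ensembles are heavily tied, so tie handling matters. Youden's J is
computed by definition, sensitivity + specificity - 1.

McNemar's test compares two classifiers' per-subject correctness over the same
subjects using only the discordant counts b (A correct, B wrong) and c (A
wrong, B correct):

* ``chi2``:            (b - c)^2 / (b + c), 1-df chi-square reference
* ``chi2_corrected``:  (|b - c| - 1)^2 / (b + c), continuity-corrected
* ``exact``:           two-sided binomial(b; b + c, 1/2)
* ``auto``:            continuity-corrected when min(b, c) < 25, else plain
                       chi-square (standard small-sample practice)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import binom, chi2, rankdata

from .data import (
    ASD,
    NON_ASD,
    CohortLabels,
    DegenerateInputError,
    ValidationError,
)

__all__ = [
    "ConfusionCounts",
    "PerformanceSummary",
    "McNemarResult",
    "confusion",
    "rank_auc",
    "performance",
    "mcnemar",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class PerformanceSummary:
    """Table-row of diagnostic accuracy metrics (positive class = ASD)."""

    auc: float
    acc: float
    sensitivity: float
    specificity: float
    youden_j: float
    n: int

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "acc": self.acc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "youden_j": self.youden_j,
            "n": self.n,
        }


@dataclass(frozen=True)
class McNemarResult:
    b: int
    c: int
    statistic: float
    p_value: float
    method: str

    def to_dict(self) -> dict:
        return {
            "b": self.b,
            "c": self.c,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "method": self.method,
        }


def _align(
    labels: CohortLabels, predictions: Mapping[str, str], what: str
) -> tuple[np.ndarray, np.ndarray]:
    """Return (is_asd_true, is_asd_pred) aligned over the labelled subjects."""
    ids = sorted(labels.by_subject)
    missing = [s for s in ids if s not in predictions]
    extra = sorted(set(predictions) - set(ids))
    if missing or extra:
        raise ValidationError(
            f"{what} do not cover the labelled subjects exactly "
            f"(missing {missing[:5]}, extra {extra[:5]})"
        )
    bad = {v for v in predictions.values()} - {ASD, NON_ASD}
    if bad:
        raise ValidationError(f"{what}: unknown class calls {sorted(bad)}")
    truth = np.array([labels.by_subject[s] == ASD for s in ids])
    pred = np.array([predictions[s] == ASD for s in ids])
    return truth, pred


def confusion(labels: CohortLabels, predictions: Mapping[str, str]) -> ConfusionCounts:
    """2x2 confusion counts of per-subject class calls (positive = ASD)."""
    truth, pred = _align(labels, predictions, "predictions")
    return ConfusionCounts(
        tp=int(np.sum(truth & pred)),
        fp=int(np.sum(~truth & pred)),
        tn=int(np.sum(~truth & ~pred)),
        fn=int(np.sum(truth & ~pred)),
    )


def rank_auc(pos: Sequence[float], neg: Sequence[float]) -> float:
    """Midrank Mann-Whitney AUC of positive-class scores vs negative-class."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise DegenerateInputError("AUC undefined with an empty class")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size))


def performance(
    labels: CohortLabels,
    scores: Mapping[str, float],
    threshold: float = 0.5,
) -> PerformanceSummary:
    """Score-based metric suite: class call = ASD iff score >= threshold."""
    ids = sorted(labels.by_subject)
    missing = [s for s in ids if s not in scores]
    extra = sorted(set(scores) - set(ids))
    if missing or extra:
        raise ValidationError(
            f"scores do not cover the labelled subjects exactly "
            f"(missing {missing[:5]}, extra {extra[:5]})"
        )
    truth = np.array([labels.by_subject[s] == ASD for s in ids])
    s = np.array([float(scores[i]) for i in ids])
    if truth.all() or not truth.any():
        raise DegenerateInputError("both classes required (AUC undefined)")
    auc = rank_auc(s[truth], s[~truth])
    pred = s >= threshold
    tp = int(np.sum(truth & pred))
    fp = int(np.sum(~truth & pred))
    tn = int(np.sum(~truth & ~pred))
    fn = int(np.sum(truth & ~pred))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return PerformanceSummary(
        auc=auc,
        acc=(tp + tn) / truth.size,
        sensitivity=sens,
        specificity=spec,
        youden_j=sens + spec - 1.0,
        n=int(truth.size),
    )


def mcnemar(
    labels: CohortLabels,
    pred_a: Mapping[str, str],
    pred_b: Mapping[str, str],
    method: str = "auto",
) -> McNemarResult:
    """Paired McNemar test on two classifiers' error rates (see module doc).

    ``b`` counts subjects classifier A got right and B wrong; ``c`` the
    reverse. With no discordant pairs the statistic is 0 and p = 1.
    """
    truth, a = _align(labels, pred_a, "pred_a")
    _, bvec = _align(labels, pred_b, "pred_b")
    a_ok = a == truth
    b_ok = bvec == truth
    b = int(np.sum(a_ok & ~b_ok))
    c = int(np.sum(~a_ok & b_ok))
    n_disc = b + c
    if method == "auto":
        method = "chi2_corrected" if min(b, c) < 25 else "chi2"
    if method not in {"chi2", "chi2_corrected", "exact"}:
        raise ValidationError(f"unknown McNemar method {method!r}")
    if n_disc == 0:
        return McNemarResult(b=0, c=0, statistic=0.0, p_value=1.0, method=method)
    if method == "exact":
        p = min(1.0, 2.0 * float(binom.cdf(min(b, c), n_disc, 0.5)))
        return McNemarResult(b=b, c=c, statistic=float(abs(b - c)), p_value=p,
                             method=method)
    if method == "chi2":
        stat = (b - c) ** 2 / n_disc
    else:
        stat = (abs(b - c) - 1) ** 2 / n_disc
    return McNemarResult(
        b=b,
        c=c,
        statistic=float(stat),
        p_value=float(chi2.sf(stat, df=1)),
        method=method,
    )
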