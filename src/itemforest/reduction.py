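"""Stepwise reduced-feature models over an importance hierarchy.

The procedure mirrors a four-step item-reduction protocol for two-group
diagnostic data:

1. **Ranking** — permutation importance of every item, computed on the
   development portion only (75% of subjects; the 25% holdout never touches
   the ranking).
2. **Cross-validated testing** — for each feature count k, the top-k prefix
   of the ranking is trained/tested under stratified 20-fold cross-validation
   of the development data (95% train / 5% test per fold), yielding mean
   test-set metrics.
3. **Validation & weighted selection** — each prefix model is refit on the
   whole development set and evaluated on the untouched validation holdout;
   a weighted score ``w1 * AUC_val + w2 * complexity(k)`` with w1 = 0.35 and
   w2 = 0.65 (simplicity weighted 2:1 over accuracy) picks the *optimal*
   model.
4. **McNemar minimality** — each prefix model's validation predictions are
   compared against the full-feature model's; the *minimal* model is the
   smallest prefix whose error rate is statistically indistinguishable from
   the full model (p >= alpha).

Complexity is mapped onto the AUC scale by a configurable normalization:
``linear_inverse`` gives 1 - (k-1)/(N-1) (1 for a single item, 0 for the
full set); ``rank_based`` gives (N-k)/N. Higher = simpler under both.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import rf
from .data import (
    ASD,
    NON_ASD,
    CohortLabels,
    DegenerateInputError,
    ItemMatrix,
    ValidationError,
    config_to_dict,
)
from .metrics import McNemarResult, PerformanceSummary, mcnemar, performance
from .rf import ImportanceRanking, RFConfig

__all__ = [
    "SplitPlan",
    "SelectionConfig",
    "ModelEvaluation",
    "SelectionReport",
    "make_split",
    "complexity",
    "evaluate_reduced_model",
    "select_models",
]


@dataclass
class SplitPlan:
    """Stratified 75/25 development/validation split plus 20 CV folds.

    ``folds`` partitions ``development_ids``: every development subject
    appears in exactly one fold's test set.
    """

    development_ids: list[str]
    validation_ids: list[str]
    folds: list[tuple[list[str], list[str]]]
    seed: int

    def audit(self) -> None:
        """Raise if the holdout leaks into any fold (or folds malform)."""
        dev, val = set(self.development_ids), set(self.validation_ids)
        if dev & val:
            raise ValidationError(f"development/validation overlap: {sorted(dev & val)[:5]}")
        seen_test: list[str] = []
        for i, (train, test) in enumerate(self.folds):
            tr, te = set(train), set(test)
            if (tr | te) != dev or (tr & te):
                raise ValidationError(f"fold {i} is not a partition of development")
            if (tr | te) & val:
                raise ValidationError(f"fold {i} contains validation subjects")
            seen_test.extend(test)
        if sorted(seen_test) != sorted(self.development_ids):
            raise ValidationError("fold test sets do not partition development")


def make_split(
    matrix: ItemMatrix,
    labels: CohortLabels,
    seed: int,
    validation_fraction: float = 0.25,
    n_folds: int = 20,
) -> SplitPlan:
    """Hold out a stratified validation fraction, fold the rest.

    Per class, ``round(fraction * n_class)`` subjects go to validation, so a
    100 + 100 cohort yields exactly 25 holdout subjects per class. Folds come
    from a seeded, shuffled :class:`~sklearn.model_selection.StratifiedKFold`
    over the development subjects.
    """
    labels.validate_against(matrix.subject_ids)
    ids = np.array(matrix.subject_ids)
    is_asd = labels.is_asd(matrix.subject_ids)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    val_ids: list[str] = []
    dev_ids: list[str] = []
    for cls_mask in (is_asd, ~is_asd):
        cls_ids = ids[cls_mask]
        if cls_ids.size < 2:
            raise DegenerateInputError(
                "need >= 2 subjects per class to stratify the holdout"
            )
        n_val = int(round(validation_fraction * cls_ids.size))
        perm = rng.permutation(cls_ids.size)
        val_ids.extend(cls_ids[perm[:n_val]])
        dev_ids.extend(cls_ids[perm[n_val:]])
    # Restore matrix order for reproducible serialization.
    order = {s: i for i, s in enumerate(matrix.subject_ids)}
    val_ids.sort(key=order.__getitem__)
    dev_ids.sort(key=order.__getitem__)
    dev_arr = np.array(dev_ids)
    y_dev = labels.is_asd(dev_ids).astype(int)
    counts = np.bincount(y_dev, minlength=2)
    if counts.min() < n_folds:
        raise DegenerateInputError(
            f"cannot stratify {n_folds} folds: smallest class has "
            f"{counts.min()} development subjects"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=seed % (2**31 - 1))
    folds = [
        (list(dev_arr[tr]), list(dev_arr[te]))
        for tr, te in skf.split(np.zeros(len(dev_ids)), y_dev)
    ]
    plan = SplitPlan(
        development_ids=dev_ids,
        validation_ids=val_ids,
        folds=folds,
        seed=seed,
    )
    plan.audit()
    return plan


def complexity(k: int, n_features: int, normalization: str = "linear_inverse") -> float:
    """Model simplicity in [0, 1] for a k-feature model out of N candidates."""
    if n_features < 2:
        raise ValidationError(f"need >= 2 candidate features, got {n_features}")
    if not 1 <= k <= n_features:
        raise ValidationError(f"k must be in 1..{n_features}, got {k}")
    if normalization == "linear_inverse":
        return 1.0 - (k - 1) / (n_features - 1)
    if normalization == "rank_based":
        # Fraction of candidate models at least as complex, minus the 1/N
        # offset that keeps the value inside [0, 1).
        return (n_features - k) / n_features
    raise ValidationError(f"unknown complexity normalization {normalization!r}")


@dataclass
class SelectionConfig:
    """Weights and knobs of the selection procedure.

    ``w1``/``w2`` weight validation AUC against simplicity 0.35 : 0.65 — the
    2:1 preference for simpler models. ``run_cv=False`` skips the 20-fold
    test-set pass (validation-set quantities are unaffected); used for large
    multi-seed experiments.
    """

    w1: float = 0.35
    w2: float = 0.65
    alpha: float = 0.05
    complexity_normalization: str = "linear_inverse"
    threshold: float = 0.5
    rf: RFConfig = field(default_factory=RFConfig)
    mcnemar_method: str = "auto"
    run_cv: bool = True
    n_folds: int = 20
    validation_fraction: float = 0.25

    def validate(self) -> None:
        if abs(self.w1 + self.w2 - 1.0) > 1e-9:
            raise ValidationError(f"w1 + w2 must equal 1, got {self.w1 + self.w2}")
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        complexity(1, 2, self.complexity_normalization)  # raises on bad token
        self.rf.validate()


def _mean_summary(parts: list[PerformanceSummary]) -> PerformanceSummary:
    return PerformanceSummary(
        auc=float(np.mean([p.auc for p in parts])),
        acc=float(np.mean([p.acc for p in parts])),
        sensitivity=float(np.mean([p.sensitivity for p in parts])),
        specificity=float(np.mean([p.specificity for p in parts])),
        youden_j=float(np.mean([p.youden_j for p in parts])),
        n=int(sum(p.n for p in parts)),
    )


def _calls(scores: dict[str, float], threshold: float) -> dict[str, str]:
    return {s: (ASD if v >= threshold else NON_ASD) for s, v in scores.items()}


@dataclass
class ModelEvaluation:
    """Metrics of one top-k prefix model.

    ``test_summary`` is the mean over the CV folds (None when CV skipped);
    ``validation_summary`` comes from a single refit on all development
    subjects scored on the holdout.
    """

    k: int
    feature_ids: list[str]
    test_summary: PerformanceSummary | None
    validation_summary: PerformanceSummary
    validation_predictions: dict[str, str]
    weighted_score: float

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "feature_ids": self.feature_ids,
            "test_summary": self.test_summary.to_dict() if self.test_summary else None,
            "validation_summary": self.validation_summary.to_dict(),
            "validation_predictions": self.validation_predictions,
            "weighted_score": self.weighted_score,
        }


def _fold_seed(base: int, k: int, fold: int) -> int:
    # Distinct, reproducible stream per (k, fold); kept under 2**31.
    return (base * 1_000_003 + k * 7919 + fold * 104_729) % (2**31 - 1)


def evaluate_reduced_model(
    matrix: ItemMatrix,
    labels: CohortLabels,
    ranking: ImportanceRanking,
    k: int,
    plan: SplitPlan,
    config: SelectionConfig,
) -> ModelEvaluation:
    """Train/test the top-k prefix per the plan and score it.

    CV pass: one fit per fold on the fold's training subjects, metrics on the
    fold's test subjects, averaged. Validation pass: one refit on the whole
    development set, scored on the holdout. The weighted score combines the
    *validation* AUC with complexity(k).
    """
    config.validate()
    features = ranking.top(k)
    n_features = len(ranking.item_ids)
    test_summary = None
    if config.run_cv:
        parts = []
        for f, (train, test) in enumerate(plan.folds):
            try:
                model = rf.fit(
                    matrix.subset(subject_ids=train),
                    labels.subset(train),
                    features,
                    config.rf.reseeded(_fold_seed(config.rf.seed, k, f + 1)),
                )
                scores = rf.predict_scores(model, matrix.subset(subject_ids=test))
                parts.append(
                    performance(labels.subset(test), scores, config.threshold)
                )
            except DegenerateInputError as e:
                raise DegenerateInputError(f"fold {f}: {e}") from e
        test_summary = _mean_summary(parts)
    dev_model = rf.fit(
        matrix.subset(subject_ids=plan.development_ids),
        labels.subset(plan.development_ids),
        features,
        config.rf.reseeded(_fold_seed(config.rf.seed, k, 0)),
    )
    val_scores = rf.predict_scores(
        dev_model, matrix.subset(subject_ids=plan.validation_ids)
    )
    val_summary = performance(
        labels.subset(plan.validation_ids), val_scores, config.threshold
    )
    score = config.w1 * val_summary.auc + config.w2 * complexity(
        k, n_features, config.complexity_normalization
    )
    return ModelEvaluation(
        k=k,
        feature_ids=features,
        test_summary=test_summary,
        validation_summary=val_summary,
        validation_predictions=_calls(val_scores, config.threshold),
        weighted_score=float(score),
    )


@dataclass
class SelectionReport:
    """Everything the selection produced: ranking, k-curve, chosen models."""

    ranking: ImportanceRanking
    evaluations: dict[int, ModelEvaluation]
    optimal_k: int
    minimal_k: int | None
    mcnemar_vs_full: dict[int, McNemarResult]
    plan: SplitPlan
    config: SelectionConfig
    seed: int

    @property
    def n_features(self) -> int:
        return len(self.ranking.item_ids)

    @property
    def full(self) -> ModelEvaluation:
        return self.evaluations[self.n_features]

    @property
    def optimal(self) -> ModelEvaluation:
        return self.evaluations[self.optimal_k]

    @property
    def minimal(self) -> ModelEvaluation | None:
        return None if self.minimal_k is None else self.evaluations[self.minimal_k]

    def to_json_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config": config_to_dict(self.config),
            "ranking": {
                "item_ids": self.ranking.item_ids,
                "importances": [float(v) for v in self.ranking.importances],
            },
            "plan": {
                "development_ids": self.plan.development_ids,
                "validation_ids": self.plan.validation_ids,
                "folds": [[tr, te] for tr, te in self.plan.folds],
                "seed": self.plan.seed,
            },
            "evaluations": {str(k): e.to_dict() for k, e in self.evaluations.items()},
            "optimal_k": self.optimal_k,
            "minimal_k": self.minimal_k,
            "mcnemar_vs_full": {
                str(k): r.to_dict() for k, r in self.mcnemar_vs_full.items()
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_json_dict(), indent=1, sort_keys=True)

    def metrics_table(self) -> pd.DataFrame:
        """Three-row summary (full / optimal / minimal models), wide format."""
        rows = []
        for name, ev in (
            ("full", self.full),
            ("optimal", self.optimal),
            ("minimal", self.minimal),
        ):
            if ev is None:
                continue
            row = {"model": name, "k": ev.k}
            if ev.test_summary is not None:
                for m, v in ev.test_summary.to_dict().items():
                    if m != "n":
                        row[f"{m}_test"] = v
            for m, v in ev.validation_summary.to_dict().items():
                if m != "n":
                    row[f"{m}_val"] = v
            row["weighted_score"] = ev.weighted_score
            row["mcnemar_p_vs_full"] = self.mcnemar_vs_full[ev.k].p_value
            rows.append(row)
        return pd.DataFrame(rows)

    def auc_curve(self) -> pd.DataFrame:
        """AUC (and weighted score) against feature count — the k-curve."""
        rows = []
        for k in sorted(self.evaluations):
            ev = self.evaluations[k]
            rows.append(
                {
                    "k": k,
                    "auc_val": ev.validation_summary.auc,
                    "auc_test": (
                        ev.test_summary.auc if ev.test_summary is not None else np.nan
                    ),
                    "weighted_score": ev.weighted_score,
                }
            )
        return pd.DataFrame(rows)

    def ranked_items(self) -> pd.DataFrame:
        df = self.ranking.to_frame()
        return df


def select_models(
    matrix: ItemMatrix,
    labels: CohortLabels,
    plan: SplitPlan,
    config: SelectionConfig,
    ks: Sequence[int] | None = None,
) -> SelectionReport:
    """Run the full procedure: rank on development, evaluate prefixes, choose.

    ``ks`` defaults to 1..N. The full-feature count N is always evaluated
    (it anchors the McNemar comparisons). Optimal k maximizes the weighted
    score, ties to the smaller k; minimal k is the smallest evaluated k whose
    validation predictions are McNemar-equivalent to the full model's
    (p >= alpha), or None if none is.
    """
    config.validate()
    plan.audit()
    labels.validate_against(matrix.subject_ids)
    dev_matrix = matrix.subset(subject_ids=plan.development_ids)
    dev_labels = labels.subset(plan.development_ids)
    try:
        ranking = rf.importance(dev_matrix, dev_labels, matrix.item_ids, config.rf)
    except (DegenerateInputError, ValidationError) as e:
        raise type(e)(f"ranking stage: {e}") from e
    n_features = len(ranking.item_ids)
    if ks is None:
        ks = range(1, n_features + 1)
    ks = sorted(set(int(k) for k in ks) | {n_features})
    evaluations: dict[int, ModelEvaluation] = {}
    for k in ks:
        try:
            evaluations[k] = evaluate_reduced_model(
                matrix, labels, ranking, k, plan, config
            )
        except DegenerateInputError as e:
            raise DegenerateInputError(f"evaluation stage (k={k}): {e}") from e
    full_pred = evaluations[n_features].validation_predictions
    val_labels = labels.subset(plan.validation_ids)
    mcn = {
        k: mcnemar(
            val_labels,
            evaluations[k].validation_predictions,
            full_pred,
            config.mcnemar_method,
        )
        for k in ks
    }
    best = max(evaluations.values(), key=lambda e: (e.weighted_score, -e.k))
    minimal_k = next(
        (k for k in ks if mcn[k].p_value >= config.alpha), None
    )
    return SelectionReport(
        ranking=ranking,
        evaluations=evaluations,
        optimal_k=best.k,
        minimal_k=minimal_k,
        mcnemar_vs_full=mcn,
        plan=plan,
        config=config,
        seed=plan.seed,
    )
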