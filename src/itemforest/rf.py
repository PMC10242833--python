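"""Majority-vote tree ensembles with out-of-bag permutation importance.

The classifier is Breiman-style bagging: each tree is fit on a bootstrap
sample of the training subjects and considers a random subset of features at
every split; the ensemble's class call is the majority vote, and the score we
expose is the fraction of trees voting ASD. Individual trees are scikit-learn
``DecisionTreeClassifier``s; the bagging loop is owned here so that each
tree's bootstrap (and hence out-of-bag, OOB) subjects are known exactly —
required for the importance measure.

Feature importance is the mean decrease in accuracy: for each tree, OOB
accuracy is measured before and after permuting one feature's values among
the OOB subjects, and the drop is averaged over trees and permutation
repeats. A feature the trees never use, or one carrying no signal, hovers
near zero; informative features lose accuracy when scrambled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .data import (
    MISSING,
    CohortLabels,
    DegenerateInputError,
    ItemMatrix,
    ValidationError,
)

__all__ = [
    "RFConfig",
    "FittedModel",
    "ImportanceRanking",
    "fit",
    "predict_scores",
    "importance",
]

_SEED_MOD = 2**31 - 1


@dataclass(frozen=True)
class RFConfig:
    """Ensemble hyperparameters.

    ``features_per_split`` accepts the rule token ``"sqrt"`` (square-root-of-p,
    the common default) or an explicit integer.
    """

    n_trees: int = 500
    features_per_split: str | int = "sqrt"
    min_leaf: int = 1
    importance_repeats: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.n_trees < 1:
            raise ValidationError(f"n_trees must be >= 1, got {self.n_trees}")
        if self.importance_repeats < 1:
            raise ValidationError(
                f"importance_repeats must be >= 1, got {self.importance_repeats}"
            )
        if isinstance(self.features_per_split, str):
            if self.features_per_split != "sqrt":
                raise ValidationError(
                    f"unknown features_per_split rule {self.features_per_split!r}"
                )
        elif self.features_per_split < 1:
            raise ValidationError("features_per_split must be >= 1")

    def reseeded(self, seed: int) -> "RFConfig":
        return replace(self, seed=int(seed) % _SEED_MOD)


@dataclass
class FittedModel:
    """A trained ensemble plus the bookkeeping needed for OOB computations."""

    trees: list[DecisionTreeClassifier]
    bootstrap_indices: list[np.ndarray]
    feature_ids: list[str]
    n_train: int
    config: RFConfig
    _train_X: np.ndarray = field(repr=False, default=None)
    _train_y: np.ndarray = field(repr=False, default=None)


def _design(
    matrix: ItemMatrix, labels: CohortLabels, feature_ids: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    missing_cols = [f for f in feature_ids if f not in matrix.item_ids]
    if missing_cols:
        raise ValidationError(f"features not in matrix: {missing_cols[:5]}")
    sub = matrix.subset(item_ids=list(feature_ids))
    if (sub.codes == MISSING).any():
        bad = [
            sub.subject_ids[i]
            for i in np.unique(np.nonzero(sub.codes == MISSING)[0])[:5]
        ]
        raise ValidationError(
            f"missing codes among requested features (complete-case filtering "
            f"is the caller's job); offending subjects include {bad}"
        )
    X = sub.codes.astype(np.float64)
    y = labels.is_asd(matrix.subject_ids).astype(np.int64)
    if X.shape[0] == 0:
        raise DegenerateInputError("no usable subjects")
    if len(np.unique(y)) < 2:
        raise DegenerateInputError("both classes required to fit")
    return X, y


def _mtry(p: int, rule: str | int) -> int:
    if rule == "sqrt":
        return max(1, int(round(np.sqrt(p))))
    return min(int(rule), p)


def fit(
    matrix: ItemMatrix,
    labels: CohortLabels,
    feature_ids: Sequence[str],
    config: RFConfig,
) -> FittedModel:
    """Fit the bagged ensemble on complete-case subjects. Seed-deterministic."""
    config.validate()
    X, y = _design(matrix, labels, feature_ids)
    n = X.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    mtry = _mtry(X.shape[1], config.features_per_split)
    trees: list[DecisionTreeClassifier] = []
    boots: list[np.ndarray] = []
    for _ in range(config.n_trees):
        idx = rng.integers(0, n, size=n)
        tree = DecisionTreeClassifier(
            max_features=mtry,
            min_samples_leaf=config.min_leaf,
            random_state=int(rng.integers(0, _SEED_MOD)),
        )
        tree.fit(X[idx], y[idx])
        trees.append(tree)
        boots.append(idx)
    return FittedModel(
        trees=trees,
        bootstrap_indices=boots,
        feature_ids=list(feature_ids),
        n_train=n,
        config=config,
        _train_X=X,
        _train_y=y,
    )


def _vote_matrix(model: FittedModel, X: np.ndarray) -> np.ndarray:
    """(n_trees, n_subjects) matrix of per-tree ASD votes (0/1)."""
    votes = np.empty((len(model.trees), X.shape[0]), dtype=np.int64)
    for t, tree in enumerate(model.trees):
        pred = tree.predict(X)
        # A tree trained on a one-class bootstrap predicts that class for all.
        votes[t] = pred if tree.n_classes_ > 1 else np.full(X.shape[0], pred[0])
    return votes


def predict_scores(model: FittedModel, matrix: ItemMatrix) -> dict[str, float]:
    """Per-subject vote fraction in [0, 1]: share of trees calling ASD."""
    missing_cols = [f for f in model.feature_ids if f not in matrix.item_ids]
    if missing_cols:
        raise ValidationError(f"matrix lacks model features: {missing_cols[:5]}")
    sub = matrix.subset(item_ids=model.feature_ids)
    if (sub.codes == MISSING).any():
        raise ValidationError("missing codes among model features at predict time")
    votes = _vote_matrix(model, sub.codes.astype(np.float64))
    scores = votes.mean(axis=0)
    return dict(zip(matrix.subject_ids, scores.astype(float)))


@dataclass
class ImportanceRanking:
    """Items ordered by mean decrease in OOB accuracy (descending).

    ``rank`` is 1-based; ties in importance keep the items' input order
    (stable sort), so rankings are reproducible.
    """

    item_ids: list[str]
    importances: np.ndarray

    def __post_init__(self) -> None:
        self.importances = np.asarray(self.importances, dtype=float)
        if len(self.item_ids) != self.importances.size:
            raise ValidationError("item_ids and importances length mismatch")
        if np.any(np.diff(self.importances) > 1e-12):
            raise ValidationError("importances must be non-increasing with rank")

    def top(self, k: int) -> list[str]:
        if not 1 <= k <= len(self.item_ids):
            raise ValidationError(
                f"k must be in 1..{len(self.item_ids)}, got {k}"
            )
        return self.item_ids[:k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.item_ids) + 1),
                "item_id": self.item_ids,
                "importance": self.importances,
            }
        )


def importance(
    matrix: ItemMatrix,
    labels: CohortLabels,
    feature_ids: Sequence[str],
    config: RFConfig,
) -> ImportanceRanking:
    """Permutation importance on out-of-bag subjects, averaged over trees.

    For each tree with a non-empty OOB set: baseline OOB accuracy minus
    accuracy after permuting each feature among the OOB subjects, repeated
    ``config.importance_repeats`` times with fresh permutations. The ranking
    is computed on whatever subjects the caller passes in — holdout data must
    be excluded upstream.
    """
    model = fit(matrix, labels, feature_ids, config)
    X, y = model._train_X, model._train_y
    n, p = X.shape
    reps = config.importance_repeats
    # Separate stream from the bootstrap RNG, still derived from config.seed.
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))
    drops = np.zeros(p)
    used_trees = 0
    for tree, boot in zip(model.trees, model.bootstrap_indices):
        oob = np.setdiff1d(np.arange(n), boot, assume_unique=False)
        m = oob.size
        if m == 0:
            continue
        Xo = X[oob]
        yo = y[oob]
        base = float(np.mean(tree.predict(Xo) == yo))
        # One stacked predict call per tree: (reps * p) permuted OOB copies.
        big = np.tile(Xo, (reps * p, 1)).reshape(reps, p, m, p)
        for r in range(reps):
            for j in range(p):
                big[r, j, :, j] = Xo[rng.permutation(m), j]
        perm_pred = tree.predict(big.reshape(reps * p * m, p)).reshape(reps, p, m)
        perm_acc = (perm_pred == yo).mean(axis=2)  # (reps, p)
        drops += base - perm_acc.mean(axis=0)
        used_trees += 1
    if used_trees == 0:
        raise DegenerateInputError("no tree had out-of-bag subjects")
    drops /= used_trees
    order = np.argsort(-drops, kind="stable")
    return ImportanceRanking(
        item_ids=[feature_ids[i] for i in order],
        importances=drops[order],
    )
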