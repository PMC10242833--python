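"""Synthetic two-group cohorts of ordinal instrument items.

Because clinical ADOS/ADI-R records are confidential, every downstream stage
of the pipeline is exercised on simulated cohorts. Items are generated from a
proportional-odds (ordered-logit) model: the non-ASD group draws codes from a
baseline multinomial (uniform over levels by default), and the ASD group from
the same cumulative-logit model with its location shifted by the item's
``shift``, which moves probability mass toward higher codes. A single scalar
per item therefore controls that item's discriminability, and the implied
class-conditional multinomials — and hence the exact single-item AUC — are
available in closed form for calibration.

ADI-R missingness is interview-level: a seeded Bernoulli draw per subject
blanks that subject's entire ADI-R block, mirroring cohorts where only a
subset of children had an ADI-R interview.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit
from scipy.stats import rankdata

from .data import (
    ASD,
    MISSING,
    NON_ASD,
    CohortLabels,
    DegenerateInputError,
    Instrument,
    ItemDefinition,
    ItemMatrix,
    ValidationError,
)

__all__ = [
    "CohortSpec",
    "generate_cohort",
    "single_item_discriminability",
    "item_class_probabilities",
    "closed_form_item_auc",
    "default_cohort_spec",
    "null_cohort_spec",
]


@dataclass
class CohortSpec:
    """Recipe for one synthetic cohort.

    ``adi_missing_fraction`` is the per-subject probability that the whole
    ADI-R block is missing; ADOS items are never blanked.
    """

    n_asd: int
    n_nonasd: int
    items: list[ItemDefinition] = field(default_factory=list)
    adi_missing_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_asd < 1:
            raise ValidationError(f"n_asd must be >= 1, got {self.n_asd}")
        if self.n_nonasd < 1:
            raise ValidationError(f"n_nonasd must be >= 1, got {self.n_nonasd}")
        if not self.items:
            raise ValidationError("items must be non-empty")
        if not 0.0 <= self.adi_missing_fraction <= 1.0:
            raise ValidationError(
                f"adi_missing_fraction must be in [0, 1], "
                f"got {self.adi_missing_fraction}"
            )
        seen: set[str] = set()
        for item in self.items:
            item.validate()
            if item.item_id in seen:
                raise ValidationError(f"duplicate item_id {item.item_id!r}")
            seen.add(item.item_id)


def _uniform_cutpoints(n_levels: int) -> np.ndarray:
    # Cumulative logits of a uniform baseline: c_k = logit((k+1)/K).
    return logit(np.arange(1, n_levels) / n_levels)


def item_class_probabilities(item: ItemDefinition) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form class-conditional code distributions (non-ASD, ASD).

    Under the cumulative-logit model, P(code <= k | group) =
    expit(c_k - location) with location 0 for non-ASD and ``item.shift`` for
    ASD; cutpoints are chosen so the non-ASD baseline is uniform over levels.
    Each returned vector sums to 1 exactly (last cumulative value is pinned
    to 1).
    """
    item.validate()
    cuts = _uniform_cutpoints(item.n_levels)

    def probs(location: float) -> np.ndarray:
        cdf = np.append(expit(cuts - location), 1.0)
        p = np.diff(cdf, prepend=0.0)
        return p / p.sum()

    return probs(0.0), probs(item.shift)


def closed_form_item_auc(item: ItemDefinition) -> float:
    """Exact AUC of a single item's code for ASD vs non-ASD (midrank ties)."""
    p_non, p_asd = item_class_probabilities(item)
    # P(asd > non) + 0.5 * P(asd == non) over independent draws.
    cdf_non = np.cumsum(p_non)
    below = np.concatenate([[0.0], cdf_non[:-1]])
    return float(np.sum(p_asd * below) + 0.5 * np.sum(p_asd * p_non))


def generate_cohort(spec: CohortSpec) -> tuple[ItemMatrix, CohortLabels]:
    """Draw one cohort: codes independently per subject and item, seeded.

    Subjects are ordered ASD block first (ids ``asd0001`` ...), then non-ASD
    (``ctl0001`` ...). Bit-identical output for identical specs.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_asd + spec.n_nonasd
    subject_ids = [f"asd{i + 1:04d}" for i in range(spec.n_asd)] + [
        f"ctl{i + 1:04d}" for i in range(spec.n_nonasd)
    ]
    labels = CohortLabels(
        {s: (ASD if i < spec.n_asd else NON_ASD) for i, s in enumerate(subject_ids)}
    )
    codes = np.empty((n, len(spec.items)), dtype=np.int64)
    for j, item in enumerate(spec.items):
        p_non, p_asd = item_class_probabilities(item)
        codes[: spec.n_asd, j] = rng.choice(item.n_levels, size=spec.n_asd, p=p_asd)
        codes[spec.n_asd :, j] = rng.choice(
            item.n_levels, size=spec.n_nonasd, p=p_non
        )
    if spec.adi_missing_fraction > 0:
        adi_cols = [
            j
            for j, item in enumerate(spec.items)
            if item.instrument == Instrument.ADI_R
        ]
        blank = rng.random(n) < spec.adi_missing_fraction
        if adi_cols:
            codes[np.ix_(blank, adi_cols)] = MISSING
    matrix = ItemMatrix(
        subject_ids=subject_ids,
        item_ids=[item.item_id for item in spec.items],
        codes=codes,
        item_meta={item.item_id: item for item in spec.items},
    )
    return matrix, labels


def single_item_discriminability(
    matrix: ItemMatrix, labels: CohortLabels, item_id: str
) -> float:
    """Rank-based two-sample AUC of one item's codes for ASD vs non-ASD.

    Midranks handle the (heavy) ties of ordinal codes; missing codes are
    dropped. Raises :class:`DegenerateInputError` when either class has no
    observed code.
    """
    col = matrix.column(item_id)
    is_asd = labels.is_asd(matrix.subject_ids)
    observed = col != MISSING
    pos = col[observed & is_asd]
    neg = col[observed & ~is_asd]
    if pos.size == 0 or neg.size == 0:
        raise DegenerateInputError(
            f"item {item_id!r}: no observed codes for "
            f"{'ASD' if pos.size == 0 else 'non-ASD'} subjects"
        )
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size))


def default_cohort_spec(
    seed: int = 0,
    n_per_group: int = 250,
    n_informative: int = 10,
    shift: float = 1.5,
    n_ados: int = 29,
    n_adi: int = 31,
    n_levels: int = 3,
    adi_missing_fraction: float = 0.0,
) -> CohortSpec:
    """The package's reference fixture: 29 "ADOS" + 31 "ADI-R" items, 250
    subjects per group, 10 informative items at ordered-logit shift 1.5.

    Informative items alternate between the two instrument blocks (ceil-half
    ADOS, floor-half ADI-R) so both instruments carry signal by default.
    """
    n_inf_ados = min((n_informative + 1) // 2, n_ados)
    n_inf_adi = min(n_informative - n_inf_ados, n_adi)
    items = [
        ItemDefinition(
            f"ados_{i + 1:02d}",
            Instrument.ADOS,
            n_levels,
            shift if i < n_inf_ados else 0.0,
        )
        for i in range(n_ados)
    ] + [
        ItemDefinition(
            f"adi_{i + 1:02d}",
            Instrument.ADI_R,
            n_levels,
            shift if i < n_inf_adi else 0.0,
        )
        for i in range(n_adi)
    ]
    return CohortSpec(
        n_asd=n_per_group,
        n_nonasd=n_per_group,
        items=items,
        adi_missing_fraction=adi_missing_fraction,
        seed=seed,
    )


def null_cohort_spec(seed: int = 0, n_per_group: int = 250) -> CohortSpec:
    """All-null variant of the reference fixture (every shift 0)."""
    return default_cohort_spec(seed=seed, n_per_group=n_per_group, n_informative=0)
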