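# Methods

## The selection procedure

`itemforest` treats item reduction as prefix selection over a single
importance hierarchy. Given a subjects × items matrix of ordinal codes and a
binary label (positive class = ASD):

1. A stratified 25% validation holdout is drawn first (per class,
   `round(0.25 · n_class)` subjects). Everything below runs on the remaining
   development portion; the holdout is only ever *scored*.
2. Items are ranked by permutation importance (mean decrease in out-of-bag
   accuracy) of one ensemble fit on the development data.
3. For k = 1..N, the top-k prefix is evaluated two ways: (a) stratified
   20-fold cross-validation of the development set — one fit per fold on the
   ~95% training part, metrics on the ~5% test part, averaged; (b) one refit
   on the whole development set, scored on the holdout.
4. The weighted score `S(k) = w1·AUC_val(k) + w2·complexity(k)` with
   w1 = 0.35, w2 = 0.65 picks the **optimal** k (argmax; ties go to the
   smaller k, consistent with the 2:1 simplicity preference). McNemar's test
   of each prefix model's holdout predictions against the full model's picks
   the **minimal** k (smallest k with p ≥ α).

Model evaluations are nested by construction (`top(k) ⊂ top(k+1)`); the
package deliberately does not search non-prefix subsets, re-rank per fold,
or try other learners.

## The classifier

Breiman-style bagging: each of `n_trees` CART trees is fit on a bootstrap
sample (n draws with replacement) of the training subjects, considering
`√p` randomly chosen features at each split (`features_per_split`,
configurable to any integer); leaves may hold a single subject
(`min_leaf = 1`). The ensemble score of a subject is the fraction of trees
voting ASD, and the class call is score ≥ 0.5 (`threshold`, configurable —
vote fractions are heavily tied, so the threshold convention matters and is
applied as ≥). Trees are scikit-learn `DecisionTreeClassifier`s; the
bagging loop is implemented here so each tree's bootstrap — and therefore
its out-of-bag (OOB) complement — is known exactly.

Defaults: `n_trees = 500`, `importance_repeats = 5`. Ensembles this size
make vote fractions and rankings stable to within the Monte-Carlo noise of
everything else in the pipeline; the multi-seed experiments in the test
suite and acceptance script use 100 trees and 1–2 repeats, which on the
reference fixture (p = 60, n = 500) leaves rankings and AUCs statistically
indistinguishable from the defaults while keeping 20–200-seed experiments
at desk scale (the full k = 1..60 sweep takes ~8 s per seed without the CV
pass, ~4 min with it).

### Permutation importance

For each tree with a non-empty OOB set: baseline OOB accuracy minus OOB
accuracy after permuting one feature's values among the OOB subjects,
repeated `importance_repeats` times, averaged over repeats and trees.
Importance is computed on whatever subjects the caller passes —
`select_models` passes the development portion only, so the holdout can
never influence the ranking (a test verifies the ranking is bit-identical
after scrambling all holdout rows). Ties in importance are broken by input
item order via a stable sort, keeping rankings reproducible. A constant
feature has importance exactly 0 up to floating noise (permutation is a
no-op); null features scatter around 0 and may go slightly negative.

## Metrics and the McNemar test

AUC is the midrank Mann-Whitney statistic — equivalent to the trapezoidal
ROC area, and the right form for heavily tied vote fractions. Youden's J is
computed by definition (Sens + Spec − 1) from the same 2×2 table as
accuracy. McNemar's test uses only the discordant counts b (model A correct,
B wrong) and c (the reverse): statistic `(b−c)²/(b+c)` against a 1-df
chi-square, `(|b−c|−1)²/(b+c)` with continuity correction, or the two-sided
exact binomial `2·P(X ≤ min(b,c))`, X ~ Bin(b+c, ½), capped at 1. The
default method is `auto`: continuity-corrected below min(b, c) = 25,
plain chi-square above — standard small-sample practice. With b = c = 0
(e.g. a model compared against itself) the statistic is 0 and p = 1.

## Complexity normalization

The weighted score needs "number of variables" on the same [0, 1] scale as
AUC. Two normalizations are implemented, both decreasing in k:

* `linear_inverse` (default): `1 − (k−1)/(N−1)` — 1 for a one-item model,
  0 for the full set;
* `rank_based`: `(N−k)/N` — the fraction of candidate models with more than
  k features.

With w2 = 0.65 and `linear_inverse`, each additional feature costs
0.65/(N−1) in score — 0.011 at N = 60 — so a step from k to k+1 pays off
only if it buys more than 0.031 of validation AUC. Any AUC-vs-k curve that
stagnates (which is the expected and observed shape whenever few items are
informative) therefore yields a very small optimum, typically k ≈ 3 on the
reference fixture. This is a property of the scoring rule itself, not of the
implementation: applying the same weights to any published table of
(AUC, k) pairs with a stagnating curve selects far smaller models than a
selection based on peak AUC would. Both normalizations and both AUC sources
are exposed in `SelectionConfig` so users can study this trade-off; the
package does not tune the weights.

## The synthetic cohort generator

Each item is a proportional-odds (cumulative-logit) ordinal variable with
cutpoints fixed so the non-ASD group is uniform over its `n_levels` codes
(default 3, mirroring the 0–2 algorithm-code convention of clinical
instruments); the ASD group shares the cutpoints with its location shifted
by the item's `shift` ≥ 0, moving mass toward higher codes. One scalar per
item thus sets its discriminability, and the implied class-conditional
multinomials — hence the exact single-item AUC — are available in closed
form (`closed_form_item_auc`): shift 0 → 0.5, shift 1.5 → 0.697, shift
2.0 → 0.741. Draws are independent across subjects and items given the
seed. ADI-R missingness is interview-level: a Bernoulli draw per subject
blanks that subject's entire ADI-R block.

The reference fixture — 250 subjects per group, 29 "ADOS" + 31 "ADI-R"
items, 10 informative at shift 1.5 (alternating between the blocks) — is
sized so that multi-seed experiments finish in minutes while the signal is
comfortably recoverable: across 20 seeds the top-10 ranking recovers all 10
informative items essentially always, and the validation AUC at k = 10 is
within ~0.002 of the full model's.

What the generator does *not* emulate: inter-item correlation (real
instrument items are strongly correlated within domains), rater and site
effects, administrative codes (7/8) and item-level recodings, and
age-dependent symptom expression. Passing tests therefore demonstrate that
the pipeline recovers signal and is calibrated under independent ordinal
items — not that any particular item subset of the real instruments is
sufficient.

### Statistical behavior worth knowing

* On a validation holdout of ~125 subjects, a null-model AUC has standard
  deviation `√((n₁+n₂+1)/(12·n₁·n₂))` ≈ 0.05, so under the all-null fixture
  roughly 30% of seeds fall outside [0.45, 0.55] purely by sampling noise.
  Tightening that spread materially requires a validation set several times
  larger. The calibration itself is clean: the mean null AUC across seeds is
  0.50, and the McNemar false-rejection rate for the k = 1 model versus the
  full model sits at ~3–7% at α = 0.05 (slightly conservative, as expected
  of the continuity-corrected test).
* The two-universe comparison (`combined` vs `ados_only`) runs both analyses
  on the same subjects and the same validation split so the McNemar test
  between the full models is properly paired. Real cohorts often have the
  ADI-R only for a subset of children; `adi_missing_fraction` plus the
  complete-case policy reproduces that confound deliberately (the
  `ados_only` universe then analyzes more subjects than `combined`).

## Numerical and degenerate-input choices

* Complete-case policy: subjects missing any item of the active feature
  universe are dropped *before* splitting; the ensemble refuses missing
  values at fit/predict time rather than imputing silently.
* One-class inputs (after filtering, in a CV fold, or in AUC computation)
  raise `DegenerateInputError` with the failing stage or fold named.
* All seeds below 2³¹; every stochastic component (cohort draw, holdout
  split, fold shuffle, bootstraps, permutations) derives from explicit
  seeds, and per-(k, fold) ensemble seeds are derived arithmetically so the
  whole `SelectionReport` serializes byte-identically across reruns.
* `round`-based per-class holdout counts use banker's rounding (so 250 per
  group gives a 124-subject holdout, 62 per class).
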