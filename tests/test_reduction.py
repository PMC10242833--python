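"""Split plans, complexity/weighted scoring, and the selection procedure."""

import numpy as np
import pytest

from itemforest import (
    DegenerateInputError,
    RFConfig,
    SelectionConfig,
    ValidationError,
    complexity,
    default_cohort_spec,
    evaluate_reduced_model,
    generate_cohort,
    make_split,
    select_models,
)
from itemforest import rf as rf_mod


def _small_config(seed=7, run_cv=False, **kw):
    return SelectionConfig(
        rf=RFConfig(n_trees=30, importance_repeats=2, seed=seed),
        run_cv=run_cv,
        **kw,
    )


@pytest.fixture(scope="module")
def cohort_200():
    """100 + 100 subjects, 12 items: the split-arithmetic example cohort."""
    return generate_cohort(
        default_cohort_spec(seed=17, n_per_group=100, n_informative=4,
                            n_ados=7, n_adi=5)
    )


@pytest.fixture(scope="module")
def small_report(small_cohort):
    m, lab = small_cohort
    plan = make_split(m, lab, seed=5)
    return select_models(m, lab, plan, _small_config(seed=5, run_cv=True))


class TestMakeSplit:
    def test_validation_counts_per_class(self, cohort_200):
        m, lab = cohort_200
        plan = make_split(m, lab, seed=1)
        assert len(plan.validation_ids) == 50
        val_asd = lab.is_asd(plan.validation_ids)
        assert val_asd.sum() == 25 and (~val_asd).sum() == 25

    def test_fold_test_sizes_are_five_percent(self, cohort_200):
        m, lab = cohort_200
        plan = make_split(m, lab, seed=1)
        assert len(plan.development_ids) == 150
        sizes = {len(test) for _, test in plan.folds}
        assert sizes <= {7, 8}
        assert len(plan.folds) == 20

    def test_folds_partition_development(self, cohort_200):
        m, lab = cohort_200
        plan = make_split(m, lab, seed=2)
        seen = [s for _, test in plan.folds for s in test]
        assert sorted(seen) == sorted(plan.development_ids)
        for train, test in plan.folds:
            assert set(train) | set(test) == set(plan.development_ids)
            assert not set(train) & set(test)

    def test_same_seed_identical_plans(self, cohort_200):
        m, lab = cohort_200
        p1, p2 = make_split(m, lab, seed=9), make_split(m, lab, seed=9)
        assert p1.development_ids == p2.development_ids
        assert p1.validation_ids == p2.validation_ids
        assert p1.folds == p2.folds

    def test_holdout_disjoint_from_all_folds(self, cohort_200):
        m, lab = cohort_200
        plan = make_split(m, lab, seed=3)
        val = set(plan.validation_ids)
        assert not val & set(plan.development_ids)
        for train, test in plan.folds:
            assert not val & set(train)
            assert not val & set(test)
        plan.audit()  # raises on any violation

    def test_too_small_class_errors(self):
        m, lab = generate_cohort(
            default_cohort_spec(seed=0, n_per_group=10, n_ados=3, n_adi=2,
                                n_informative=0)
        )
        with pytest.raises(DegenerateInputError, match="folds"):
            make_split(m, lab, seed=0)


class TestComplexity:
    def test_linear_inverse_boundaries(self):
        assert complexity(1, 66) == 1.0
        assert complexity(66, 66) == 0.0

    def test_linear_inverse_example(self):
        assert complexity(18, 66) == pytest.approx(1 - 17 / 65)

    def test_rank_based_range_and_monotonicity(self):
        vals = [complexity(k, 10, "rank_based") for k in range(1, 11)]
        assert vals[0] == pytest.approx(0.9)
        assert vals[-1] == 0.0
        assert np.all(np.diff(vals) < 0)

    def test_strictly_decreasing_in_k(self):
        for norm in ("linear_inverse", "rank_based"):
            vals = [complexity(k, 30, norm) for k in range(1, 31)]
            assert np.all(np.diff(vals) < 0)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            complexity(0, 10)
        with pytest.raises(ValidationError):
            complexity(11, 10)
        with pytest.raises(ValidationError):
            complexity(1, 1)
        with pytest.raises(ValidationError):
            complexity(1, 10, "bogus")


class TestWeightedScore:
    def test_matches_closed_form_example(self):
        # AUC_val = 0.86, k = 18 of N = 66 under linear_inverse:
        # 0.35 * 0.86 + 0.65 * (1 - 17/65) = 0.781.
        score = 0.35 * 0.86 + 0.65 * complexity(18, 66)
        assert score == pytest.approx(0.781, abs=5e-4)

    def test_report_scores_obey_formula(self, small_report):
        cfg = small_report.config
        n = small_report.n_features
        for k, ev in small_report.evaluations.items():
            expected = cfg.w1 * ev.validation_summary.auc + cfg.w2 * complexity(
                k, n, cfg.complexity_normalization
            )
            assert ev.weighted_score == pytest.approx(expected)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="w1"):
            SelectionConfig(w1=0.5, w2=0.6).validate()


class TestSelectModels:
    def test_prefix_nesting_across_k(self, small_report):
        ks = sorted(small_report.evaluations)
        for k_small, k_big in zip(ks, ks[1:]):
            small = set(small_report.evaluations[k_small].feature_ids)
            big = set(small_report.evaluations[k_big].feature_ids)
            assert small < big
        for k, ev in small_report.evaluations.items():
            assert ev.feature_ids == small_report.ranking.item_ids[:k]

    def test_full_model_mcnemar_is_identity(self, small_report):
        r = small_report.mcnemar_vs_full[small_report.n_features]
        assert (r.b, r.c, r.statistic, r.p_value) == (0, 0, 0.0, 1.0)

    def test_optimal_maximizes_weighted_score_ties_to_smaller_k(self, small_report):
        best = max(ev.weighted_score for ev in small_report.evaluations.values())
        opt = small_report.evaluations[small_report.optimal_k]
        assert opt.weighted_score == best
        for k, ev in small_report.evaluations.items():
            if ev.weighted_score == best:
                assert small_report.optimal_k <= k

    def test_minimal_is_smallest_equivalent_k(self, small_report):
        alpha = small_report.config.alpha
        ks = sorted(small_report.evaluations)
        expected = next(
            k for k in ks if small_report.mcnemar_vs_full[k].p_value >= alpha
        )
        assert small_report.minimal_k == expected

    def test_validation_predictions_cover_holdout_exactly(self, small_report):
        for ev in small_report.evaluations.values():
            assert sorted(ev.validation_predictions) == sorted(
                small_report.plan.validation_ids
            )

    def test_ranking_ignores_validation_subjects(self, small_cohort):
        """Scrambling the holdout subjects' codes must not change the ranking."""
        m, lab = small_cohort
        plan = make_split(m, lab, seed=11)
        cfg = _small_config(seed=11)
        rep1 = select_models(m, lab, plan, cfg, ks=[1, m.n_items])
        rng = np.random.default_rng(0)
        codes = m.codes.copy()
        val_rows = [m.subject_ids.index(s) for s in plan.validation_ids]
        for i in val_rows:
            codes[i] = rng.permutation(codes[i])
        m2 = type(m)(m.subject_ids, m.item_ids, codes, m.item_meta)
        rep2 = select_models(m2, lab, plan, cfg, ks=[1, m.n_items])
        assert rep1.ranking.item_ids == rep2.ranking.item_ids
        np.testing.assert_array_equal(
            rep1.ranking.importances, rep2.ranking.importances
        )

    def test_cv_mean_is_fold_average(self, small_cohort):
        m, lab = small_cohort
        plan = make_split(m, lab, seed=3)
        cfg = _small_config(seed=3, run_cv=True)
        ranking = rf_mod.importance(
            m.subset(subject_ids=plan.development_ids),
            lab.subset(plan.development_ids),
            m.item_ids,
            cfg.rf,
        )
        ev = evaluate_reduced_model(m, lab, ranking, 4, plan, cfg)
        assert ev.test_summary is not None
        assert ev.test_summary.n == len(plan.development_ids)
        assert 0 <= ev.test_summary.auc <= 1

    def test_k_equal_n_uses_all_items(self, small_report):
        full = small_report.evaluations[small_report.n_features]
        assert sorted(full.feature_ids) == sorted(small_report.ranking.item_ids)

    def test_informative_prefix_close_to_full_auc(self, small_cohort):
        m, lab = small_cohort
        plan = make_split(m, lab, seed=19)
        rep = select_models(
            m, lab, plan, _small_config(seed=19), ks=[4, m.n_items]
        )
        gap = abs(
            rep.evaluations[4].validation_summary.auc
            - rep.full.validation_summary.auc
        )
        assert gap < 0.15

    def test_serialization_roundtrip_is_deterministic(self, small_cohort):
        m, lab = small_cohort
        plan = make_split(m, lab, seed=23)
        cfg = _small_config(seed=23, run_cv=True)
        r1 = select_models(m, lab, plan, cfg, ks=[2, 5, m.n_items])
        r2 = select_models(m, lab, plan, cfg, ks=[2, 5, m.n_items])
        assert r1.to_json() == r2.to_json()

    def test_metrics_table_has_three_model_rows(self, small_report):
        table = small_report.metrics_table()
        assert list(table["model"]) == ["full", "optimal", "minimal"]
        assert {"auc_val", "acc_val", "mcnemar_p_vs_full"} <= set(table.columns)
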