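"""Orchestration: config -> cohort -> complete-case filter -> split -> reports.

Two feature universes mirror the paired analyses of interest for diagnostic
instruments: ``combined`` (all ADOS + ADI-R items) and ``ados_only``. A run
writes a report JSON, Table-style CSVs (metrics, ranked items, AUC-vs-k
curve) and a manifest recording the config hash, seed, library versions and
subject counts, so any run can be reproduced byte-for-byte.

``compare_universes`` evaluates both universes on one shared validation
split (complete cases of the combined universe), making the comparison
paired, and adds a McNemar test between the two full models.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import sklearn

from . import __version__
from .data import (
    CohortLabels,
    Instrument,
    ItemMatrix,
    ValidationError,
    config_to_dict,
    read_labels,
    read_matrix,
)
from .metrics import mcnemar
from .reduction import SelectionConfig, SelectionReport, make_split, select_models
from .synthetic import CohortSpec, generate_cohort

__all__ = ["RunConfig", "run", "compare_universes", "universe_items"]

log = logging.getLogger("itemforest")

UNIVERSES = ("combined", "ados_only")


@dataclass
class RunConfig:
    """One pipeline run. Exactly one of (input paths, cohort_spec) is set."""

    out_dir: str | Path
    seed: int = 0
    feature_universe: str = "combined"
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    cohort_spec: CohortSpec | None = None
    matrix_path: str | Path | None = None
    meta_path: str | Path | None = None
    labels_path: str | Path | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        from_files = self.matrix_path is not None
        if from_files == (self.cohort_spec is not None):
            raise ValidationError(
                "exactly one of (matrix_path [+ meta/labels paths], cohort_spec) "
                "must be provided"
            )
        if from_files and (self.meta_path is None or self.labels_path is None):
            raise ValidationError("matrix_path requires meta_path and labels_path")
        if self.feature_universe not in UNIVERSES:
            raise ValidationError(
                f"feature_universe must be one of {UNIVERSES}, "
                f"got {self.feature_universe!r}"
            )
        self.selection.validate()

    def config_hash(self) -> str:
        """Hash of the scientific configuration (where outputs go and how
        verbosely we log do not change the analysis)."""
        payload = config_to_dict(self)
        payload.pop("out_dir", None)
        payload.pop("log_level", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def universe_items(matrix: ItemMatrix, universe: str) -> list[str]:
    """Item ids forming the requested feature universe."""
    if universe == "combined":
        return list(matrix.item_ids)
    if universe == "ados_only":
        items = matrix.items_for(Instrument.ADOS)
        if not items:
            raise ValidationError("no ADOS-instrument items in the matrix metadata")
        return items
    raise ValidationError(f"unknown feature universe {universe!r}")


def _load(config: RunConfig) -> tuple[ItemMatrix, CohortLabels]:
    if config.cohort_spec is not None:
        return generate_cohort(config.cohort_spec)
    matrix = read_matrix(config.matrix_path, config.meta_path)
    labels = read_labels(config.labels_path)
    labels.validate_against(matrix.subject_ids)
    return matrix, labels


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def _manifest(
    config: RunConfig,
    n_total: int,
    n_kept: int,
    plan_seed: int,
    elapsed: float,
) -> dict:
    return {
        "config": config_to_dict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "plan_seed": plan_seed,
        "n_subjects_loaded": n_total,
        "n_subjects_analyzed": n_kept,
        "n_subjects_dropped": n_total - n_kept,
        "versions": {
            "itemforest": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "sklearn": sklearn.__version__,
        },
        "elapsed_seconds": round(elapsed, 2),
    }


def _persist(report: SelectionReport, out: Path, config_hash: str, prefix: str = "") -> None:
    (out / f"{prefix}report.json").write_text(report.to_json())
    _write_csv(report.metrics_table(), out / f"{prefix}metrics_table.csv", config_hash)
    _write_csv(report.ranked_items(), out / f"{prefix}ranking.csv", config_hash)
    _write_csv(report.auc_curve(), out / f"{prefix}auc_vs_k.csv", config_hash)


def run(config: RunConfig) -> SelectionReport:
    """Execute one universe end-to-end and persist all outputs."""
    t0 = time.time()
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, labels = _load(config)
    n_total = matrix.n_subjects
    items = universe_items(matrix, config.feature_universe)
    kept = matrix.complete_case_ids(items)
    if len(kept) < n_total:
        log.info(
            "complete-case filter (%s): kept %d of %d subjects",
            config.feature_universe, len(kept), n_total,
        )
    analysis_matrix = matrix.subset(subject_ids=kept, item_ids=items)
    analysis_labels = labels.subset(kept)
    plan = make_split(
        analysis_matrix,
        analysis_labels,
        config.seed,
        validation_fraction=config.selection.validation_fraction,
        n_folds=config.selection.n_folds,
    )
    log.info(
        "split: %d development / %d validation subjects, %d folds",
        len(plan.development_ids), len(plan.validation_ids), len(plan.folds),
    )
    report = select_models(analysis_matrix, analysis_labels, plan, config.selection)
    log.info(
        "selection: N=%d items, optimal k=%d, minimal k=%s",
        report.n_features, report.optimal_k, report.minimal_k,
    )
    config_hash = config.config_hash()
    _persist(report, out, config_hash)
    manifest = _manifest(config, n_total, len(kept), plan.seed, time.time() - t0)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return report


def compare_universes(config: RunConfig) -> dict[str, SelectionReport]:
    """Run combined and ADOS-only universes on one shared validation split.

    Subjects are the complete cases of the *combined* universe for both runs,
    so the two full models are evaluated on identical validation subjects and
    can be compared with McNemar's test. Outputs get a ``combined_`` /
    ``ados_only_`` prefix plus a side-by-side comparison table.
    """
    t0 = time.time()
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, labels = _load(config)
    n_total = matrix.n_subjects
    combined_items = universe_items(matrix, "combined")
    kept = matrix.complete_case_ids(combined_items)
    config_hash = config.config_hash()
    reports: dict[str, SelectionReport] = {}
    plan = None
    for universe in UNIVERSES:
        items = universe_items(matrix, universe)
        analysis_matrix = matrix.subset(subject_ids=kept, item_ids=items)
        analysis_labels = labels.subset(kept)
        if plan is None:
            plan = make_split(
                analysis_matrix,
                analysis_labels,
                config.seed,
                validation_fraction=config.selection.validation_fraction,
                n_folds=config.selection.n_folds,
            )
        report = select_models(analysis_matrix, analysis_labels, plan, config.selection)
        _persist(report, out, config_hash, prefix=f"{universe}_")
        reports[universe] = report
        log.info(
            "%s: N=%d items, optimal k=%d, minimal k=%s, full-model val AUC %.3f",
            universe, report.n_features, report.optimal_k, report.minimal_k,
            report.full.validation_summary.auc,
        )
    val_labels = labels.subset(plan.validation_ids)
    full_vs_full = mcnemar(
        val_labels,
        reports["combined"].full.validation_predictions,
        reports["ados_only"].full.validation_predictions,
        config.selection.mcnemar_method,
    )
    rows = []
    for universe, report in reports.items():
        table = report.metrics_table()
        table.insert(0, "universe", universe)
        rows.append(table)
    comparison = pd.concat(rows, ignore_index=True)
    _write_csv(comparison, out / "comparison_table.csv", config_hash)
    summary = {
        "mcnemar_full_combined_vs_full_ados_only": full_vs_full.to_dict(),
        "validation_ids": plan.validation_ids,
        "optimal_k": {u: r.optimal_k for u, r in reports.items()},
        "minimal_k": {u: r.minimal_k for u, r in reports.items()},
        "full_model_validation_auc": {
            u: r.full.validation_summary.auc for u, r in reports.items()
        },
    }
    (out / "comparison.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    manifest = _manifest(config, n_total, len(kept), plan.seed, time.time() - t0)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return reports
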