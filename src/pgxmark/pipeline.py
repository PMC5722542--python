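"""End-to-end comparison of single-gene and multi-gene markers on two releases.

Per drug of the common panel: build the time-stamped split, threshold at the
training median, test every feature for association and pick the best marker,
CV-select and fit the random forest, evaluate both classifiers on training
and test sets (plus the forest's cross-validated MCC), and aggregate the
paired comparisons into a cohort summary.  Drugs with an empty test set, a
single-class training set or no testable feature are excluded from the
comparison and reported with a reason, never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import evaluation, multi_gene, partition, single_gene
from .evaluation import CohortSummary, DrugComparison, MetricSet, metric_set
from .io_gdsc import DatasetRelease
from .multi_gene import ForestConfig

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "export_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Knobs of a full pipeline run."""

    fdr: float = 0.2
    correction_mode: str = "bh"  # or "fixed"
    fixed_cutoff: float = single_gene.GDSC_FIXED_CUTOFF
    min_mutants: int = 3
    min_test_size: int = 1
    min_train_size: int = 2
    direction_aware: bool = False
    forest: ForestConfig = field(default_factory=ForestConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        forest_raw = raw.pop("forest", {})
        if "mtry_grid" in forest_raw and forest_raw["mtry_grid"] is not None:
            forest_raw["mtry_grid"] = tuple(forest_raw["mtry_grid"])
        return cls(forest=ForestConfig(**forest_raw), **raw)


@dataclass
class PipelineResult:
    comparisons: list[DrugComparison]
    summary: CohortSummary | None
    associations: pd.DataFrame
    excluded: pd.DataFrame  # drug_id, reason
    split_manifests: pd.DataFrame
    model_report: pd.DataFrame
    predictions: pd.DataFrame


def _evaluate_drug(
    drug_id: str,
    r1: DatasetRelease,
    r2: DatasetRelease,
    features1: pd.DataFrame,
    features2: pd.DataFrame,
    cfg: RunConfig,
    results_bucket: list,
) -> tuple[DrugComparison | None, str | None, dict]:
    """Full per-drug analysis; returns (comparison, exclusion_reason, artifacts)."""
    artifacts: dict = {}
    split = partition.build_time_stamped_split(r1, r2, drug_id)
    if split.n_train < cfg.min_train_size:
        return None, f"training set too small ({split.n_train})", artifacts
    if split.n_test < cfg.min_test_size:
        return None, f"test set too small ({split.n_test})", artifacts

    train_resp = r1.responses_for_drug(drug_id).loc[list(split.training_cell_lines)]
    test_resp = r2.responses_for_drug(drug_id).loc[list(split.test_cell_lines)]
    threshold = partition.compute_threshold(train_resp)
    y_train = partition.assign_labels(train_resp, threshold)
    y_test = partition.assign_labels(test_resp, threshold)
    artifacts["manifest"] = partition.split_manifest(split, train_resp, test_resp, threshold)
    if y_train.nunique() < 2:
        return None, "single-class training labels (constant responses)", artifacts

    # single-gene stage
    assoc = single_gene.associations_for_drug(
        drug_id, train_resp, features1, min_mutants=cfg.min_mutants
    )
    results_bucket.extend(assoc)
    marker = single_gene.select_best_marker(assoc)
    if marker is None:
        return None, "markerless drug (no testable feature)", artifacts

    pred_train_sg = single_gene.predict_single_gene(
        marker, features1, split.training_cell_lines, cfg.direction_aware
    )
    pred_test_sg = single_gene.predict_single_gene(
        marker, features2, split.test_cell_lines, cfg.direction_aware
    )
    # the marker makes no prediction when no evaluated cell line is mutant
    no_pred_test = not features2.loc[list(split.test_cell_lines), marker.feature_name].any()
    single_metrics: dict[str, MetricSet] = {
        "train": metric_set(y_train, pred_train_sg),
        "test": metric_set(y_test, pred_test_sg, no_prediction=bool(no_pred_test)),
    }

    # multi-gene stage
    seed = multi_gene.drug_seed(cfg.seed, drug_id)
    forest = multi_gene.fit_drug_forest(
        features1.loc[list(split.training_cell_lines)], y_train, cfg.forest, drug_id, seed
    )
    pred_train_mg, votes_train = multi_gene.predict_multi_gene(
        forest, features1, split.training_cell_lines
    )
    pred_test_mg, votes_test = multi_gene.predict_multi_gene(
        forest, features2, split.test_cell_lines
    )
    multi_metrics: dict[str, MetricSet] = {
        "train": metric_set(y_train, pred_train_mg),
        # pooled out-of-fold predictions at the chosen m_try
        "cv": metric_set(y_train, forest.oof_predictions),
        "test": metric_set(y_test, pred_test_mg),
    }

    drug_class = "unknown"
    if r1.drug_metadata is not None and drug_id in r1.drug_metadata.index:
        drug_class = str(r1.drug_metadata.loc[drug_id].get("drug_class", "unknown"))

    comparison = evaluation.compare_drug(
        drug_id,
        single_metrics,
        multi_metrics,
        y_test,
        drug_class=drug_class,
        best_marker=marker.feature_name,
        chosen_mtry=forest.chosen_mtry,
    )
    artifacts["model_report"] = {
        "drug_id": drug_id,
        "chosen_mtry": forest.chosen_mtry,
        "selection_metric": forest.selection_metric,
        "cv_score_per_mtry": ";".join(
            f"{m}:{s!r}" for m, s in sorted(forest.cv_score_per_mtry.items())
        ),
        "training_mcc": forest.training_mcc,
        "cv_mcc": forest.cv_mcc,
        "best_marker": marker.feature_name,
        "best_marker_p": marker.p_value,
    }
    pred_rows = []
    for role, cells, votes, labels in (
        ("train", split.training_cell_lines, votes_train, pred_train_mg),
        ("test", split.test_cell_lines, votes_test, pred_test_mg),
    ):
        for cell in cells:
            pred_rows.append(
                {
                    "drug_id": drug_id,
                    "cell_line_id": cell,
                    "role": role,
                    "vote_fraction": votes.loc[cell],
                    "predicted_label": "sensitive" if labels.loc[cell] else "resistant",
                }
            )
    artifacts["predictions"] = pd.DataFrame(pred_rows)
    return comparison, None, artifacts


def run_pipeline(r1: DatasetRelease, r2: DatasetRelease, cfg: RunConfig) -> PipelineResult:
    """Run the full per-drug comparison over the common panel of two releases."""
    drugs, features = partition.common_panel(r1, r2)
    features1 = r1.features[features]
    features2 = r2.features[features]
    logger.info("common panel: %d drugs, %d features", len(drugs), len(features))

    all_assoc: list[single_gene.AssociationResult] = []
    comparisons: list[DrugComparison] = []
    excluded: list[dict] = []
    manifests: list[pd.DataFrame] = []
    model_rows: list[dict] = []
    prediction_frames: list[pd.DataFrame] = []

    per_drug: list[tuple[str, DrugComparison | None, dict]] = []
    for drug_id in drugs:
        comparison, reason, artifacts = _evaluate_drug(
            drug_id, r1, r2, features1, features2, cfg, all_assoc
        )
        if "manifest" in artifacts:
            manifests.append(artifacts["manifest"])
        if reason is not None:
            logger.warning("drug %s excluded: %s", drug_id, reason)
            excluded.append({"drug_id": drug_id, "reason": reason})
            continue
        per_drug.append((drug_id, comparison, artifacts))
        model_rows.append(artifacts["model_report"])
        prediction_frames.append(artifacts["predictions"])
        comparisons.append(comparison)

    # multiple-testing correction runs over the full drug x feature family
    if all_assoc:
        single_gene.adjust_pvalues(
            all_assoc, mode=cfg.correction_mode, fdr=cfg.fdr, fixed_cutoff=cfg.fixed_cutoff
        )
    best_map = {c.drug_id: c.best_marker for c in comparisons}
    assoc_table = single_gene.association_table(all_assoc, best_map)

    summary = evaluation.summarize_cohort(comparisons) if len(comparisons) >= 2 else None
    return PipelineResult(
        comparisons=comparisons,
        summary=summary,
        associations=assoc_table,
        excluded=pd.DataFrame(excluded, columns=["drug_id", "reason"]),
        split_manifests=(
            pd.concat(manifests, ignore_index=True)
            if manifests
            else pd.DataFrame(columns=["drug_id", "cell_line_id", "role", "log_ic50", "label"])
        ),
        model_report=pd.DataFrame(model_rows),
        predictions=(
            pd.concat(prediction_frames, ignore_index=True)
            if prediction_frames
            else pd.DataFrame(
                columns=["drug_id", "cell_line_id", "role", "vote_fraction", "predicted_label"]
            )
        ),
    )


def export_pipeline(result: PipelineResult, out_dir: str | Path, plots: bool = False) -> dict:
    """Write every pipeline artifact (associations, splits, models, reports)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.associations.to_csv(out_dir / "associations.csv", index=False)
    result.excluded.to_csv(out_dir / "excluded_drugs.csv", index=False)
    result.split_manifests.to_csv(out_dir / "split_manifest.csv", index=False)
    result.model_report.to_csv(out_dir / "model_report.csv", index=False)
    result.predictions.to_csv(out_dir / "predictions.csv", index=False)
    paths = {}
    if result.summary is not None:
        paths = evaluation.export_reports(result.summary, result.comparisons, out_dir, plots)
    return paths
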