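"""Confusion-matrix metrics, paired per-drug comparisons and cohort summaries.

Positive instances are drug-sensitive cell lines.  The Matthews correlation
coefficient (MCC), precision (PR), recall (RC) and F1 follow the standard
formulas with explicit degenerate conventions:

* any zero factor in the MCC denominator gives MCC = 0 (the "no better than
  random" baseline);
* PR = 0 when nothing is predicted sensitive, RC = 0 when nothing is truly
  sensitive;
* F1 = 0 when PR + RC = 0;
* a drug whose marker cannot make any prediction on the evaluated set (no
  mutant cell line present) carries a ``no_prediction`` flag and is scored
  MCC = PR = 0 — flagged, never dropped.

Cohort summaries report per-metric win counts between the two marker types
(strict inequality, ties separate), the 2x2 sign breakdown of test MCCs,
mean/median metrics per model and data set, the overfitting gap (mean train
MCC minus mean test MCC), and two-tailed Spearman rank correlations of the
multi-gene test MCC against test-set class imbalance and test-set size.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "DrugComparison",
    "CohortSummary",
    "confusion",
    "mcc",
    "precision_recall",
    "f_score",
    "metric_set",
    "compare_drug",
    "summarize_cohort",
    "spearman_two_tailed",
    "export_reports",
]

logger = logging.getLogger(__name__)

MODELS = ("single_gene", "multi_gene")
DATASETS = ("train", "cv", "test")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    mcc: float
    precision: float
    recall: float
    f1: float
    no_prediction: bool = False


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Confusion counts from aligned boolean labels (True = sensitive)."""
    t = np.asarray(y_true, dtype=bool)
    p = np.asarray(y_pred, dtype=bool)
    if t.shape != p.shape:
        raise ValueError(f"label length mismatch: {t.shape} vs {p.shape}")
    return ConfusionMatrix(
        tp=int(np.sum(t & p)),
        tn=int(np.sum(~t & ~p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
    )


def mcc(cm: ConfusionMatrix, no_prediction: bool = False) -> float:
    """Matthews correlation coefficient; 0 on any zero denominator factor."""
    if no_prediction:
        return 0.0
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    denom = (tp + fn) * (fn + tn) * (tn + fp) * (fp + tp)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def precision_recall(cm: ConfusionMatrix, no_prediction: bool = False) -> tuple[float, float]:
    """(PR, RC) = (TP/(TP+FP), TP/(TP+FN)), each 0 on a zero denominator."""
    pr = 0.0 if (no_prediction or cm.tp + cm.fp == 0) else cm.tp / (cm.tp + cm.fp)
    rc = 0.0 if cm.tp + cm.fn == 0 else cm.tp / (cm.tp + cm.fn)
    return pr, rc


def f_score(precision: float, recall: float) -> float:
    """Equally-weighted harmonic mean of precision and recall; F1(0,0) = 0."""
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def metric_set(y_true, y_pred, no_prediction: bool = False) -> MetricSet:
    """All four metrics for one (labels, predictions) pair."""
    cm = confusion(y_true, y_pred)
    pr, rc = precision_recall(cm, no_prediction)
    return MetricSet(
        mcc=mcc(cm, no_prediction),
        precision=pr,
        recall=rc,
        f1=f_score(pr, rc),
        no_prediction=no_prediction,
    )


@dataclass
class DrugComparison:
    """Paired metrics of the two marker types for one drug.

    ``metrics`` maps (model, dataset) -> MetricSet over models single_gene /
    multi_gene and datasets train / cv / test (the single-gene marker has no
    cross-validation stage; its 'cv' slot may be absent).  Test imbalance is
    the signed count n_sensitive - n_resistant on the test set.
    """

    drug_id: str
    drug_class: str
    metrics: dict[tuple[str, str], MetricSet]
    test_imbalance: int
    test_size: int
    best_marker: str | None = None
    chosen_mtry: int | None = None

    def get(self, model: str, dataset: str) -> MetricSet | None:
        return self.metrics.get((model, dataset))


def compare_drug(
    drug_id: str,
    single_metrics: dict[str, MetricSet],
    multi_metrics: dict[str, MetricSet],
    test_labels,
    drug_class: str = "unknown",
    best_marker: str | None = None,
    chosen_mtry: int | None = None,
) -> DrugComparison:
    """Assemble the per-drug comparison record from both models' metric sets.

    ``single_metrics``/``multi_metrics`` map dataset name -> MetricSet; both
    models must have been evaluated on the identical test cell-line set whose
    boolean labels are passed as ``test_labels``.
    """
    labels = np.asarray(test_labels, dtype=bool)
    metrics: dict[tuple[str, str], MetricSet] = {}
    for dataset, ms in single_metrics.items():
        metrics[("single_gene", dataset)] = ms
    for dataset, ms in multi_metrics.items():
        metrics[("multi_gene", dataset)] = ms
    n_sens = int(labels.sum())
    return DrugComparison(
        drug_id=drug_id,
        drug_class=drug_class,
        metrics=metrics,
        test_imbalance=n_sens - (labels.size - n_sens),
        test_size=int(labels.size),
        best_marker=best_marker,
        chosen_mtry=chosen_mtry,
    )


def spearman_two_tailed(x, y) -> tuple[float | None, float | None]:
    """Spearman rho with a two-tailed p-value; exact enumeration below n = 10.

    Returns (None, None) when either variable has no rank variation (rho
    undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return None, None
    rho = float(stats.spearmanr(x, y).statistic)
    n = len(x)
    if n < 10:
        # exact permutation null of the rank correlation
        ry = stats.rankdata(y)
        rx = stats.rankdata(x)
        observed = abs(rho)
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = float(stats.spearmanr(rx, np.array(perm)).statistic)
            if abs(r) >= observed - 1e-12:
                count += 1
            total += 1
        return rho, count / total
    return rho, float(stats.spearmanr(x, y).pvalue)


@dataclass
class CohortSummary:
    """Cohort-level aggregate of the paired per-drug comparisons."""

    n_drugs: int
    win_counts: dict[str, dict[str, int]]  # metric -> {multi_wins, single_wins, ties}
    sign_table: dict[str, int]  # rf_pos_single_pos, rf_pos_single_nonpos, ...
    zero_mcc_ties: dict[str, int]  # exact-zero MCC counts per model
    mean_metrics: pd.DataFrame  # rows (model, dataset), cols metric means
    median_metrics: pd.DataFrame
    overfitting_gap: dict[str, float]  # model -> mean train MCC - mean test MCC
    spearman_imbalance: tuple[float | None, float | None]
    spearman_test_size: tuple[float | None, float | None]
    no_prediction_drugs: list[str] = field(default_factory=list)
    by_drug_class: pd.DataFrame | None = None


TEST_METRICS = ("mcc", "precision", "recall", "f1")


def summarize_cohort(comparisons: list[DrugComparison]) -> CohortSummary:
    """Aggregate paired comparisons into the cohort-level summary."""
    if len(comparisons) < 2:
        raise ValueError("need at least two drug comparisons to summarise a cohort")

    win_counts: dict[str, dict[str, int]] = {}
    for metric in TEST_METRICS:
        multi_w = single_w = ties = 0
        for c in comparisons:
            s = getattr(c.get("single_gene", "test"), metric)
            m = getattr(c.get("multi_gene", "test"), metric)
            if m > s:
                multi_w += 1
            elif s > m:
                single_w += 1
            else:
                ties += 1
        win_counts[metric] = {"multi_wins": multi_w, "single_wins": single_w, "ties": ties}

    # 2x2 sign breakdown of test MCCs; exact zeros fall in the non-positive cells
    sign_table = {
        "rf_pos_single_pos": 0,
        "rf_pos_single_nonpos": 0,
        "rf_nonpos_single_pos": 0,
        "rf_nonpos_single_nonpos": 0,
    }
    zero_ties = {"single_gene": 0, "multi_gene": 0}
    for c in comparisons:
        s = c.get("single_gene", "test").mcc
        m = c.get("multi_gene", "test").mcc
        key = ("rf_pos" if m > 0 else "rf_nonpos") + ("_single_pos" if s > 0 else "_single_nonpos")
        sign_table[key] += 1
        if s == 0:
            zero_ties["single_gene"] += 1
        if m == 0:
            zero_ties["multi_gene"] += 1

    rows = []
    for model in MODELS:
        for dataset in DATASETS:
            vals = {
                metric: [
                    getattr(c.get(model, dataset), metric)
                    for c in comparisons
                    if c.get(model, dataset) is not None
                ]
                for metric in TEST_METRICS
            }
            if not vals["mcc"]:
                continue
            rows.append(
                {
                    "model": model,
                    "dataset": dataset,
                    **{f"mean_{k}": float(np.mean(v)) for k, v in vals.items()},
                    **{f"median_{k}": float(np.median(v)) for k, v in vals.items()},
                    "n": len(vals["mcc"]),
                }
            )
    stat_table = pd.DataFrame(rows).set_index(["model", "dataset"])
    mean_metrics = stat_table[[c for c in stat_table.columns if c.startswith("mean_")]]
    median_metrics = stat_table[[c for c in stat_table.columns if c.startswith("median_")]]

    overfit = {}
    for model in MODELS:
        if (model, "train") in stat_table.index and (model, "test") in stat_table.index:
            overfit[model] = float(
                stat_table.loc[(model, "train"), "mean_mcc"]
                - stat_table.loc[(model, "test"), "mean_mcc"]
            )

    test_mcc_rf = [c.get("multi_gene", "test").mcc for c in comparisons]
    imbalance = [c.test_imbalance for c in comparisons]
    sizes = [c.test_size for c in comparisons]
    rho_imb = spearman_two_tailed(test_mcc_rf, imbalance)
    rho_size = spearman_two_tailed(test_mcc_rf, sizes)

    classes = sorted({c.drug_class for c in comparisons})
    strat_rows = []
    for cls in classes:
        sub = [c for c in comparisons if c.drug_class == cls]
        strat_rows.append(
            {
                "drug_class": cls,
                "n_drugs": len(sub),
                **{
                    f"{metric}_multi_wins": sum(
                        1
                        for c in sub
                        if getattr(c.get("multi_gene", "test"), metric)
                        > getattr(c.get("single_gene", "test"), metric)
                    )
                    for metric in TEST_METRICS
                },
            }
        )
    by_class = pd.DataFrame(strat_rows) if strat_rows else None

    return CohortSummary(
        n_drugs=len(comparisons),
        win_counts=win_counts,
        sign_table=sign_table,
        zero_mcc_ties=zero_ties,
        mean_metrics=mean_metrics,
        median_metrics=median_metrics,
        overfitting_gap=overfit,
        spearman_imbalance=rho_imb,
        spearman_test_size=rho_size,
        no_prediction_drugs=[
            c.drug_id
            for c in comparisons
            if c.get("single_gene", "test") is not None and c.get("single_gene", "test").no_prediction
        ],
        by_drug_class=by_class,
    )


def comparisons_table(comparisons: list[DrugComparison]) -> pd.DataFrame:
    """Long-form per-drug metrics table (one row per drug x model x dataset)."""
    rows = []
    for c in comparisons:
        for (model, dataset), ms in sorted(c.metrics.items()):
            rows.append(
                {
                    "drug_id": c.drug_id,
                    "drug_class": c.drug_class,
                    "model": model,
                    "dataset": dataset,
                    "mcc": ms.mcc,
                    "precision": ms.precision,
                    "recall": ms.recall,
                    "f1": ms.f1,
                    "no_prediction": ms.no_prediction,
                    "test_imbalance": c.test_imbalance,
                    "test_size": c.test_size,
                    "best_marker": c.best_marker if model == "single_gene" else "",
                    "chosen_mtry": c.chosen_mtry if model == "multi_gene" else "",
                }
            )
    return pd.DataFrame(rows)


def export_reports(
    summary: CohortSummary,
    comparisons: list[DrugComparison],
    out_dir: str | Path,
    plots: bool = False,
) -> dict[str, Path]:
    """Write per-drug metrics, sign breakdown and the cohort summary to disk."""
    if not comparisons:
        raise ValueError("no comparisons to export")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    per_drug = comparisons_table(comparisons)
    paths["per_drug_metrics"] = out_dir / "per_drug_metrics.csv"
    per_drug.to_csv(paths["per_drug_metrics"], index=False, float_format=None)

    sign = pd.DataFrame(
        [
            {"cell": k, "count": v}
            for k, v in summary.sign_table.items()
        ]
        + [{"cell": f"zero_mcc_{m}", "count": n} for m, n in summary.zero_mcc_ties.items()]
    )
    paths["sign_breakdown"] = out_dir / "sign_breakdown.csv"
    sign.to_csv(paths["sign_breakdown"], index=False)

    paths["summary"] = out_dir / "cohort_summary.txt"
    with open(paths["summary"], "w") as fh:
        fh.write(format_summary(summary))

    if plots:
        paths["plots"] = _paired_metric_plots(comparisons, out_dir)
    return paths


def format_summary(summary: CohortSummary) -> str:
    lines = [f"drugs compared: {summary.n_drugs}", ""]
    for metric, wc in summary.win_counts.items():
        lines.append(
            f"test-set {metric}: multi-gene better on {wc['multi_wins']}, "
            f"single-gene better on {wc['single_wins']}, ties {wc['ties']}"
        )
    lines.append("")
    lines.append("test MCC sign breakdown (rows RF, cols single-gene; zeros in non-positive):")
    st = summary.sign_table
    lines.append(f"  RF>0 : single>0 {st['rf_pos_single_pos']:4d}  single<=0 {st['rf_pos_single_nonpos']:4d}")
    lines.append(f"  RF<=0: single>0 {st['rf_nonpos_single_pos']:4d}  single<=0 {st['rf_nonpos_single_nonpos']:4d}")
    lines.append(f"  exact-zero MCC ties: {summary.zero_mcc_ties}")
    lines.append("")
    lines.append("mean metrics per model/dataset:")
    lines.append(summary.mean_metrics.to_string())
    lines.append("")
    lines.append("median metrics per model/dataset:")
    lines.append(summary.median_metrics.to_string())
    lines.append("")
    for model, gap in summary.overfitting_gap.items():
        lines.append(f"overfitting gap ({model}): mean train MCC - mean test MCC = {gap:.4f}")
    rho, p = summary.spearman_imbalance
    lines.append(
        "Spearman test-MCC vs class imbalance: "
        + ("not computable (constant ranks)" if rho is None else f"rho={rho:.4f}, p={p:.3g}")
    )
    rho, p = summary.spearman_test_size
    lines.append(
        "Spearman test-MCC vs test size: "
        + ("not computable (constant ranks)" if rho is None else f"rho={rho:.4f}, p={p:.3g}")
    )
    if summary.no_prediction_drugs:
        lines.append(
            f"drugs whose best marker was absent from the test set "
            f"({len(summary.no_prediction_drugs)}): {', '.join(summary.no_prediction_drugs)}"
        )
    if summary.by_drug_class is not None:
        lines.append("")
        lines.append("stratification by drug class (multi-gene test-set wins):")
        lines.append(summary.by_drug_class.to_string(index=False))
    return "\n".join(lines) + "\n"


def _paired_metric_plots(comparisons: list[DrugComparison], out_dir: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 4, figsize=(16, 4))
    colors = {"cytotoxic": "red", "targeted": "blue", "unknown": "grey"}
    for ax, metric in zip(axes, TEST_METRICS):
        xs = [c.get("single_gene", "test").__getattribute__(metric) for c in comparisons]
        ys = [c.get("multi_gene", "test").__getattribute__(metric) for c in comparisons]
        cs = [colors.get(c.drug_class, "grey") for c in comparisons]
        ax.scatter(xs, ys, c=cs, s=12, alpha=0.7)
        lim = (-1, 1) if metric == "mcc" else (0, 1)
        ax.plot(lim, lim, "k--", lw=0.5)
        ax.set_xlabel(f"single-gene test {metric}")
        ax.set_ylabel(f"multi-gene test {metric}")
        ax.set_xlim(lim)
        ax.set_ylim(lim)
    fig.tight_layout()
    path = out_dir / "paired_test_metrics.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
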