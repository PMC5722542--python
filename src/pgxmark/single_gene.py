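"""Per-drug drug-gene association testing and the single-gene classifier.

Each (drug, feature) association is scored on training data with a
pooled-variance two-group comparison of logIC50 between mutant and wild-type
cell lines (a two-sample t-test with equal variances, equivalent to one-way
ANOVA with two groups).  Associations with too few mutants are untestable and
carry p = 1.  Multiple-testing correction runs over the full drug x feature
family, either Benjamini-Hochberg at a target FDR or a fixed p-value cutoff
compatibility mode.

The best marker of a drug is the lowest-p association — retained even when
not significant, so the single-gene approach is evaluated at its best case.
As a classifier it predicts *sensitive* exactly for cell lines harbouring the
marker alteration; wild-type cell lines are predicted resistant.  An optional
direction-aware mode inverts the prediction for resistance-associated
markers, but is off by default because the mutant=>sensitive rule is the one
whose degenerate-case bookkeeping (zero mutants in the test set => zero
precision and MCC) the evaluation conventions assume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GDSC_FIXED_CUTOFF",
    "AssociationResult",
    "MarkerClassifier",
    "test_association",
    "associations_for_drug",
    "adjust_pvalues",
    "select_best_marker",
    "predict_single_gene",
]

logger = logging.getLogger(__name__)

#: adjusted significance cutoff published with the original association table
GDSC_FIXED_CUTOFF = 0.00840749

SENSITISING = "sensitising"
RESISTANCE = "resistance-associated"


@dataclass
class AssociationResult:
    drug_id: str
    feature_name: str
    p_value: float
    effect_direction: str  # sensitising | resistance-associated
    n_mutant: int
    n_wildtype: int
    mean_difference: float  # mutant mean - wild-type mean, log10 uM
    testable: bool
    adjusted_significant: bool = False


@dataclass(frozen=True)
class MarkerClassifier:
    """The single-feature classifier built from a drug's best association."""

    drug_id: str
    feature_name: str
    p_value: float
    effect_direction: str
    adjusted_significant: bool = False


def test_association(
    drug_id: str,
    feature_name: str,
    responses: np.ndarray,
    mutation_flags: np.ndarray,
    min_mutants: int = 3,
) -> AssociationResult:
    """Pooled-variance two-group test of logIC50 between mutant and WT cells.

    Features with fewer than ``min_mutants`` mutant cell lines (or fewer than
    ``min_mutants`` wild-type ones) are untestable and returned with p = 1.
    Zero variance in both groups with equal means also yields p = 1.
    """
    responses = np.asarray(responses, dtype=float)
    flags = np.asarray(mutation_flags)
    mut = responses[flags == 1]
    wt = responses[flags == 0]
    n_mut, n_wt = len(mut), len(wt)
    if n_mut < min_mutants or n_wt < min_mutants:
        return AssociationResult(
            drug_id, feature_name, 1.0, SENSITISING, n_mut, n_wt, 0.0, testable=False
        )
    diff = float(mut.mean() - wt.mean())
    direction = SENSITISING if diff < 0 else RESISTANCE
    tstat, p = stats.ttest_ind(mut, wt, equal_var=True)
    if not np.isfinite(p):  # zero variance in both groups
        p = 1.0 if diff == 0 else 0.0
    return AssociationResult(
        drug_id, feature_name, float(p), direction, n_mut, n_wt, diff, testable=True
    )


def associations_for_drug(
    drug_id: str,
    training_responses: pd.Series,
    features: pd.DataFrame,
    min_mutants: int = 3,
) -> list[AssociationResult]:
    """Test every feature of the panel against one drug's training responses."""
    cells = training_responses.index
    feats = features.loc[cells]
    responses = training_responses.to_numpy(dtype=float)
    return [
        test_association(drug_id, name, responses, feats[name].to_numpy(), min_mutants)
        for name in feats.columns
    ]


def adjust_pvalues(
    results: list[AssociationResult],
    mode: str = "bh",
    fdr: float = 0.2,
    fixed_cutoff: float = GDSC_FIXED_CUTOFF,
) -> list[AssociationResult]:
    """Set ``adjusted_significant`` flags over the full association family.

    ``mode='bh'`` applies Benjamini-Hochberg step-up at the given FDR;
    ``mode='fixed'`` compares each raw p-value to a fixed cutoff (the
    compatibility default being the published adjusted threshold 0.00840749).
    """
    if not results:
        raise ValueError("no association results to adjust")
    if mode == "bh":
        if not 0 < fdr < 1:
            raise ValueError(f"fdr must lie in (0, 1), got {fdr}")
        pvals = np.array([r.p_value for r in results])
        reject, *_ = multipletests(pvals, alpha=fdr, method="fdr_bh")
        for r, sig in zip(results, reject):
            r.adjusted_significant = bool(sig)
    elif mode == "fixed":
        for r in results:
            r.adjusted_significant = r.p_value <= fixed_cutoff
    else:
        raise ValueError(f"unknown correction mode {mode!r}")
    return results


def select_best_marker(results: list[AssociationResult]) -> MarkerClassifier | None:
    """Lowest-p association for a drug, significant or not.

    Ties on p-value break toward the larger absolute mean difference, then
    lexicographically by feature name.  Returns None (markerless drug) when
    no feature was testable.
    """
    testable = [r for r in results if r.testable]
    if not testable:
        return None
    best = min(testable, key=lambda r: (r.p_value, -abs(r.mean_difference), r.feature_name))
    return MarkerClassifier(
        drug_id=best.drug_id,
        feature_name=best.feature_name,
        p_value=best.p_value,
        effect_direction=best.effect_direction,
        adjusted_significant=best.adjusted_significant,
    )


def predict_single_gene(
    marker: MarkerClassifier,
    features: pd.DataFrame,
    cell_ids: "list[str] | tuple[str, ...]",
    direction_aware: bool = False,
) -> pd.Series:
    """Boolean predictions (True = sensitive) for the given cell lines.

    Default rule: predicted sensitive iff the cell line harbours the marker
    alteration, regardless of effect direction.  With ``direction_aware``,
    resistance-associated markers predict mutants resistant and WT sensitive.
    """
    if marker.feature_name not in features.columns:
        raise KeyError(f"marker feature {marker.feature_name!r} absent from feature matrix")
    flags = features.loc[list(cell_ids), marker.feature_name].astype(bool)
    if direction_aware and marker.effect_direction == RESISTANCE:
        flags = ~flags
    return flags.rename("predicted_sensitive")


def association_table(results: list[AssociationResult], best: dict[str, str]) -> pd.DataFrame:
    """Flat per-association table; ``best`` maps drug_id -> best feature name."""
    return pd.DataFrame(
        {
            "drug_id": [r.drug_id for r in results],
            "feature": [r.feature_name for r in results],
            "p_value": [r.p_value for r in results],
            "direction": [r.effect_direction for r in results],
            "n_mutant": [r.n_mutant for r in results],
            "n_wt": [r.n_wildtype for r in results],
            "mean_difference": [r.mean_difference for r in results],
            "testable": [r.testable for r in results],
            "adjusted_significant": [r.adjusted_significant for r in results],
            "is_best": [best.get(r.drug_id) == r.feature_name for r in results],
        }
    )
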