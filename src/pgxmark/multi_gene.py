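"""Per-drug multi-gene random-forest classifier with m_try selected by CV.

For each drug a family of random forests is trained on the binary feature
matrix, one per candidate value of m_try (the number of features considered
at each split).  The candidate with the best mean out-of-fold score under a
shared seeded 10-fold stratified cross-validation is selected (ties break
toward the smallest m_try), then refit on the full training set with the
configured number of trees (1000 by default).

Two selection metrics are available: ``cv_mcc`` (mean per-fold Matthews
correlation of hard class predictions; the default, since the whole
evaluation is MCC-based) and ``cv_rmse`` (root-mean-square error of the
sensitive-class vote fraction against the 0/1 label, minimised).

Prediction outputs both the sensitive-vote fraction and the hard label:
sensitive iff the vote fraction strictly exceeds the vote threshold (an
exact 0.5 is resistant).  Feature columns are aligned by name, so column
order never changes predictions.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .evaluation import confusion, mcc

__all__ = [
    "ForestConfig",
    "SelectedForest",
    "cross_validate_mtry",
    "train_forest",
    "fit_drug_forest",
    "predict_multi_gene",
    "drug_seed",
]

logger = logging.getLogger(__name__)


@dataclass
class ForestConfig:
    """Random-forest training controls.

    ``mtry_grid=None`` means every value 1..n_features.  ``n_trees`` defaults
    to 1000; tests and the acceptance analyses use smaller forests and a
    coarse grid to keep runtimes sensible (see docs/methods.md).
    """

    n_trees: int = 1000
    mtry_grid: tuple[int, ...] | None = None
    cv_folds: int = 10
    selection_metric: str = "cv_mcc"  # or "cv_rmse"
    vote_threshold: float = 0.5
    seed: int = 0
    refold_cap: int = 5

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.selection_metric not in ("cv_mcc", "cv_rmse"):
            raise ValueError(f"unknown selection metric {self.selection_metric!r}")

    def grid_for(self, n_features: int) -> tuple[int, ...]:
        grid = self.mtry_grid if self.mtry_grid is not None else tuple(range(1, n_features + 1))
        bad = [m for m in grid if not 1 <= m <= n_features]
        if bad:
            raise ValueError(f"m_try values {bad} outside [1, {n_features}]")
        return tuple(grid)


@dataclass
class SelectedForest:
    """A fitted per-drug forest with its CV selection record."""

    drug_id: str
    chosen_mtry: int
    cv_score_per_mtry: dict[int, float]
    model: RandomForestClassifier
    feature_names: list[str]
    training_mcc: float
    selection_metric: str = "cv_mcc"
    vote_threshold: float = 0.5
    cv_mcc: float | None = None  # mean per-fold MCC at the chosen m_try
    oof_predictions: np.ndarray | None = None  # pooled out-of-fold hard predictions


def drug_seed(cohort_seed: int, drug_id: str) -> int:
    """Stable per-drug seed independent of drug processing order."""
    return (int(cohort_seed) ^ zlib.crc32(drug_id.encode())) & 0x7FFFFFFF


def _make_forest(mtry: int, n_trees: int, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees, max_features=mtry, random_state=seed, n_jobs=1
    )


def _fold_indices(y: np.ndarray, config: ForestConfig, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified folds, refolded (new seed) if a fold lacks a class."""
    n_splits = min(config.cv_folds, int(y.sum()), int((~y).sum()))
    if n_splits < 2:
        raise ValueError("training set must contain at least two cell lines of each class")
    for attempt in range(config.refold_cap + 1):
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed + attempt)
        folds = list(skf.split(np.zeros(len(y)), y))
        ok = all(
            len(np.unique(y[tr])) == 2 and len(np.unique(y[te])) == 2 for tr, te in folds
        )
        if ok:
            if attempt:
                logger.info("refolded CV %d time(s) to keep both classes per fold", attempt)
            return folds
    raise RuntimeError("could not build folds containing both classes within the retry cap")


def cross_validate_mtry(
    features: pd.DataFrame,
    labels: pd.Series,
    config: ForestConfig,
    seed: int | None = None,
) -> tuple[dict[int, float], int, dict[int, float], dict[int, np.ndarray]]:
    """Mean out-of-fold score per m_try over shared folds; pick the winner.

    Returns ``(scores, chosen_mtry, cv_mcc_per_mtry, oof_predictions)``:
    scores follow the configured selection metric, ``cv_mcc_per_mtry`` is
    always the mean per-fold MCC (reported regardless of the selection
    metric), and ``oof_predictions`` holds the pooled out-of-fold hard
    predictions per m_try, aligned with ``labels``.  The same fold
    assignment is used for every grid point.
    """
    y = np.asarray(labels, dtype=bool)
    X = features.to_numpy()
    seed = config.seed if seed is None else seed
    folds = _fold_indices(y, config, seed)
    grid = config.grid_for(X.shape[1])

    scores: dict[int, float] = {}
    mcc_scores: dict[int, float] = {}
    oof: dict[int, np.ndarray] = {}
    for mtry in grid:
        fold_mcc: list[float] = []
        fold_rmse: list[float] = []
        pooled = np.zeros(len(y), dtype=bool)
        for k, (tr, te) in enumerate(folds):
            model = _make_forest(mtry, config.n_trees, seed + 1000 * k)
            model.fit(X[tr], y[tr])
            proba = model.predict_proba(X[te])[:, list(model.classes_).index(True)]
            pred = proba > config.vote_threshold
            pooled[te] = pred
            fold_mcc.append(mcc(confusion(y[te], pred)))
            fold_rmse.append(float(np.sqrt(np.mean((proba - y[te].astype(float)) ** 2))))
        mcc_scores[mtry] = float(np.mean(fold_mcc))
        oof[mtry] = pooled
        scores[mtry] = (
            mcc_scores[mtry] if config.selection_metric == "cv_mcc" else float(np.mean(fold_rmse))
        )

    better = max if config.selection_metric == "cv_mcc" else min
    best_score = better(scores.values())
    chosen = min(m for m, s in scores.items() if s == best_score)
    return scores, chosen, mcc_scores, oof


def train_forest(
    features: pd.DataFrame,
    labels: pd.Series,
    mtry: int,
    config: ForestConfig,
    drug_id: str = "",
    seed: int | None = None,
) -> SelectedForest:
    """Fit the final full-training-set forest at a fixed m_try."""
    y = np.asarray(labels, dtype=bool)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    seed = config.seed if seed is None else seed
    model = _make_forest(mtry, config.n_trees, seed)
    model.fit(features.to_numpy(), y)
    proba = model.predict_proba(features.to_numpy())[:, list(model.classes_).index(True)]
    train_pred = proba > config.vote_threshold
    return SelectedForest(
        drug_id=drug_id,
        chosen_mtry=mtry,
        cv_score_per_mtry={},
        model=model,
        feature_names=list(features.columns),
        training_mcc=mcc(confusion(y, train_pred)),
        selection_metric=config.selection_metric,
        vote_threshold=config.vote_threshold,
    )


def fit_drug_forest(
    features: pd.DataFrame,
    labels: pd.Series,
    config: ForestConfig,
    drug_id: str = "",
    seed: int | None = None,
) -> SelectedForest:
    """CV-select m_try, then refit on the full training set."""
    scores, chosen, mcc_scores, oof = cross_validate_mtry(features, labels, config, seed)
    forest = train_forest(features, labels, chosen, config, drug_id, seed)
    forest.cv_score_per_mtry = scores
    forest.cv_mcc = mcc_scores[chosen]
    forest.oof_predictions = oof[chosen]
    return forest


def predict_multi_gene(
    forest: SelectedForest,
    features: pd.DataFrame,
    cell_ids: "list[str] | tuple[str, ...]",
) -> tuple[pd.Series, pd.Series]:
    """(labels, vote fractions) for the given cell lines.

    Columns are aligned to the training feature order by name; missing or
    extra features raise with their names.  Sensitive iff the sensitive-vote
    fraction strictly exceeds the vote threshold.
    """
    missing = [f for f in forest.feature_names if f not in features.columns]
    extra = [f for f in features.columns if f not in forest.feature_names]
    if missing or extra:
        raise ValueError(f"feature mismatch: missing {missing}, unexpected {extra}")
    X = features.loc[list(cell_ids), forest.feature_names].to_numpy()
    proba = forest.model.predict_proba(X)[:, list(forest.model.classes_).index(True)]
    votes = pd.Series(proba, index=pd.Index(cell_ids, name="cell_line_id"), name="vote_fraction")
    labels = (votes > forest.vote_threshold).rename("predicted_sensitive")
    return labels, votes
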