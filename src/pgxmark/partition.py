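"""Time-stamped train/test splits and median-threshold class labels.

For each drug the training set is every cell line with a measured response in
the first release; the test set is every cell line measured in the second
release that is absent from the training set — a prospective, non-overlapping
partition by construction.  The sensitivity threshold is the median training
logIC50, reused unchanged on the test set; cell lines strictly below the
threshold are labelled sensitive, all others (including exact ties) resistant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_gdsc import DatasetRelease

__all__ = [
    "TimeStampedSplit",
    "common_panel",
    "build_time_stamped_split",
    "compute_threshold",
    "assign_labels",
    "split_manifest",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TimeStampedSplit:
    """Per-drug disjoint training and test cell-line sets."""

    drug_id: str
    training_cell_lines: tuple[str, ...]
    test_cell_lines: tuple[str, ...]

    def __post_init__(self) -> None:
        overlap = set(self.training_cell_lines) & set(self.test_cell_lines)
        if overlap:
            raise ValueError(
                f"drug {self.drug_id}: training/test overlap {sorted(overlap)[:5]}"
            )

    @property
    def n_train(self) -> int:
        return len(self.training_cell_lines)

    @property
    def n_test(self) -> int:
        return len(self.test_cell_lines)


def common_panel(r1: DatasetRelease, r2: DatasetRelease) -> tuple[list[str], list[str]]:
    """Drug ids and feature names present in both releases (sorted).

    All downstream stages are restricted to this shared panel.
    """
    drugs = sorted(set(r1.drug_ids) & set(r2.drug_ids))
    features = sorted(set(r1.feature_names) & set(r2.feature_names))
    if not drugs:
        raise ValueError("releases share no drugs")
    if not features:
        raise ValueError("releases share no features")
    return drugs, features


def build_time_stamped_split(
    r1: DatasetRelease, r2: DatasetRelease, drug_id: str
) -> TimeStampedSplit:
    """Training = measured in release 1; test = newly measured in release 2."""
    train = sorted(
        r1.responses.loc[r1.responses["drug_id"] == drug_id, "cell_line_id"].unique()
    )
    train_set = set(train)
    test = sorted(
        c
        for c in r2.responses.loc[r2.responses["drug_id"] == drug_id, "cell_line_id"].unique()
        if c not in train_set
    )
    return TimeStampedSplit(drug_id, tuple(train), tuple(test))


def compute_threshold(training_responses: "pd.Series | np.ndarray") -> float:
    """Median training logIC50 (even count: mean of the central pair)."""
    values = np.asarray(training_responses, dtype=float)
    if values.size == 0:
        raise ValueError("cannot compute a sensitivity threshold from zero responses")
    return float(np.median(values))


def assign_labels(responses: pd.Series, threshold: float) -> pd.Series:
    """Boolean labels (True = sensitive) for responses against a threshold.

    Sensitive means logIC50 strictly below the threshold; a value exactly at
    the threshold is resistant.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return responses < threshold


def split_manifest(
    split: TimeStampedSplit,
    train_responses: pd.Series,
    test_responses: pd.Series,
    threshold: float,
) -> pd.DataFrame:
    """Long-form per-cell-line manifest: role, logIC50 and class label."""
    frames = []
    for role, cells, resp in (
        ("train", split.training_cell_lines, train_responses),
        ("test", split.test_cell_lines, test_responses),
    ):
        resp = resp.reindex(list(cells))
        frames.append(
            pd.DataFrame(
                {
                    "drug_id": split.drug_id,
                    "cell_line_id": list(cells),
                    "role": role,
                    "log_ic50": resp.to_numpy(),
                    "label": np.where(assign_labels(resp, threshold), "sensitive", "resistant"),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
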