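"""Synthetic two-release pharmacogenomic cohorts with planted drivers.

Emulates the statistical structure the downstream comparison assumes: a panel
of sparse binary somatic-alteration features per cell line, per-drug logIC50
responses generated as an additive model over planted driver mutations plus
Gaussian noise, missing-at-random drug-cell coverage, and a second release
that keeps every first-release measurement while adding new cell lines.

Drugs come in three kinds: *single-driver* (one sensitising mutation with a
large effect), *multi-driver* (several mutations with smaller effects, the
regime where combining genes should pay off) and *null* (no genetic signal).
The planted configuration is returned as a :class:`GroundTruth` so recovery
can be scored exactly.

All randomness flows from one :class:`numpy.random.Generator` seeded from
``config.seed``, drawn in a fixed documented order (prevalences, mutations,
baselines, driver assignment, noise, coverage masks), so identical configs
give bit-identical releases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io_gdsc import DatasetRelease, DialectConfig, write_release

__all__ = ["GenerativeConfig", "GroundTruth", "generate_cohort", "summarize_ground_truth"]

FUSION_NAMES = ("BCR_ABL", "MLL_AFF1", "EWS_FLI1")
MSI_NAME = "msi"


@dataclass
class GenerativeConfig:
    """Cohort-level generative parameters.

    Defaults mirror the scale of the two public GDSC releases the pipeline
    targets: 638 cell lines growing to 708, 127 drugs, 71 binary features
    (genes + 3 fusions + msi), 57.6% / 80.68% measured drug-cell coverage.
    Effects are log10 uM shifts per driver mutation (negative = sensitising);
    noise_sd is the residual spread of logIC50 around the genetic mean.
    """

    n_cell_lines_release1: int = 638
    n_new_cell_lines_release2: int = 70
    n_features: int = 71
    n_drugs: int = 127
    prevalence_range: tuple[float, float] = (0.02, 0.3)
    drug_mix: tuple[float, float, float] = (0.4, 0.4, 0.2)  # single, multi, null
    drivers_per_multi_drug: int = 3
    effect_size: float = -1.0
    multi_driver_effect_size: float = -0.6
    noise_sd: float = 0.5
    coverage_release1: float = 0.576
    coverage_release2: float = 0.8068
    cytotoxic_fraction: float = 14 / 127
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.drug_mix) - 1.0) > 1e-9:
            raise ValueError("drug_mix fractions must sum to 1")
        if not (0 < self.coverage_release1 <= 1 and 0 < self.coverage_release2 <= 1):
            raise ValueError("coverage fractions must lie in (0, 1]")
        lo, hi = self.prevalence_range
        if not (0 < lo <= hi < 1):
            raise ValueError("prevalence_range must satisfy 0 < low <= high < 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_features < 5:
            raise ValueError("need at least 5 features (genes + fusions + msi)")
        if self.drivers_per_multi_drug > self.n_features - 1:
            raise ValueError("drivers_per_multi_drug exceeds the driver-eligible panel")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GenerativeConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("prevalence_range", "drug_mix"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class GroundTruth:
    """Planted configuration of a synthetic cohort.

    ``drivers`` maps drug_id -> {feature_name: effect size}; null drugs map
    to an empty dict.  ``drug_class`` carries the arbitrary cytotoxic/targeted
    labels used to exercise stratified reporting.
    """

    drivers: dict[str, dict[str, float]]
    drug_class: dict[str, str]
    drug_kind: dict[str, str] = field(default_factory=dict)  # single/multi/null

    def __post_init__(self) -> None:
        for drug, kind in self.drug_kind.items():
            if kind == "null" and self.drivers.get(drug):
                raise ValueError(f"null drug {drug} has planted drivers")


def _largest_remainder_counts(fractions: tuple[float, float, float], total: int) -> list[int]:
    """Deterministic integer allocation of `total` across fractions."""
    raw = [f * total for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    remainder = total - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def generate_cohort(
    config: GenerativeConfig,
) -> tuple[DatasetRelease, DatasetRelease, GroundTruth]:
    """Generate two releases over a shared feature panel plus the ground truth.

    Release 2 contains every release-1 cell line (with identical feature
    profiles and responses for retained pairs) plus new cell lines drawn
    from the same law; measured pairs are sampled uniformly at the per-release
    coverage rate, with release-1 pairs always retained in release 2.
    """
    rng = np.random.default_rng(config.seed)

    n1 = config.n_cell_lines_release1
    n_total = n1 + config.n_new_cell_lines_release2
    n_genes = config.n_features - len(FUSION_NAMES) - 1
    gene_names = [f"GENE{i + 1:03d}" for i in range(n_genes)]
    feature_names = gene_names + list(FUSION_NAMES) + [MSI_NAME]
    cell_ids = [f"CL{i + 1:04d}" for i in range(n_total)]
    drug_ids = [f"D{i + 1:03d}" for i in range(config.n_drugs)]

    # 1. per-feature prevalences, log-uniform over the configured range
    lo, hi = config.prevalence_range
    prevalence = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_features))
    # 2. mutation matrix: independent Bernoulli per (cell, feature)
    mutations = (rng.random((n_total, config.n_features)) < prevalence).astype(np.int8)
    features = pd.DataFrame(
        mutations, index=pd.Index(cell_ids, name="cell_line_id"), columns=feature_names
    )

    # 3. per-drug baseline logIC50
    baselines = rng.normal(0.0, 1.0, size=config.n_drugs)

    # 4. drug kinds (deterministic largest-remainder allocation) and drivers
    n_single, n_multi, n_null = _largest_remainder_counts(config.drug_mix, config.n_drugs)
    kinds = ["single"] * n_single + ["multi"] * n_multi + ["null"] * n_null
    eligible = [f for f in feature_names if f != MSI_NAME]
    drivers: dict[str, dict[str, float]] = {}
    for drug, kind in zip(drug_ids, kinds):
        if kind == "single":
            chosen = rng.choice(len(eligible), size=1, replace=False)
            drivers[drug] = {eligible[chosen[0]]: config.effect_size}
        elif kind == "multi":
            chosen = rng.choice(len(eligible), size=config.drivers_per_multi_drug, replace=False)
            drivers[drug] = {eligible[i]: config.multi_driver_effect_size for i in chosen}
        else:
            drivers[drug] = {}

    # 5. responses: baseline + additive driver effects + Gaussian noise
    effect_matrix = np.zeros((config.n_features, config.n_drugs))
    feat_index = {f: i for i, f in enumerate(feature_names)}
    for j, drug in enumerate(drug_ids):
        for feat, eff in drivers[drug].items():
            effect_matrix[feat_index[feat], j] = eff
    genetic = mutations @ effect_matrix  # (cells, drugs)
    noise = rng.normal(0.0, config.noise_sd, size=(n_total, config.n_drugs))
    log_ic50 = baselines[None, :] + genetic + noise

    # 6. coverage masks; release-1 measured pairs are always kept in release 2
    mask1 = rng.random((n1, config.n_drugs)) < config.coverage_release1
    mask2 = rng.random((n_total, config.n_drugs)) < config.coverage_release2
    mask2[:n1] |= mask1

    drug_class = {
        drug: ("cytotoxic" if (i * config.cytotoxic_fraction) % 1 < config.cytotoxic_fraction
               else "targeted")
        for i, drug in enumerate(drug_ids)
    }
    metadata = pd.DataFrame(
        {
            "drug_id": drug_ids,
            "name": [f"compound-{d}" for d in drug_ids],
            "drug_class": [drug_class[d] for d in drug_ids],
        }
    ).set_index("drug_id")

    dialect = DialectConfig(
        gene_columns=gene_names, fusion_columns=list(FUSION_NAMES), msi_column=MSI_NAME
    )

    def _release(tag: str, cells: slice, mask: np.ndarray) -> DatasetRelease:
        rows, cols = np.nonzero(mask)
        responses = pd.DataFrame(
            {
                "drug_id": [drug_ids[c] for c in cols],
                "cell_line_id": [cell_ids[r] for r in rows],
                "log_ic50": log_ic50[rows, cols],
            }
        )
        return DatasetRelease(
            tag=tag,
            features=features.iloc[cells].copy(),
            responses=responses,
            drug_metadata=metadata.copy(),
            dialect=dialect,
        )

    release1 = _release("release1", slice(0, n1), mask1)
    release2 = _release("release2", slice(0, n_total), mask2)
    truth = GroundTruth(
        drivers=drivers,
        drug_class=drug_class,
        drug_kind=dict(zip(drug_ids, kinds)),
    )
    return release1, release2, truth


def summarize_ground_truth(truth: GroundTruth) -> pd.DataFrame:
    """One row per drug listing its kind, class and planted drivers/effects."""
    rows = []
    for drug in sorted(truth.drivers):
        drv = truth.drivers[drug]
        rows.append(
            {
                "drug_id": drug,
                "kind": truth.drug_kind.get(drug, "unknown"),
                "drug_class": truth.drug_class.get(drug, "unknown"),
                "n_drivers": len(drv),
                "drivers": ";".join(sorted(drv)),
                "effects": ";".join(repr(drv[f]) for f in sorted(drv)),
            }
        )
    return pd.DataFrame(rows)


def write_cohort(
    config: GenerativeConfig, out_dir: str | Path
) -> tuple[DatasetRelease, DatasetRelease, GroundTruth]:
    """Generate a cohort and write release1/, release2/ and ground_truth.csv."""
    out_dir = Path(out_dir)
    r1, r2, truth = generate_cohort(config)
    write_release(r1, out_dir / "release1")
    write_release(r2, out_dir / "release2")
    summarize_ground_truth(truth).to_csv(out_dir / "ground_truth.csv", index=False)
    return r1, r2, truth
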