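import numpy as np
import pandas as pd
import pytest

from pgxmark import DatasetRelease, DialectConfig, GenerativeConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but non-trivial two-release cohort with planted drivers."""
    cfg = GenerativeConfig(
        n_cell_lines_release1=120,
        n_new_cell_lines_release2=60,
        n_drugs=12,
        n_features=20,
        prevalence_range=(0.08, 0.25),
        drug_mix=(0.5, 0.25, 0.25),
        coverage_release1=0.9,
        coverage_release2=0.95,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def tiny_release_pair():
    """Hand-built release pair: 1 drug, 4 train cells, 2 new test cells."""
    dialect = DialectConfig(gene_columns=["TP53", "MYCN"], fusion_columns=["BCR_ABL"])

    def release(tag, cells, flags, responses):
        features = pd.DataFrame(
            flags, index=pd.Index(cells, name="cell_line_id"),
            columns=["TP53", "MYCN", "BCR_ABL", "msi"],
        )
        resp = pd.DataFrame(
            [("d1", c, v) for c, v in responses.items()],
            columns=["drug_id", "cell_line_id", "log_ic50"],
        )
        return DatasetRelease(tag=tag, features=features, responses=resp, dialect=dialect)

    r1 = release(
        "release1",
        ["c1", "c2", "c3", "c4"],
        [[1, 0, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 0, 0]],
        {"c1": -2.0, "c2": -1.0, "c3": 1.0, "c4": 2.0},
    )
    r2 = release(
        "release2",
        ["c1", "c2", "c3", "c4", "c5", "c6"],
        [[1, 0, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 0, 0], [1, 0, 0, 0], [0, 0, 0, 1]],
        {"c1": -2.0, "c2": -1.0, "c3": 1.0, "c4": 2.0, "c5": -1.5, "c6": 1.5},
    )
    return r1, r2


def rng(seed=0):
    return np.random.default_rng(seed)
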