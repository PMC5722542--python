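"""Release-versioned pharmacogenomic data model and GDSC-dialect CSV I/O.

The GDSC mutation-annotation dialect encodes each gene/cell-line entry as an
``x::y`` token pair, where ``x`` is a coding-variant descriptor (``wt``/``na``
meaning no variant) and ``y`` is a copy-number descriptor whose wild-type form
is a literal token (default ``0<cna<8``).  Gene fusions carry a single token
(a not-detected vocabulary versus a fusion identifier), and microsatellite
instability (msi) is one extra binary column.  Drug responses are logIC50
values in log10 micromolar units; files on the natural-log scale are converted
on read (logIC50 = ln IC50 / ln 10, so logIC50 = 1 is 10 uM).

A :class:`DatasetRelease` bundles the parsed 0/1 feature matrix, the long-form
response table and optional per-drug metadata under a release tag, and
round-trips losslessly through :func:`write_release` / :func:`read_release`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LN10",
    "DialectConfig",
    "DatasetRelease",
    "GdscParseError",
    "parse_variant_annotation",
    "parse_fusion_status",
    "convert_ln_to_log10",
    "read_release",
    "write_release",
    "deduplicate_drugs",
]

logger = logging.getLogger(__name__)

LN10 = math.log(10.0)

#: tokens meaning "no coding variant" in the x slot, compared case-insensitively
_NO_VARIANT_TOKENS = frozenset({"wt", "na"})

DATA_FILENAME = "data.csv"
DIALECT_FILENAME = "dialect.yaml"
DRUG_METADATA_FILENAME = "drug_metadata.csv"

DRUG_CLASSES = ("cytotoxic", "targeted", "unknown")


class GdscParseError(ValueError):
    """Malformed content in a GDSC-dialect file, with row/column location."""


@dataclass
class DialectConfig:
    """Column layout and token vocabulary of a GDSC-dialect CSV.

    The exact header of the source files is never assumed; it is declared
    here so the same reader consumes both real exports and synthetic
    fixtures.
    """

    cell_line_column: str = "cell_line"
    gene_columns: list[str] = field(default_factory=list)
    fusion_columns: list[str] = field(default_factory=list)
    msi_column: str | None = "msi"
    drug_column_prefix: str = "IC50_"
    response_scale: str = "log10"  # "ln" or "log10"
    wt_copy_number_token: str = "0<cna<8"
    fusion_not_detected_tokens: tuple[str, ...] = (
        "wt",
        "na",
        "nd",
        "0",
        "fusion not-detected",
        "not-detected",
    )
    msi_positive_tokens: tuple[str, ...] = ("1", "msi", "msi-h", "unstable")

    def __post_init__(self) -> None:
        if self.response_scale not in ("ln", "log10"):
            raise ValueError(f"response_scale must be 'ln' or 'log10', got {self.response_scale!r}")

    @property
    def feature_names(self) -> list[str]:
        names = list(self.gene_columns) + list(self.fusion_columns)
        if self.msi_column is not None:
            names.append(self.msi_column)
        return names

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DialectConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("fusion_not_detected_tokens", "msi_positive_tokens"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "cell_line_column": self.cell_line_column,
            "gene_columns": list(self.gene_columns),
            "fusion_columns": list(self.fusion_columns),
            "msi_column": self.msi_column,
            "drug_column_prefix": self.drug_column_prefix,
            "response_scale": self.response_scale,
            "wt_copy_number_token": self.wt_copy_number_token,
            "fusion_not_detected_tokens": list(self.fusion_not_detected_tokens),
            "msi_positive_tokens": list(self.msi_positive_tokens),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class DatasetRelease:
    """A release-tagged bundle of genomic features and drug responses.

    Attributes
    ----------
    tag
        Release label (e.g. ``"release1"``).
    features
        0/1 DataFrame indexed by cell-line id, one column per binary genomic
        feature (gene alterations, fusions, msi).  No missing entries.
    responses
        Long-form table with columns ``drug_id``, ``cell_line_id``,
        ``log_ic50`` (log10 uM); at most one row per (drug, cell line) pair,
        and absence of a row means the pair was not measured.
    drug_metadata
        Optional DataFrame indexed by drug_id with columns ``name`` and
        ``drug_class`` (cytotoxic / targeted / unknown).
    dialect
        The dialect the release was read with (or should be written with).
    """

    tag: str
    features: pd.DataFrame
    responses: pd.DataFrame
    drug_metadata: pd.DataFrame | None = None
    dialect: DialectConfig | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        feats = self.features
        if feats.index.has_duplicates:
            raise ValueError(f"[{self.tag}] duplicate cell line ids in feature matrix")
        if feats.columns.has_duplicates:
            raise ValueError(f"[{self.tag}] duplicate feature names")
        values = feats.to_numpy()
        if values.size and not np.isin(values, (0, 1)).all():
            raise ValueError(f"[{self.tag}] feature matrix entries must be 0/1 with no gaps")
        resp = self.responses
        required = {"drug_id", "cell_line_id", "log_ic50"}
        if not required.issubset(resp.columns):
            raise ValueError(f"[{self.tag}] responses must have columns {sorted(required)}")
        if resp.duplicated(["drug_id", "cell_line_id"]).any():
            dup = resp[resp.duplicated(["drug_id", "cell_line_id"])].iloc[0]
            raise GdscParseError(
                f"[{self.tag}] duplicate response record for drug "
                f"{dup['drug_id']!r}, cell line {dup['cell_line_id']!r}"
            )
        if len(resp) and not np.isfinite(resp["log_ic50"].to_numpy(dtype=float)).all():
            raise ValueError(f"[{self.tag}] non-finite log_ic50 values")
        missing = set(resp["cell_line_id"]) - set(feats.index)
        if missing:
            raise ValueError(
                f"[{self.tag}] cell lines with responses but no features: {sorted(missing)[:5]}"
            )

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.features.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def drug_ids(self) -> list[str]:
        return sorted(self.responses["drug_id"].unique())

    def responses_for_drug(self, drug_id: str) -> pd.Series:
        """logIC50 values for one drug as a Series indexed by cell line."""
        sub = self.responses[self.responses["drug_id"] == drug_id]
        return pd.Series(
            sub["log_ic50"].to_numpy(), index=pd.Index(sub["cell_line_id"], name="cell_line_id")
        )


def parse_variant_annotation(
    coding_variant: str, copy_number: str, wt_copy_number_token: str = "0<cna<8"
) -> int:
    """Binary mutation flag from an ``x::y`` annotation pair.

    Returns 1 iff a coding variant is present (``x`` not in {wt, na},
    case-insensitively) or the copy-number token differs from the wild-type
    token; 0 otherwise.  Tokens are whitespace-trimmed; comparison is
    case-insensitive.
    """
    x = coding_variant.strip()
    y = copy_number.strip()
    if not x or not y:
        raise GdscParseError(f"empty annotation token in {coding_variant!r}::{copy_number!r}")
    if x.lower() not in _NO_VARIANT_TOKENS:
        return 1
    if y.lower() != wt_copy_number_token.strip().lower():
        return 1
    return 0


def _split_annotation(raw: str) -> tuple[str, str]:
    if "::" not in raw:
        raise GdscParseError(f"annotation {raw!r} lacks the '::' separator")
    x, _, y = raw.partition("::")
    return x, y


def parse_fusion_status(
    token: str,
    not_detected_tokens: tuple[str, ...] = DialectConfig.fusion_not_detected_tokens,
) -> int:
    """Binary flag for a gene-fusion column: 0 if not detected, else 1.

    Unknown tokens count as detected (the file names the identified fusion,
    e.g. ``BCR_ABL``) and are logged rather than rejected.
    """
    tok = token.strip()
    if not tok:
        raise GdscParseError("empty fusion token")
    vocab = {t.strip().lower() for t in not_detected_tokens}
    if tok.lower() in vocab:
        return 0
    if tok.lower() not in {"1", "mut", "mutated"}:
        logger.debug("fusion token %r not in not-detected vocabulary; counting as detected", tok)
    return 1


def convert_ln_to_log10(value: float) -> float:
    """Convert a natural-log uM concentration to log10 uM (divide by ln 10)."""
    if not math.isfinite(value):
        raise ValueError(f"non-finite logIC50 value: {value!r}")
    return value / LN10


def _parse_msi(token: str, positive_tokens: tuple[str, ...]) -> int:
    tok = str(token).strip().lower()
    vocab = {t.strip().lower() for t in positive_tokens}
    return 1 if tok in vocab else 0


def read_release(
    path: str | Path,
    dialect: DialectConfig | None = None,
    tag: str | None = None,
) -> DatasetRelease:
    """Read a GDSC-dialect release from a CSV file or a release directory.

    ``path`` may be a directory (holding ``data.csv``, ``dialect.yaml`` and
    optionally ``drug_metadata.csv``, as produced by :func:`write_release`)
    or a bare CSV file, in which case ``dialect`` must be given.
    """
    path = Path(path)
    metadata = None
    if path.is_dir():
        if dialect is None:
            dialect = DialectConfig.from_yaml(path / DIALECT_FILENAME)
        meta_path = path / DRUG_METADATA_FILENAME
        if meta_path.exists():
            metadata = pd.read_csv(meta_path, dtype={"drug_id": str}).set_index("drug_id")
        csv_path = path / DATA_FILENAME
        if tag is None:
            tag = path.name
    else:
        csv_path = path
        if tag is None:
            tag = path.stem
    if dialect is None:
        raise ValueError("a DialectConfig is required when reading a bare CSV file")

    table = pd.read_csv(csv_path, dtype=str, keep_default_na=False)
    known = {dialect.cell_line_column, *dialect.gene_columns, *dialect.fusion_columns}
    if dialect.msi_column is not None:
        known.add(dialect.msi_column)
    unknown = [
        c for c in table.columns if c not in known and not c.startswith(dialect.drug_column_prefix)
    ]
    if unknown:
        raise GdscParseError(f"{csv_path}: unknown columns {unknown}")
    missing_cols = sorted(known - set(table.columns))
    if missing_cols:
        raise GdscParseError(f"{csv_path}: missing declared columns {missing_cols}")

    cell_ids = table[dialect.cell_line_column].astype(str).str.strip()
    if cell_ids.duplicated().any():
        dup = cell_ids[cell_ids.duplicated()].iloc[0]
        raise GdscParseError(f"{csv_path}: duplicate cell line id {dup!r}")

    flags: dict[str, np.ndarray] = {}
    for col in dialect.gene_columns:
        parsed = np.empty(len(table), dtype=np.int8)
        for i, raw in enumerate(table[col]):
            try:
                x, y = _split_annotation(raw)
                parsed[i] = parse_variant_annotation(x, y, dialect.wt_copy_number_token)
            except GdscParseError as exc:
                raise GdscParseError(
                    f"{csv_path}: row {i + 2} (cell line {cell_ids.iloc[i]!r}), "
                    f"column {col!r}: {exc}"
                ) from exc
        flags[col] = parsed
    for col in dialect.fusion_columns:
        parsed = np.empty(len(table), dtype=np.int8)
        for i, raw in enumerate(table[col]):
            try:
                parsed[i] = parse_fusion_status(raw, dialect.fusion_not_detected_tokens)
            except GdscParseError as exc:
                raise GdscParseError(
                    f"{csv_path}: row {i + 2}, column {col!r}: {exc}"
                ) from exc
        flags[col] = parsed
    if dialect.msi_column is not None:
        flags[dialect.msi_column] = np.array(
            [_parse_msi(v, dialect.msi_positive_tokens) for v in table[dialect.msi_column]],
            dtype=np.int8,
        )

    features = pd.DataFrame(flags, index=pd.Index(cell_ids, name="cell_line_id"))

    drug_cols = [c for c in table.columns if c.startswith(dialect.drug_column_prefix)]
    records: list[tuple[str, str, float]] = []
    for col in drug_cols:
        drug_id = col[len(dialect.drug_column_prefix):]
        for cell, raw in zip(cell_ids, table[col]):
            raw = raw.strip()
            if raw == "" or raw.lower() in ("na", "nan"):
                continue  # unmeasured pair
            try:
                value = float(raw)
            except ValueError as exc:
                raise GdscParseError(
                    f"{csv_path}: unparsable response {raw!r} for drug {drug_id!r}, "
                    f"cell line {cell!r}"
                ) from exc
            if dialect.response_scale == "ln":
                value = convert_ln_to_log10(value)
            records.append((drug_id, cell, value))
    responses = pd.DataFrame(records, columns=["drug_id", "cell_line_id", "log_ic50"])
    responses["log_ic50"] = responses["log_ic50"].astype(float)

    release = DatasetRelease(
        tag=tag, features=features, responses=responses, drug_metadata=metadata, dialect=dialect
    )
    logger.info(
        "read release %s: %d cell lines, %d features, %d drugs, %d response records",
        tag, len(features), features.shape[1], responses["drug_id"].nunique(), len(responses),
    )
    return release


def write_release(release: DatasetRelease, directory: str | Path) -> Path:
    """Write a release as a GDSC-dialect directory; inverse of :func:`read_release`.

    Binary gene flags are serialised back to ``x::y`` tokens (``wt::<wt-token>``
    for 0, ``mut::<wt-token>`` for 1), fusions to ``wt`` or the fusion's own
    name, and responses on the log10 scale, so a read of the written directory
    reproduces the release exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dialect = release.dialect
    if dialect is None:
        feature_names = release.feature_names
        msi = "msi" if "msi" in feature_names else None
        dialect = DialectConfig(
            gene_columns=[f for f in feature_names if f != msi],
            fusion_columns=[],
            msi_column=msi,
        )
    dialect = replace(dialect, response_scale="log10")

    wt_tok = dialect.wt_copy_number_token
    out = pd.DataFrame(index=release.features.index)
    for col in dialect.gene_columns:
        out[col] = np.where(release.features[col].to_numpy() == 1, f"mut::{wt_tok}", f"wt::{wt_tok}")
    for col in dialect.fusion_columns:
        out[col] = np.where(release.features[col].to_numpy() == 1, col, "wt")
    if dialect.msi_column is not None:
        out[dialect.msi_column] = release.features[dialect.msi_column].astype(int).astype(str)

    wide = release.responses.pivot(index="cell_line_id", columns="drug_id", values="log_ic50")
    wide = wide.reindex(release.features.index)
    for drug_id in sorted(wide.columns):
        col = wide[drug_id]
        out[f"{dialect.drug_column_prefix}{drug_id}"] = [
            "" if pd.isna(v) else repr(float(v)) for v in col
        ]
    out.insert(0, dialect.cell_line_column, release.features.index)

    out.to_csv(directory / DATA_FILENAME, index=False)
    dialect.to_yaml(directory / DIALECT_FILENAME)
    if release.drug_metadata is not None:
        release.drug_metadata.reset_index().to_csv(directory / DRUG_METADATA_FILENAME, index=False)
    return directory


def deduplicate_drugs(release: DatasetRelease, keep_map: dict[str, str]) -> DatasetRelease:
    """Collapse duplicate-name drug groups, keeping one id per compound name.

    ``keep_map`` maps a duplicated compound name to the drug id to retain;
    response records (and metadata rows) of the other ids under that name are
    dropped.  Requires ``drug_metadata`` with a ``name`` column.
    """
    if not keep_map:
        return release
    if release.drug_metadata is None or "name" not in release.drug_metadata.columns:
        raise ValueError("deduplicate_drugs requires drug_metadata with a 'name' column")
    meta = release.drug_metadata
    drop_ids: list[str] = []
    for name, kept in keep_map.items():
        group = meta.index[meta["name"] == name]
        if kept not in set(group):
            raise ValueError(f"keep_map entry {name!r} -> {kept!r}: id not found under that name")
        drop_ids.extend(d for d in group if d != kept)
    if drop_ids:
        logger.info("deduplicate_drugs: dropping drug ids %s", drop_ids)
    responses = release.responses[~release.responses["drug_id"].isin(drop_ids)].reset_index(
        drop=True
    )
    return DatasetRelease(
        tag=release.tag,
        features=release.features,
        responses=responses,
        drug_metadata=meta.drop(index=drop_ids),
        dialect=release.dialect,
    )
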