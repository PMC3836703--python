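"""Domain types and tabular I/O.

Expression matrices are features x samples TSV tables (header row of
sample ids, first column feature ids), the dialect of common TCGA/GEO
matrix exports. The clinical table is one row per sample with survival
time in days and a vital-status event column; extra columns are carried
along as covariates. A binding-site prediction table lists
(miR, gene, tool) triples from target-prediction programs.

Values are assumed already normalised (log-scale); no normalisation is
performed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "BindingPredictionTable",
    "AlignedDataset",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_clinical_table",
    "read_prediction_table",
    "align_dataset",
]

#: tools aggregated by the miRecords comparison survey
DEFAULT_TOOL_VOCABULARY = (
    "DIANA-microT",
    "MicroInspector",
    "miRanda",
    "MirTarget2",
    "miTarget",
    "NBmiRTar",
    "PicTar",
    "PITA",
    "RNA22",
    "RNAhybrid",
    "TargetScan",
)

_EVENT_SYNONYMS = {
    "1": True, "0": False,
    "true": True, "false": False,
    "deceased": True, "living": False,
    "dead": True, "alive": False,
}


@dataclass(frozen=True)
class ExpressionMatrix:
    """Named features x named samples matrix of finite log-scale values."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            raise ValueError("duplicate feature identifier")
        if df.columns.has_duplicates:
            raise ValueError("duplicate sample identifier")
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValueError("expression matrix has zero usable rows or columns")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number) or not np.isfinite(arr).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, feature_id: str) -> np.ndarray:
        return self.values.loc[feature_id].to_numpy(dtype=float)


@dataclass(frozen=True)
class ClinicalTable:
    """Per-sample survival time (days), event status, and optional covariates.

    ``table`` is indexed by sample id with at least columns ``time``
    (non-negative float) and ``event`` (bool); any further columns are
    covariates.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise ValueError("duplicate sample identifier")
        for col in ("time", "event"):
            if col not in t.columns:
                raise ValueError(f"clinical table lacks mandatory column {col!r}")
        if (t["time"].to_numpy(dtype=float) < 0).any():
            raise ValueError("negative survival time")
        if t["event"].dtype != bool:
            raise ValueError("event column must be boolean")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.table.columns if c not in ("time", "event")]

    def times(self) -> np.ndarray:
        return self.table["time"].to_numpy(dtype=float)

    def events(self) -> np.ndarray:
        return self.table["event"].to_numpy(dtype=bool)


@dataclass(frozen=True)
class BindingPredictionTable:
    """Deduplicated (miR, gene, tool) binding-site prediction records."""

    records: frozenset[tuple[str, str, str]]

    def tools_for(self, mir_id: str, gene_id: str) -> list[str]:
        return sorted(t for m, g, t in self.records if m == mir_id and g == gene_id)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class AlignedDataset:
    """The three inputs restricted and re-ordered to their common samples."""

    gene_expr: ExpressionMatrix
    mir_expr: ExpressionMatrix
    clinical: ClinicalTable
    sample_ids: tuple[str, ...]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def read_expression_matrix(path, *, strict: bool = False) -> ExpressionMatrix:
    """Read a features x samples TSV matrix.

    Rows containing missing or non-numeric values are dropped with a
    logged warning (default) or raise in ``strict`` mode: a correlation
    computed over a per-pair-varying sample subset would silently change
    its n, so partially observed features are never propagated.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):  # pandas would silently rename these
        raise ValueError(f"{path}: duplicate sample identifier")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate feature identifier")
    df = df.apply(pd.to_numeric, errors="coerce")
    bad = ~np.isfinite(df.to_numpy()).all(axis=1)
    if bad.any():
        if strict:
            raise ValueError(
                f"{path}: {int(bad.sum())} rows contain missing/non-numeric values"
            )
        logger.warning(
            "%s: dropped %d of %d rows with missing/non-numeric values",
            path, int(bad.sum()), len(df),
        )
        df = df.loc[~bad]
    if len(df) == 0:
        raise ValueError(f"{path}: zero usable rows")
    return ExpressionMatrix(df.astype(float))


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(Path(path), sep="\t", float_format="%.10g")


def read_clinical_table(path, column_map: dict | None = None) -> ClinicalTable:
    """Read a clinical TSV with sample id, survival time and vital status.

    ``column_map`` maps the logical names ``sample``, ``time`` and
    ``event`` to the file's column names. Event encodings 1/0,
    true/false, deceased/living (and dead/alive) are accepted;
    unrecognised values are an error, never guessed. Rows with a missing
    time or event are excluded with a logged count. Extra columns are
    retained as covariates.
    """
    path = Path(path)
    cmap = {"sample": "sample_id", "time": "time", "event": "event"}
    cmap.update(column_map or {})
    df = pd.read_csv(path, sep="\t", dtype={cmap["sample"]: str})
    for key in ("sample", "time", "event"):
        if cmap[key] not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {cmap[key]!r}")
    df = df.rename(
        columns={cmap["sample"]: "sample_id", cmap["time"]: "time", cmap["event"]: "event"}
    )
    df = df.set_index("sample_id")

    df["time"] = pd.to_numeric(df["time"], errors="coerce")
    missing = df["time"].isna() | df["event"].isna()
    if missing.any():
        logger.warning(
            "%s: excluded %d samples with missing follow-up time or vital status",
            path, int(missing.sum()),
        )
        df = df.loc[~missing]
    if (df["time"] < 0).any():
        raise ValueError(f"{path}: negative survival time")

    def decode(v):
        key = str(v).strip().lower()
        if key in ("1.0", "0.0"):
            key = key[0]
        if key not in _EVENT_SYNONYMS:
            raise ValueError(f"{path}: unmappable event value {v!r}")
        return _EVENT_SYNONYMS[key]

    df["event"] = df["event"].map(decode).astype(bool)
    df["time"] = df["time"].astype(float)
    ordered = ["time", "event"] + [c for c in df.columns if c not in ("time", "event")]
    return ClinicalTable(df[ordered])


def read_prediction_table(
    path, *, vocabulary: tuple[str, ...] | None = None
) -> BindingPredictionTable:
    """Read a (mir, gene, tool) prediction TSV, deduplicated.

    With a ``vocabulary`` supplied, unknown tool names are an error; an
    empty file yields an empty (valid) table.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return BindingPredictionTable(frozenset())
    for col in ("mir", "gene", "tool"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")
    if vocabulary is not None:
        unknown = set(df["tool"]) - set(vocabulary)
        if unknown:
            raise ValueError(f"{path}: unknown tool name(s): {sorted(unknown)}")
    records = frozenset(
        (str(m), str(g), str(t)) for m, g, t in zip(df["mir"], df["gene"], df["tool"])
    )
    return BindingPredictionTable(records)


def align_dataset(
    gene_expr: ExpressionMatrix,
    mir_expr: ExpressionMatrix,
    clinical: ClinicalTable,
    min_group_size: int = 10,
) -> AlignedDataset:
    """Restrict all three inputs to their common samples.

    The intersection is ordered lexicographically so every downstream
    seeded computation is reproducible across runs and platforms; each
    matrix is re-indexed to that order. Fails when fewer than
    ``2 * min_group_size`` samples are shared.
    """
    common = sorted(
        set(gene_expr.sample_ids) & set(mir_expr.sample_ids) & set(clinical.sample_ids)
    )
    if len(common) < 2 * min_group_size:
        raise ValueError(
            f"insufficient common samples: {len(common)} shared, "
            f"need at least {2 * min_group_size}"
        )
    for name, ids in (
        ("gene matrix", gene_expr.sample_ids),
        ("miR matrix", mir_expr.sample_ids),
        ("clinical table", clinical.sample_ids),
    ):
        dropped = len(ids) - len(common)
        if dropped:
            logger.info("alignment dropped %d samples from the %s", dropped, name)
    return AlignedDataset(
        gene_expr=ExpressionMatrix(gene_expr.values.loc[:, common]),
        mir_expr=ExpressionMatrix(mir_expr.values.loc[:, common]),
        clinical=ClinicalTable(clinical.table.loc[common]),
        sample_ids=tuple(common),
    )
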