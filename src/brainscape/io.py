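"""Reading, unit conversion and merging of cohort expression matrices.

Bulk RNA-seq cohorts arrive as gene-by-sample abundance tables quantified by
different pipelines and in different units (FPKM or TPM).  Before any joint
analysis they are converted to a common unit (TPM), restricted to a shared
protein-coding gene space, log-transformed, and concatenated into a single
matrix with a per-sample cohort label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Unit",
    "ExpressionMatrix",
    "GeneSpace",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_metadata",
    "read_gene_space",
    "fpkm_to_tpm",
    "intersect_and_merge",
    "log2_transform",
]

#: Columns every sample-metadata table carries; empty string means missing.
METADATA_COLUMNS = [
    "sample_id",
    "patient_id",
    "dataset",
    "disease_label",
    "sample_type",
    "age_years",
    "sex",
    "survival_years",
    "event",
]

SAMPLE_TYPES = {"primary", "recurrent", "secondary", "normal"}


class Unit(str, Enum):
    """Expression abundance unit.

    ``LOG2TPM`` denotes ``log2(TPM + 1)``, which keeps zeros at zero and is
    therefore nonnegative like the linear-scale units.
    """

    FPKM = "FPKM"
    TPM = "TPM"
    LOG2TPM = "LOG2TPM"


@dataclass
class ExpressionMatrix:
    """Gene-by-sample nonnegative expression values with a declared unit.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol with sample ids as columns.
    unit
        The abundance unit of ``values``.
    dataset
        Cohort label (e.g. ``"TCGA"``); ``"merged"`` after cohort merging.
    """

    values: pd.DataFrame
    unit: Unit
    dataset: str = ""
    #: batch-corrected log matrices may carry small negative values
    allow_negative: bool = field(default=False, repr=False, compare=False)

    @classmethod
    def corrected(cls, values: pd.DataFrame, unit: Unit, dataset: str) -> "ExpressionMatrix":
        """Construct a post-correction matrix, permitting small negatives."""
        return cls(values, unit, dataset, allow_negative=True)

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] == 0:
            raise ValueError("expression matrix has zero genes")
        if v.shape[1] == 0:
            raise ValueError("expression matrix has zero samples")
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dups[:5]}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        arr = v.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("expression matrix contains non-finite values")
        if not self.allow_negative and (arr < 0).any():
            raise ValueError(f"negative values not allowed for unit {self.unit.value}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class GeneSpace:
    """A reference set of (protein-coding) gene symbols."""

    symbols: frozenset[str]

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError("gene space is empty")

    @classmethod
    def from_file(cls, path: str | Path) -> "GeneSpace":
        symbols = [
            line.strip()
            for line in Path(path).read_text().splitlines()
            if line.strip()
        ]
        return cls(frozenset(symbols))

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols


def read_gene_space(path: str | Path) -> GeneSpace:
    """Read a gene-space file (one symbol per line)."""
    return GeneSpace.from_file(path)


def read_expression_matrix(
    path: str | Path, unit: Unit | str, dataset: str
) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column gene symbols, header sample ids).

    Duplicate gene symbols are collapsed by keeping the row with the highest
    mean across samples (a common rule for multi-mapped symbols); each
    collapse is logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.shape[0] == 0:
        raise ValueError(f"zero genes in {path}")
    try:
        df = df.astype(float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    if df.index.has_duplicates:
        means = df.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="stable")
        keep_first = df.iloc[order]
        dup_symbols = df.index[df.index.duplicated()].unique().tolist()
        logger.info(
            "collapsing %d duplicated gene symbols by highest mean: %s",
            len(dup_symbols),
            dup_symbols[:10],
        )
        keep_first = keep_first[~keep_first.index.duplicated(keep="first")]
        df = keep_first.reindex(pd.unique(df.index))
    return ExpressionMatrix(values=df, unit=Unit(unit), dataset=dataset)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix to TSV in the same layout ``read_expression_matrix`` reads."""
    out = m.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample-metadata CSV; empty strings become missing values.

    Enforces unique sample ids and the contract that ``survival_years`` is
    present whenever ``event`` is.
    """
    meta = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    meta = meta.replace("", pd.NA)
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    for col in ("age_years", "survival_years"):
        meta[col] = pd.to_numeric(meta[col])
    meta["event"] = meta["event"].map(
        {"True": True, "False": False, "1": True, "0": False, pd.NA: pd.NA}
    )
    bad = meta["event"].notna() & meta["survival_years"].isna()
    if bad.any():
        raise ValueError(
            "survival_years missing where event present for samples: "
            f"{meta.loc[bad, 'sample_id'].tolist()[:5]}"
        )
    unknown_types = set(meta["sample_type"].dropna()) - SAMPLE_TYPES
    if unknown_types:
        raise ValueError(f"unknown sample_type values: {sorted(unknown_types)}")
    return meta.set_index("sample_id", drop=False)


def fpkm_to_tpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Convert FPKM to TPM by per-sample renormalization.

    TPM_ij = FPKM_ij / sum_i FPKM_ij * 1e6, so each sample (column) sums to
    one million.
    """
    if m.unit is not Unit.FPKM:
        raise ValueError(f"expected FPKM input, got {m.unit.value}")
    colsums = m.values.sum(axis=0)
    zero = colsums[colsums == 0]
    if len(zero):
        raise ValueError(f"all-zero sample column(s): {list(zero.index)[:5]}")
    tpm = m.values.div(colsums, axis=1) * 1e6
    return ExpressionMatrix(values=tpm, unit=Unit.TPM, dataset=m.dataset)


def intersect_and_merge(
    matrices: list[ExpressionMatrix], space: GeneSpace
) -> tuple[ExpressionMatrix, pd.Series]:
    """Merge TPM cohort matrices on the shared gene space.

    The merged matrix is restricted to the intersection of all cohorts' genes
    with ``space`` and gene order is sorted lexicographically, so the result
    does not depend on cohort input order.

    Returns
    -------
    merged
        ExpressionMatrix with dataset label ``"merged"``.
    datasets
        Series mapping sample id to its cohort of origin.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    for m in matrices:
        if m.unit is not Unit.TPM:
            raise ValueError(f"all matrices must be TPM; {m.dataset!r} is {m.unit.value}")
    common = set(matrices[0].genes)
    for m in matrices[1:]:
        common &= set(m.genes)
    common &= space.symbols
    if not common:
        raise ValueError("empty gene intersection across cohorts and gene space")
    genes = sorted(common)
    all_samples: list[str] = []
    for m in matrices:
        all_samples.extend(m.samples)
    if len(set(all_samples)) != len(all_samples):
        seen: set[str] = set()
        dups = [s for s in all_samples if s in seen or seen.add(s)]
        raise ValueError(f"duplicate sample id across cohorts: {sorted(set(dups))[:5]}")
    merged = pd.concat([m.values.loc[genes] for m in matrices], axis=1)
    datasets = pd.Series(
        {s: m.dataset for m in matrices for s in m.samples}, name="dataset"
    ).loc[merged.columns]
    return ExpressionMatrix(values=merged, unit=Unit.TPM, dataset="merged"), datasets


def log2_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise ``log2(TPM + 1)``; monotone and zero-preserving."""
    if m.unit is not Unit.TPM:
        raise ValueError(f"expected TPM input, got {m.unit.value}")
    return ExpressionMatrix(
        values=np.log2(m.values + 1.0), unit=Unit.LOG2TPM, dataset=m.dataset
    )
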