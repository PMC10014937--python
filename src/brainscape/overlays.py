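"""Multi-omic per-sample summaries projected over the landscape: mutation
burden, gene-fusion burden (high-confidence Arriba calls only), GISTIC
copy-number gain/loss counts, group fusion frequencies and single-gene
panels combining all sources."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = [
    "read_variant_table",
    "read_fusion_table",
    "read_cn_matrix",
    "merge_variant_callers",
    "mutation_burden",
    "fusion_filter_and_burden",
    "cn_gain_loss_counts",
    "fusion_frequency_by_group",
    "gene_panel",
]

VARIANT_COLUMNS = ["sample_id", "gene", "position", "alt", "variant_class", "caller"]
FUSION_COLUMNS = ["sample_id", "gene_5prime", "gene_3prime", "confidence", "caller"]

#: MAF-minimal column mapping for variant TSVs
_MAF_RENAME = {
    "Tumor_Sample_Barcode": "sample_id",
    "Hugo_Symbol": "gene",
    "Start_Position": "position",
    "Tumor_Seq_Allele2": "alt",
    "Variant_Classification": "variant_class",
}

CONFIDENCE_LEVELS = {"high", "medium", "low"}
ARRIBA = "arriba"


def read_variant_table(path: str | Path) -> pd.DataFrame:
    """Read a MAF-minimal variant TSV into the internal column layout."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df = df.rename(columns=_MAF_RENAME)
    missing = [c for c in ("sample_id", "gene") if c not in df.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    for col in VARIANT_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    bad = (df["sample_id"] == "") | (df["gene"] == "")
    if bad.any():
        raise ValueError("variant rows with empty sample_id or gene")
    return df[VARIANT_COLUMNS]


def read_fusion_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df = df.rename(
        columns={"sample": "sample_id", "gene5": "gene_5prime", "gene3": "gene_3prime"}
    )
    missing = [c for c in FUSION_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ValueError(f"fusion table missing columns: {missing}")
    for col in FUSION_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    if ((df["gene_5prime"] == "") | (df["gene_3prime"] == "")).any():
        raise ValueError("fusion rows with empty partner gene")
    unknown = set(df["confidence"]) - CONFIDENCE_LEVELS - {""}
    if unknown:
        raise ValueError(f"unknown fusion confidence values: {sorted(unknown)}")
    return df[FUSION_COLUMNS]


def read_cn_matrix(path: str | Path) -> pd.DataFrame:
    """Read a GISTIC-thresholded gene-by-sample copy-number TSV (-2..2)."""
    cn = pd.read_csv(path, sep="\t", index_col=0)
    _validate_cn(cn)
    return cn


def _validate_cn(cn: pd.DataFrame) -> None:
    arr = cn.to_numpy()
    if not np.isin(arr, [-2, -1, 0, 1, 2]).all():
        raise ValueError("copy-number values outside {-2, -1, 0, 1, 2}")


def merge_variant_callers(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Union variant tables from several callers, deduplicating on
    (sample_id, gene, position, alt); when position/alt are absent the key
    falls back to (sample_id, gene, variant_class).  The caller column
    becomes the sorted, comma-joined list of supporting callers."""
    if not tables:
        raise ValueError("need at least one variant table")
    merged = pd.concat(tables, ignore_index=True)
    if merged.empty:
        return merged.reindex(columns=VARIANT_COLUMNS)
    has_locus = (merged["position"] != "") & (merged["alt"] != "")
    key = np.where(
        has_locus,
        merged["sample_id"] + "\x00" + merged["gene"] + "\x00"
        + merged["position"] + "\x00" + merged["alt"],
        merged["sample_id"] + "\x00" + merged["gene"] + "\x00"
        + merged["variant_class"],
    )
    merged = merged.assign(_key=key)
    callers = (
        merged.groupby("_key")["caller"]
        .apply(lambda c: ",".join(sorted(set(filter(None, c)))))
    )
    first = merged.drop_duplicates("_key").set_index("_key")
    first["caller"] = callers
    out = first.reset_index(drop=True)[VARIANT_COLUMNS]
    return out.sort_values(["sample_id", "gene", "position", "alt"], kind="stable").reset_index(
        drop=True
    )


def mutation_burden(variants: pd.DataFrame, samples: list[str]) -> pd.Series:
    """Number of (deduplicated) variant records per sample; absent samples
    count 0."""
    counts = variants.groupby("sample_id").size() if len(variants) else pd.Series(dtype=int)
    return pd.Series(
        [int(counts.get(s, 0)) for s in samples], index=samples, name="mutation_burden"
    )


def fusion_filter_and_burden(fusions: pd.DataFrame, samples: list[str]) -> pd.Series:
    """Fusion calls per sample after dropping non-high-confidence Arriba
    calls (other callers are not confidence-filtered)."""
    kept = filter_high_confidence(fusions)
    counts = kept.groupby("sample_id").size() if len(kept) else pd.Series(dtype=int)
    return pd.Series(
        [int(counts.get(s, 0)) for s in samples], index=samples, name="fusion_burden"
    )


def filter_high_confidence(fusions: pd.DataFrame) -> pd.DataFrame:
    """Drop Arriba calls that are not flagged high-confidence."""
    if fusions.empty:
        return fusions
    is_arriba = fusions["caller"].str.lower() == ARRIBA
    keep = ~is_arriba | (fusions["confidence"] == "high")
    return fusions[keep]


def cn_gain_loss_counts(cn: pd.DataFrame) -> pd.DataFrame:
    """Per sample: number of genes with any gain (value > 0) and any loss
    (value < 0)."""
    _validate_cn(cn)
    arr = cn.to_numpy()
    return pd.DataFrame(
        {
            "genes_gained": (arr > 0).sum(axis=0).astype(int),
            "genes_lost": (arr < 0).sum(axis=0).astype(int),
        },
        index=cn.columns,
    )


def fusion_frequency_by_group(
    fusions: pd.DataFrame, groups: pd.Series, gene: str
) -> pd.Series:
    """Percent of samples per group carrying at least one fusion with
    ``gene`` as either partner.  ``fusions`` is expected to be
    high-confidence-filtered already."""
    groups = pd.Series(groups)
    counts = groups.value_counts()
    if (counts == 0).any() or len(counts) == 0:
        raise ValueError("empty group")
    if len(fusions):
        hit_rows = fusions[
            (fusions["gene_5prime"] == gene) | (fusions["gene_3prime"] == gene)
        ]
        carriers = set(hit_rows["sample_id"])
    else:
        carriers = set()
    out = {}
    for group, members in groups.groupby(groups):
        member_ids = set(members.index)
        out[group] = 100.0 * len(member_ids & carriers) / len(member_ids)
    return pd.Series(out, name=f"{gene}_fusion_pct")


def gene_panel(
    gene: str,
    m: ExpressionMatrix,
    variants: pd.DataFrame,
    fusions: pd.DataFrame,
    cn: pd.DataFrame,
) -> pd.DataFrame:
    """Single-gene multi-omic panel: one row per expression sample with the
    gene's expression, mutation flag, CN call and fusion flag.

    Samples absent from a source default to mutated=False, fused=False,
    cn_call=0; per-source coverage flags record whether the sample was
    present in that source at all.
    """
    if gene not in m.values.index:
        raise ValueError(f"gene {gene!r} absent from expression matrix")
    samples = m.samples
    expr = m.values.loc[gene]
    mutated_samples = set(variants.loc[variants["gene"] == gene, "sample_id"])
    variant_samples = set(variants["sample_id"])
    fused_samples = set(
        fusions.loc[
            (fusions["gene_5prime"] == gene) | (fusions["gene_3prime"] == gene),
            "sample_id",
        ]
    )
    fusion_samples = set(fusions["sample_id"])
    cn_row = cn.loc[gene] if gene in cn.index else pd.Series(dtype=int)
    rows = []
    for s in samples:
        rows.append(
            {
                "sample_id": s,
                "expression": float(expr[s]),
                "mutated": s in mutated_samples,
                "cn_call": int(cn_row.get(s, 0)),
                "fused": s in fused_samples,
                "variant_covered": s in variant_samples,
                "fusion_covered": s in fusion_samples,
                "cn_covered": s in cn.columns,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")
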