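"""Rule-based WHO-CNS5 molecular subtyping of adult diffuse gliomas.

The three adult diffuse glioma groups are defined by two primary markers:
IDH1/IDH2 mutation status and 1p/19q codeletion.

* IDH-mutant + 1p/19q codeleted  -> oligodendroglioma
* IDH-mutant + 1p/19q intact     -> IDH-mutant astrocytoma
* IDH-wildtype                   -> IDH-wildtype glioblastoma

TP53/ATRX mutations (typical of IDH-mutant astrocytoma) and chromosome 7
gain / chromosome 10 loss (typical of IDH-wt glioblastoma) are corroborating
annotations only and never override the primary markers.  Missing IDH status
yields UNCLASSIFIED; no imputation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import pandas as pd

__all__ = [
    "IDHStatus",
    "CodelStatus",
    "GliomaSubtype",
    "MolecularMarkers",
    "classify_who_cns5",
    "classify_table",
    "read_markers",
]


class IDHStatus(str, Enum):
    MUTANT = "mutant"
    WILDTYPE = "wildtype"
    UNKNOWN = "unknown"


class CodelStatus(str, Enum):
    CODEL = "codel"
    INTACT = "intact"
    UNKNOWN = "unknown"


class GliomaSubtype(str, Enum):
    OLIGODENDROGLIOMA_IDH_MUT_CODEL = "OLIGODENDROGLIOMA_IDH_MUT_CODEL"
    ASTROCYTOMA_IDH_MUT = "ASTROCYTOMA_IDH_MUT"
    GLIOBLASTOMA_IDH_WT = "GLIOBLASTOMA_IDH_WT"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class MolecularMarkers:
    idh_status: IDHStatus = IDHStatus.UNKNOWN
    codel_1p19q: CodelStatus = CodelStatus.UNKNOWN
    tp53_mut: bool | None = None
    atrx_mut: bool | None = None
    chr7_gain: bool | None = None
    chr10_loss: bool | None = None
    grade: int | None = None

    def __post_init__(self) -> None:
        if self.grade is not None and not 2 <= self.grade <= 4:
            raise ValueError("grade must be 2-4")


def classify_who_cns5(m: MolecularMarkers) -> GliomaSubtype:
    """Classify a sample from its molecular markers.  Total and deterministic.

    IDH-wildtype tumors are grouped as glioblastoma regardless of grade (one
    transcriptional group); downstream reporting flags grade < 4 calls.
    """
    if m.idh_status is IDHStatus.MUTANT:
        if m.codel_1p19q is CodelStatus.CODEL:
            return GliomaSubtype.OLIGODENDROGLIOMA_IDH_MUT_CODEL
        if m.codel_1p19q is CodelStatus.INTACT:
            return GliomaSubtype.ASTROCYTOMA_IDH_MUT
        return GliomaSubtype.UNCLASSIFIED
    if m.idh_status is IDHStatus.WILDTYPE:
        return GliomaSubtype.GLIOBLASTOMA_IDH_WT
    return GliomaSubtype.UNCLASSIFIED


_BOOL = {"True": True, "False": False, "1": True, "0": False,
         "true": True, "false": False}


def read_markers(path: str | Path) -> pd.DataFrame:
    """Read a markers CSV (sample_id, idh_status, codel_1p19q, tp53_mut,
    atrx_mut, chr7_gain, chr10_loss, grade; empty = missing)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False).replace("", pd.NA)
    if "sample_id" not in df.columns:
        raise ValueError("markers CSV needs a sample_id column")
    return df.set_index("sample_id", drop=False)


def classify_table(markers: pd.DataFrame) -> pd.DataFrame:
    """Classify every row of a markers table.

    Returns a DataFrame indexed by sample_id with columns ``subtype`` and
    ``low_grade_idh_wt_flag`` (True where an IDH-wt tumor has recorded
    grade < 4 but is still grouped with glioblastoma).
    """
    rows = []
    for sample_id, r in markers.iterrows():
        idh = IDHStatus(r.get("idh_status") or "unknown")
        codel = CodelStatus(r.get("codel_1p19q") or "unknown")
        grade_raw = r.get("grade")
        grade = int(grade_raw) if pd.notna(grade_raw) and grade_raw is not None else None
        m = MolecularMarkers(
            idh_status=idh,
            codel_1p19q=codel,
            tp53_mut=_BOOL.get(str(r.get("tp53_mut"))),
            atrx_mut=_BOOL.get(str(r.get("atrx_mut"))),
            chr7_gain=_BOOL.get(str(r.get("chr7_gain"))),
            chr10_loss=_BOOL.get(str(r.get("chr10_loss"))),
            grade=grade,
        )
        subtype = classify_who_cns5(m)
        rows.append(
            {
                "sample_id": sample_id,
                "subtype": subtype.value,
                "low_grade_idh_wt_flag": bool(
                    subtype is GliomaSubtype.GLIOBLASTOMA_IDH_WT
                    and grade is not None
                    and grade < 4
                ),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")
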