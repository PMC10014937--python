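"""Kaplan-Meier estimation and nearest-neighbor survival annotation of the
embedding.

Survival analysis follows the standard product-limit construction (via
lifelines, the same estimator family the original analyses used).  The
embedding annotation colors each tumor sample with the Kaplan-Meier median
survival of a local cohort: the k nearest same-subtype, same-dataset
neighbors within a fixed radius in the 2-D embedding, where k is a fixed
fraction (default 25%) of that subtype/dataset stratum.  Samples whose
cohort is too small (default < 10) or whose cohort median is undefined (the
curve never reaches 0.5) stay unannotated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .landscape import Embedding

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "NNSurvivalParams",
    "filter_primary_unique",
    "km_curve",
    "km_median",
    "nn_survival_annotate",
    "read_survival_records",
    "records_to_frame",
]


@dataclass(frozen=True)
class SurvivalRecord:
    sample_id: str
    patient_id: str
    time_years: float
    event: bool
    subtype: str
    dataset: str

    def __post_init__(self) -> None:
        if self.time_years < 0:
            raise ValueError(f"negative survival time for {self.sample_id}")


@dataclass
class KMCurve:
    """Product-limit estimate: step function S(t), S(0)=1, non-increasing."""

    times: np.ndarray  # ascending event times (steps only)
    survival: np.ndarray  # S(t) at each event time
    at_risk: np.ndarray  # number at risk just before each event time

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly ascending")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")


@dataclass(frozen=True)
class NNSurvivalParams:
    """Knobs of the neighbor-cohort annotation.

    radius is in embedding units; cohort_fraction is the share of the
    subtype/dataset stratum used as cohort size; min_cohort is the smallest
    cohort that still gets annotated.  ``k_before_radius`` selects whether
    the k-nearest rule is applied before or after the radius filter (the
    published description is ambiguous; default filters by radius first).
    """

    radius: float = 2.0
    cohort_fraction: float = 0.25
    min_cohort: int = 10
    k_before_radius: bool = False

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not 0 < self.cohort_fraction <= 1:
            raise ValueError("cohort_fraction must be in (0, 1]")
        if self.min_cohort < 1:
            raise ValueError("min_cohort must be >= 1")


def filter_primary_unique(
    records: list[SurvivalRecord], meta: pd.DataFrame
) -> list[SurvivalRecord]:
    """Keep primary-tumor samples only, one per patient.

    Recurrent, secondary and normal-tissue samples are removed; when a
    patient has several primary samples the lexicographically smallest
    sample_id is kept (deterministic).
    """
    sample_type = meta["sample_type"]
    primary = [
        r
        for r in records
        if r.sample_id in sample_type.index and sample_type[r.sample_id] == "primary"
    ]
    best: dict[str, SurvivalRecord] = {}
    for r in sorted(primary, key=lambda r: r.sample_id):
        best.setdefault(r.patient_id, r)
    kept_ids = {r.sample_id for r in best.values()}
    return [r for r in primary if r.sample_id in kept_ids]


def km_curve(records: list[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier product-limit estimate over the given records."""
    if not records:
        raise ValueError("no survival records")
    times = np.array([r.time_years for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    steps = table[table["observed"] > 0]
    event_times = steps.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(event_times).to_numpy(dtype=float)
    at_risk = steps["at_risk"].to_numpy(dtype=float)
    return KMCurve(times=event_times, survival=surv, at_risk=at_risk)


def km_median(curve: KMCurve) -> float | None:
    """Smallest event time t with S(t) <= 0.5, or None if never reached."""
    hit = np.flatnonzero(curve.survival <= 0.5 + 1e-12)
    if len(hit) == 0:
        return None
    return float(curve.times[hit[0]])


def _cohort_median(records: list[SurvivalRecord]) -> float | None:
    return km_median(km_curve(records)) if records else None


def nn_survival_annotate(
    e: Embedding,
    records: list[SurvivalRecord],
    params: NNSurvivalParams | None = None,
) -> pd.Series:
    """Annotate each sample with the KM median survival of its local cohort.

    For sample s in stratum (subtype g, dataset d) with stratum size N_gd,
    the target cohort size is k = round(cohort_fraction * N_gd), rounding
    half away from zero.  Candidates are the other stratum samples within
    ``params.radius`` of s in the 2-D embedding; the cohort is the k nearest
    candidates (fewer if fewer qualify).  Cohorts smaller than
    ``params.min_cohort``, or with undefined KM median, leave s unannotated
    (NaN).

    Records are expected to be pre-filtered with :func:`filter_primary_unique`.
    """
    params = params or NNSurvivalParams()
    missing = [r.sample_id for r in records if r.sample_id not in e.coords.index]
    if missing:
        raise ValueError(f"record sample(s) missing from embedding: {missing[:5]}")
    xy = e.coords.iloc[:, :2]  # annotation always reads the 2-D surface
    out = pd.Series(
        np.nan, index=[r.sample_id for r in records], name="median_survival_years"
    )
    by_stratum: dict[tuple[str, str], list[SurvivalRecord]] = {}
    for r in records:
        by_stratum.setdefault((r.subtype, r.dataset), []).append(r)
    for stratum in by_stratum.values():
        n_gd = len(stratum)
        k = int(np.floor(params.cohort_fraction * n_gd + 0.5))  # half away from zero
        coords = xy.loc[[r.sample_id for r in stratum]].to_numpy(dtype=float)
        d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(d2, np.inf)  # never one's own neighbor
        dist = np.sqrt(d2)
        for i, r in enumerate(stratum):
            order = np.argsort(dist[i], kind="stable")
            if params.k_before_radius:
                nearest = order[: min(k, n_gd - 1)]
                cohort_idx = [j for j in nearest if dist[i, j] <= params.radius]
            else:
                in_radius = [j for j in order if dist[i, j] <= params.radius]
                cohort_idx = in_radius[:k]
            if len(cohort_idx) < params.min_cohort:
                continue
            med = _cohort_median([stratum[j] for j in cohort_idx])
            if med is not None:
                out[r.sample_id] = med
    return out


def records_to_frame(records: list[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records]).set_index("sample_id", drop=False)


def read_survival_records(path: str | Path) -> list[SurvivalRecord]:
    """Read a survival CSV with columns sample_id, patient_id, time_years,
    event, subtype, dataset."""
    df = pd.read_csv(path)
    return [
        SurvivalRecord(
            sample_id=str(r.sample_id),
            patient_id=str(r.patient_id),
            time_years=float(r.time_years),
            event=bool(r.event),
            subtype=str(r.subtype),
            dataset=str(r.dataset),
        )
        for r in df.itertuples()
    ]
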