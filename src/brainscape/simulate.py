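"""Synthetic multi-cohort bundles with known ground truth.

The generator emulates the statistical structure the pipeline assumes in
real consortium data, without any download: several sample groups (tumor
subtypes, a pediatric group, healthy brain) with group-specific mean shifts
on a shared log-expression baseline; cohort batch effects (additive offset
gamma on the log scale, multiplicative noise scale delta — exactly the
ComBat model); WHO-CNS5-consistent molecular markers per tumor sample;
exponential survival with subtype-specific medians and independent
exponential censoring calibrated to a target censoring fraction; and
variant / fusion / copy-number tables whose rates differ by group.

Expression is exponentiated to positive FPKM-like values, so the bundle
exercises the full harmonization path (FPKM -> TPM -> log2 -> ComBat).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, Unit, write_expression_matrix

__all__ = ["GroupSpec", "CohortSpec", "SimConfig", "TruthBundle", "simulate_cohort"]

#: canonical subtype labels used by the rule classifier
OLIGO = "OLIGODENDROGLIOMA_IDH_MUT_CODEL"
ASTRO = "ASTROCYTOMA_IDH_MUT"
GBM = "GLIOBLASTOMA_IDH_WT"


@dataclass(frozen=True)
class GroupSpec:
    """One biological group: its size, expression shift and (for tumor
    subtypes) marker/survival/omics behavior."""

    label: str
    n_samples: int
    shift_magnitude: float = 2.0  # log2 units on this group's signature genes
    subtype: str | None = None  # glioma subtype label, None for non-glioma
    median_survival_years: float | None = None
    censoring_fraction: float = 0.3
    mutation_rate: float = 5.0  # mean somatic variants per sample
    fusion_rate: float = 0.5  # mean fusions per sample
    fusion_gene: str | None = None  # recurrent 5' partner, e.g. EGFR in GBM
    cn_gain_genes: int = 0  # signature genes gained per sample
    cn_loss_genes: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if not 0 <= self.censoring_fraction < 1:
            raise ValueError("censoring_fraction must be in [0, 1)")


@dataclass(frozen=True)
class CohortSpec:
    """One cohort/pipeline batch: additive log-scale offset gamma and
    multiplicative noise scale delta (the ComBat model).

    ``gamma_gene_sd`` spreads the offset per gene (drawn once per cohort),
    emulating quantification-pipeline biases that differ gene by gene.  A
    purely uniform gamma is a per-sample scale factor and is removed by TPM
    normalization alone; the gene-specific component is what batch
    correction has to handle downstream.
    """

    label: str
    gamma: float = 0.0
    delta: float = 1.0
    gamma_gene_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.gamma_gene_sd < 0:
            raise ValueError("gamma_gene_sd must be nonnegative")


def default_groups() -> list[GroupSpec]:
    """Defaults mirroring the landscape's composition: three adult diffuse
    glioma subtypes with literature-scale median survivals (GBM ~1.2 y,
    IDH-mut astrocytoma ~8 y, oligodendroglioma ~14 y), one pediatric tumor
    group and healthy brain.  Group sizes keep the real relative abundances
    (GBM the most common adult glioma) and are large enough that each
    subtype-by-cohort stratum supports the 25%-cohort / min-10 survival
    annotation rule, as the consortium cohorts do."""
    return [
        GroupSpec(
            "glioblastoma", 200, subtype=GBM, median_survival_years=1.2,
            mutation_rate=8.0, fusion_rate=1.0, fusion_gene="EGFR",
            cn_gain_genes=30, cn_loss_genes=30,
        ),
        GroupSpec(
            "astrocytoma", 120, subtype=ASTRO, median_survival_years=8.0,
            mutation_rate=5.0, fusion_rate=0.3,
        ),
        GroupSpec(
            "oligodendroglioma", 80, subtype=OLIGO, median_survival_years=14.0,
            mutation_rate=4.0, fusion_rate=0.2,
        ),
        GroupSpec("medulloblastoma", 60, mutation_rate=2.0, fusion_rate=0.4),
        GroupSpec("healthy_brain", 100, mutation_rate=0.0, fusion_rate=0.0),
    ]


def default_cohorts() -> list[CohortSpec]:
    # one recount-style pipeline batch and one pediatric-consortium batch
    return [CohortSpec("RECOUNT", gamma=0.0, delta=1.0),
            CohortSpec("CBTN", gamma=2.0, delta=1.5, gamma_gene_sd=0.5)]


@dataclass
class SimConfig:
    n_genes: int = 600
    groups: list[GroupSpec] = field(default_factory=default_groups)
    cohorts: list[CohortSpec] = field(default_factory=default_cohorts)
    noise_sd: float = 0.5  # residual log2-scale noise (before delta scaling)
    signature_size: int = 40  # genes carrying each group's shift
    marker_noise: float = 0.0  # probability a marker call is flipped
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not self.groups or not self.cohorts:
            raise ValueError("need at least one group and one cohort")
        if self.signature_size * len(self.groups) > self.n_genes:
            raise ValueError("signatures exceed gene count")
        if not 0 <= self.marker_noise <= 1:
            raise ValueError("marker_noise must be in [0, 1]")


@dataclass
class TruthBundle:
    """Everything the pipeline reads plus the generating truth."""

    expression: dict[str, ExpressionMatrix]  # cohort label -> FPKM matrix
    metadata: pd.DataFrame
    markers: pd.DataFrame
    survival: pd.DataFrame
    variants: pd.DataFrame
    fusions: pd.DataFrame
    copy_number: pd.DataFrame
    truth: pd.DataFrame  # sample_id -> group, subtype, cohort
    batch_params: dict[str, dict[str, float]]
    gene_space: list[str]
    config: SimConfig

    def write(self, outdir: str | Path) -> dict[str, str]:
        """Write the on-disk bundle in the exact formats the pipeline reads."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, str] = {}
        for label, m in self.expression.items():
            p = outdir / f"expression_{label}.tsv"
            write_expression_matrix(m, p)
            paths[f"expression_{label}"] = str(p)
        meta = self.metadata.copy()
        meta.to_csv(outdir / "metadata.csv", index=False)
        paths["metadata"] = str(outdir / "metadata.csv")
        self.markers.to_csv(outdir / "markers.csv", index=False)
        paths["markers"] = str(outdir / "markers.csv")
        self.survival.to_csv(outdir / "survival.csv", index=False)
        paths["survival"] = str(outdir / "survival.csv")
        self.variants.to_csv(outdir / "variants.tsv", sep="\t", index=False)
        paths["variants"] = str(outdir / "variants.tsv")
        self.fusions.to_csv(outdir / "fusions.tsv", sep="\t", index=False)
        paths["fusions"] = str(outdir / "fusions.tsv")
        cn = self.copy_number.copy()
        cn.index.name = "gene"
        cn.to_csv(outdir / "copy_number.tsv", sep="\t")
        paths["copy_number"] = str(outdir / "copy_number.tsv")
        (outdir / "gene_space.txt").write_text("\n".join(self.gene_space) + "\n")
        paths["gene_space"] = str(outdir / "gene_space.txt")
        self.truth.to_csv(outdir / "truth.csv", index=False)
        truth_json = {
            "batch_params": self.batch_params,
            "config": json.loads(json.dumps(asdict(self.config), default=str)),
        }
        (outdir / "truth.json").write_text(json.dumps(truth_json, indent=2))
        paths["truth"] = str(outdir / "truth.csv")
        return paths


def _marker_row(rng: np.random.Generator, subtype: str | None, noise: float) -> dict:
    if subtype == OLIGO:
        row = {"idh_status": "mutant", "codel_1p19q": "codel",
               "tp53_mut": False, "atrx_mut": False,
               "chr7_gain": False, "chr10_loss": False, "grade": int(rng.integers(2, 4))}
    elif subtype == ASTRO:
        row = {"idh_status": "mutant", "codel_1p19q": "intact",
               "tp53_mut": True, "atrx_mut": True,
               "chr7_gain": False, "chr10_loss": False, "grade": int(rng.integers(2, 5))}
    elif subtype == GBM:
        row = {"idh_status": "wildtype", "codel_1p19q": "intact",
               "tp53_mut": bool(rng.random() < 0.3), "atrx_mut": False,
               "chr7_gain": True, "chr10_loss": True, "grade": 4}
    else:
        return {}
    if noise > 0:
        if rng.random() < noise:
            row["idh_status"] = "wildtype" if row["idh_status"] == "mutant" else "mutant"
        if rng.random() < noise:
            row["codel_1p19q"] = "intact" if row["codel_1p19q"] == "codel" else "codel"
    return row


def simulate_cohort(cfg: SimConfig) -> TruthBundle:
    """Draw a fully reproducible multi-cohort bundle from ``cfg``."""
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    # reserve recognizable symbols for omics tables
    named = ["IDH1", "TP53", "ATRX", "EGFR", "PSPHP1", "PTEN", "CDKN2A", "PDGFRA"]
    for i, sym in enumerate(named[: min(len(named), cfg.n_genes)]):
        genes[i] = sym

    base = rng.normal(3.0, 1.0, size=cfg.n_genes)  # shared log2 baseline
    signatures: dict[str, np.ndarray] = {}
    free = np.arange(len(named), cfg.n_genes)
    free = rng.permutation(free)
    for gi, group in enumerate(cfg.groups):
        sig = free[gi * cfg.signature_size: (gi + 1) * cfg.signature_size]
        signatures[group.label] = sig

    samples, sample_group, sample_cohort = [], {}, {}
    counter = 0
    n_cohorts = len(cfg.cohorts)
    for group in cfg.groups:
        for j in range(group.n_samples):
            sid = f"S{counter:04d}"
            counter += 1
            samples.append(sid)
            sample_group[sid] = group.label
            # deterministic round-robin keeps every group in every cohort
            sample_cohort[sid] = cfg.cohorts[j % n_cohorts].label

    group_by_label = {g.label: g for g in cfg.groups}
    cohort_by_label = {c.label: c for c in cfg.cohorts}

    # per-cohort per-gene additive offsets (drawn once per cohort)
    gamma_vec = {
        c.label: c.gamma + rng.normal(0.0, c.gamma_gene_sd, cfg.n_genes)
        if c.gamma_gene_sd > 0
        else np.full(cfg.n_genes, c.gamma)
        for c in cfg.cohorts
    }

    # log2 expression: baseline + group signature shift + gamma + delta * noise
    log2x = np.empty((cfg.n_genes, len(samples)))
    for j, sid in enumerate(samples):
        g = group_by_label[sample_group[sid]]
        c = cohort_by_label[sample_cohort[sid]]
        mu = base.copy()
        mu[signatures[g.label]] += g.shift_magnitude
        log2x[:, j] = (
            mu + gamma_vec[c.label] + c.delta * rng.normal(0.0, cfg.noise_sd, cfg.n_genes)
        )
    fpkm = np.power(2.0, log2x)

    expression: dict[str, ExpressionMatrix] = {}
    for c in cfg.cohorts:
        cols = [s for s in samples if sample_cohort[s] == c.label]
        df = pd.DataFrame(fpkm[:, [samples.index(s) for s in cols]],
                          index=genes, columns=cols)
        expression[c.label] = ExpressionMatrix(df, Unit.FPKM, dataset=c.label)

    # metadata + markers + survival
    meta_rows, marker_rows, surv_rows = [], [], []
    for sid in samples:
        g = group_by_label[sample_group[sid]]
        sample_type = "normal" if g.mutation_rate == 0 and g.subtype is None else "primary"
        age = float(np.round(rng.normal(12 if g.subtype is None else 50, 8), 1))
        row = {
            "sample_id": sid,
            "patient_id": f"P{sid[1:]}",
            "dataset": sample_cohort[sid],
            "disease_label": g.label,
            "sample_type": sample_type,
            "age_years": max(age, 0.5),
            "sex": "F" if rng.random() < 0.5 else "M",
            "survival_years": "",
            "event": "",
        }
        if g.subtype is not None and g.median_survival_years is not None:
            rate = np.log(2.0) / g.median_survival_years
            t = rng.exponential(1.0 / rate)
            frac = g.censoring_fraction
            if frac > 0:
                cens_rate = frac / (1.0 - frac) * rate
                ct = rng.exponential(1.0 / cens_rate)
            else:
                ct = np.inf
            observed = t <= ct
            row["survival_years"] = float(np.round(min(t, ct), 4))
            row["event"] = bool(observed)
            surv_rows.append(
                {
                    "sample_id": sid,
                    "patient_id": row["patient_id"],
                    "time_years": row["survival_years"],
                    "event": observed,
                    "subtype": g.subtype,
                    "dataset": sample_cohort[sid],
                }
            )
            mk = _marker_row(rng, g.subtype, cfg.marker_noise)
            marker_rows.append({"sample_id": sid, **mk})
        meta_rows.append(row)
    metadata = pd.DataFrame(meta_rows)
    markers = pd.DataFrame(marker_rows)
    survival = pd.DataFrame(
        surv_rows,
        columns=["sample_id", "patient_id", "time_years", "event", "subtype", "dataset"],
    )

    # somatic variants: marker-consistent drivers + Poisson passenger load
    variant_rows = []
    passenger_pool = genes
    for sid in samples:
        g = group_by_label[sample_group[sid]]
        drivers = []
        if g.subtype in (OLIGO, ASTRO):
            drivers.append("IDH1")
        if g.subtype == ASTRO:
            drivers += ["TP53", "ATRX"]
        for gene in drivers:
            variant_rows.append(
                {"sample_id": sid, "gene": gene,
                 "position": str(int(rng.integers(1, 10**6))),
                 "alt": "ACGT"[int(rng.integers(0, 4))],
                 "variant_class": "Missense_Mutation",
                 "caller": "mutect2"}
            )
        n_pass = int(rng.poisson(g.mutation_rate))
        for gene_idx in rng.integers(0, cfg.n_genes, size=n_pass):
            variant_rows.append(
                {"sample_id": sid, "gene": passenger_pool[int(gene_idx)],
                 "position": str(int(rng.integers(1, 10**6))),
                 "alt": "ACGT"[int(rng.integers(0, 4))],
                 "variant_class": "Missense_Mutation",
                 "caller": "mutect2"}
            )
    variants = pd.DataFrame(
        variant_rows,
        columns=["sample_id", "gene", "position", "alt", "variant_class", "caller"],
    ).astype(str) if variant_rows else pd.DataFrame(
        columns=["sample_id", "gene", "position", "alt", "variant_class", "caller"]
    )

    # fusions: recurrent partner per group plus random background, mixed confidence
    fusion_rows = []
    other_genes = [g for g in genes if g not in ("EGFR",)]
    for sid in samples:
        g = group_by_label[sample_group[sid]]
        n_fus = int(rng.poisson(g.fusion_rate))
        for _ in range(n_fus):
            conf = ["high", "medium", "low"][int(rng.choice(3, p=[0.6, 0.2, 0.2]))]
            if g.fusion_gene is not None and rng.random() < 0.5:
                g5 = g.fusion_gene
                g3 = "PSPHP1" if rng.random() < 0.5 else other_genes[
                    int(rng.integers(0, len(other_genes)))
                ]
            else:
                g5 = genes[int(rng.integers(0, cfg.n_genes))]
                g3 = genes[int(rng.integers(0, cfg.n_genes))]
            fusion_rows.append(
                {"sample_id": sid, "gene_5prime": g5, "gene_3prime": g3,
                 "confidence": conf, "caller": "arriba"}
            )
    fusions = pd.DataFrame(
        fusion_rows,
        columns=["sample_id", "gene_5prime", "gene_3prime", "confidence", "caller"],
    )

    # GISTIC-style copy number: group signature gains/losses + sparse noise
    cn = np.zeros((cfg.n_genes, len(samples)), dtype=int)
    for j, sid in enumerate(samples):
        g = group_by_label[sample_group[sid]]
        if g.cn_gain_genes > 0:
            sig = signatures[g.label][: g.cn_gain_genes]
            cn[sig, j] = rng.choice([1, 2], size=len(sig), p=[0.7, 0.3])
        if g.cn_loss_genes > 0:
            pool = [i for i in range(cfg.n_genes) if cn[i, j] == 0]
            loss = rng.choice(pool, size=min(g.cn_loss_genes, len(pool)), replace=False)
            cn[loss, j] = rng.choice([-1, -2], size=len(loss), p=[0.7, 0.3])
        noise_idx = rng.choice(cfg.n_genes, size=max(1, cfg.n_genes // 100), replace=False)
        for i in noise_idx:
            if cn[i, j] == 0 and rng.random() < 0.2:
                cn[i, j] = int(rng.choice([-1, 1]))
    copy_number = pd.DataFrame(cn, index=genes, columns=samples)

    truth = pd.DataFrame(
        {
            "sample_id": samples,
            "group": [sample_group[s] for s in samples],
            "subtype": [
                group_by_label[sample_group[s]].subtype or "" for s in samples
            ],
            "cohort": [sample_cohort[s] for s in samples],
        }
    )
    batch_params = {
        c.label: {"gamma": c.gamma, "delta": c.delta, "gamma_gene_sd": c.gamma_gene_sd}
        for c in cfg.cohorts
    }
    return TruthBundle(
        expression=expression,
        metadata=metadata,
        markers=markers,
        survival=survival,
        variants=variants,
        fusions=fusions,
        copy_number=copy_number,
        truth=truth,
        batch_params=batch_params,
        gene_space=list(genes),
        config=cfg,
    )
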