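"""End-to-end orchestration: harmonize -> batch-correct -> embed ->
classify -> survival-annotate -> pathway-score -> overlay.

Configured by a single JSON file; every stage after harmonization is
optional, so subsets of the landscape (e.g. a two-cohort embedding without
omics overlays) can be produced from the same entry point.  A rerun with
the same config and seed is bit-identical except for the manifest
timestamp.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .batch import BatchDesign, BatchMode, combat_adjust
from .io import (
    ExpressionMatrix,
    Unit,
    fpkm_to_tpm,
    intersect_and_merge,
    log2_transform,
    read_expression_matrix,
    read_gene_space,
    read_metadata,
)
from .landscape import EmbedParams, embed
from .overlays import (
    cn_gain_loss_counts,
    filter_high_confidence,
    fusion_filter_and_burden,
    mutation_burden,
    read_cn_matrix,
    read_fusion_table,
    read_variant_table,
)
from .pathways import gsva_scores, moderated_t_test, read_gmt
from .subtypes import classify_table, read_markers
from .survival import (
    NNSurvivalParams,
    filter_primary_unique,
    nn_survival_annotate,
    read_survival_records,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Input paths, per-stage parameter blocks, seed and output directory.

    ``expression`` maps cohort label -> {path, unit}.  Stages whose inputs
    are absent (markers, gene_sets, variants, fusions, copy_number,
    survival) are skipped.
    """

    expression: dict[str, dict[str, str]]
    metadata: str
    gene_space: str
    outdir: str
    seed: int = 0
    markers: str | None = None
    gene_sets: str | None = None
    variants: str | None = None
    fusions: str | None = None
    copy_number: str | None = None
    survival: str | None = None
    batch_mode: str = "location_scale_eb"
    embed_params: dict = field(default_factory=dict)
    nn_survival: dict = field(default_factory=dict)
    gsva: dict = field(default_factory=dict)
    pathway_groups: dict[str, list[str]] | None = None  # two named sample groups
    overlay_gene: str | None = None

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))

    def validate(self) -> None:
        if not self.expression:
            raise ValueError("no expression cohorts configured")
        for label, spec in self.expression.items():
            if not Path(spec["path"]).exists():
                raise FileNotFoundError(f"expression file for {label}: {spec['path']}")
        for name in ("metadata", "gene_space", "markers", "gene_sets", "variants",
                     "fusions", "copy_number", "survival"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict[str, str]:
    """Run all configured stages; returns output name -> file path.

    Writes a run manifest (package version, seed, parameters, output
    checksums, timestamp) alongside the outputs.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def _write_df(df: pd.DataFrame, name: str, **kwargs) -> None:
        path = outdir / name
        df.to_csv(path, **kwargs)
        outputs[name] = str(path)

    # --- harmonize -------------------------------------------------------
    stage = "harmonize"
    try:
        space = read_gene_space(cfg.gene_space)
        meta = read_metadata(cfg.metadata)
        tpm_matrices = []
        for label, spec in cfg.expression.items():
            m = read_expression_matrix(spec["path"], Unit(spec.get("unit", "FPKM")), label)
            if m.unit is Unit.FPKM:
                m = fpkm_to_tpm(m)
            tpm_matrices.append(m)
        merged, datasets = intersect_and_merge(tpm_matrices, space)
        logx = log2_transform(merged)
    except Exception as exc:  # noqa: BLE001 - aborts with stage name
        raise PipelineError(stage, exc) from exc

    # --- batch correction ------------------------------------------------
    stage = "batch_correct"
    try:
        design = BatchDesign(datasets, BatchMode(cfg.batch_mode))
        corrected = (
            combat_adjust(logx, design) if len(set(datasets)) > 1 else logx
        )
        _write_df(
            corrected.values.rename_axis("gene"), "corrected_expression.tsv", sep="\t"
        )
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- embedding -------------------------------------------------------
    stage = "embed"
    try:
        params = EmbedParams(**cfg.embed_params)
        e = embed(corrected, params, seed=cfg.seed)
        e.to_csv(outdir / "embedding.csv")
        outputs["embedding.csv"] = str(outdir / "embedding.csv")
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # --- subtype classification -----------------------------------------
    if cfg.markers is not None:
        stage = "classify"
        try:
            calls = classify_table(read_markers(cfg.markers))
            _write_df(calls.rename_axis("sample_id"), "subtype_calls.csv")
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

    # --- survival annotation --------------------------------------------
    if cfg.survival is not None:
        stage = "survival_annotate"
        try:
            records = read_survival_records(cfg.survival)
            records = filter_primary_unique(records, meta)
            annotation = nn_survival_annotate(
                e, records, NNSurvivalParams(**cfg.nn_survival)
            )
            _write_df(
                annotation.rename_axis("sample_id").to_frame(),
                "survival_annotation.csv",
            )
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

    # --- pathway scoring -------------------------------------------------
    if cfg.gene_sets is not None:
        stage = "pathways"
        try:
            sets = read_gmt(cfg.gene_sets)
            scores = gsva_scores(corrected, sets, **cfg.gsva)
            _write_df(scores, "pathway_scores.tsv", sep="\t")
            if cfg.pathway_groups:
                (name_a, group_a), (name_b, group_b) = list(cfg.pathway_groups.items())[:2]
                table = moderated_t_test(scores, group_a, group_b)
                _write_df(
                    table.rename_axis("pathway"),
                    f"differential_pathways_{name_a}_vs_{name_b}.csv",
                )
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

    # --- overlays --------------------------------------------------------
    samples = corrected.samples
    if cfg.variants is not None:
        stage = "overlays_variants"
        try:
            variants = read_variant_table(cfg.variants)
            _write_df(
                mutation_burden(variants, samples).rename_axis("sample_id").to_frame(),
                "mutation_burden.csv",
            )
        except Exception as exc:
            raise PipelineError(stage, exc) from exc
    if cfg.fusions is not None:
        stage = "overlays_fusions"
        try:
            fusions = read_fusion_table(cfg.fusions)
            _write_df(
                fusion_filter_and_burden(fusions, samples)
                .rename_axis("sample_id")
                .to_frame(),
                "fusion_burden.csv",
            )
        except Exception as exc:
            raise PipelineError(stage, exc) from exc
    if cfg.copy_number is not None:
        stage = "overlays_copy_number"
        try:
            cn = read_cn_matrix(cfg.copy_number)
            _write_df(
                cn_gain_loss_counts(cn).rename_axis("sample_id"),
                "cn_gain_loss.csv",
            )
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

    # --- manifest --------------------------------------------------------
    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "batch_mode": cfg.batch_mode,
        "embed_params": cfg.embed_params,
        "nn_survival": cfg.nn_survival,
        "outputs": {name: _sha256(Path(p)) for name, p in sorted(outputs.items())},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    outputs["manifest.json"] = str(manifest_path)
    return outputs
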