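# brainscape

Bulk RNA-seq cohorts of brain tumors are quantified by different pipelines, in
different units, with strong cohort-level technical effects — yet questions
like *where does a new sample fall relative to known glioma subtypes?* or
*what survival is typical for tumors that look like this one transcriptionally?*
need all cohorts on a single map.  `brainscape` builds that map: it harmonizes
gene-by-sample expression matrices (FPKM/TPM) from multiple cohorts into one
batch-corrected landscape, and annotates it with rule-based glioma subtypes,
neighbor-derived median survival, per-sample pathway activity and multi-omic
overlays.  It is aimed at computational oncology groups integrating adult
glioma, pediatric brain tumor and healthy-brain expression data.

## What it computes

- **Harmonization** — FPKM → TPM per sample (`TPM_ij = FPKM_ij / Σ_i FPKM_ij × 10⁶`),
  intersection onto a shared protein-coding gene space, `log2(TPM+1)`.
- **Batch correction** — parametric empirical-Bayes ComBat: per gene g and
  batch i, the model `x_ijg = α_g + γ_ig + δ_ig ε_ijg` with batch offsets γ
  and scales δ shrunk toward batch-level priors, then removed.
- **Landscape** — UMAP embedding of samples (deterministic given a seed) and
  k-NN majority-vote label transfer to unlabeled samples.
- **Subtypes** — WHO-CNS5 rules for adult diffuse glioma: IDH-mutant +
  1p/19q-codeleted → oligodendroglioma; IDH-mutant + intact → astrocytoma;
  IDH-wildtype → glioblastoma.
- **Survival** — Kaplan–Meier curves/medians (lifelines-backed) and the
  neighbor-cohort annotation: each tumor sample is colored with the KM median
  of its k nearest same-subtype, same-dataset neighbors within radius 2 of the
  2-D embedding, where k = 25% of the stratum (unannotated below 10 neighbors
  or when the median is undefined).
- **Pathways** — GSVA per-sample enrichment scores in [−1, 1]
  (Gaussian-kernel CDF, symmetric ranks, τ=1 KS random walk, max-deviation
  difference), plus a limma-style moderated t-test (`t̃_g = diff_g /
  (s̃_g √(1/n_a + 1/n_b))`, `s̃²_g = (d₀s₀² + d s²_g)/(d₀ + d)`) with
  Benjamini–Hochberg adjustment and consensus intersection across contrasts.
- **Overlays** — multi-caller variant merging, mutation burden, gene-fusion
  burden (high-confidence Arriba calls only), GISTIC copy-number gain/loss
  counts, per-group fusion frequencies and single-gene panels.
- **Synthetic cohorts** — a generator with known truth (group signatures,
  ComBat-model batch effects, marker-consistent subtypes, exponential
  survival with subtype medians, variant/fusion/CN tables) so every stage is
  testable without downloads.

## Worked example

```python
import numpy as np, pandas as pd
import brainscape as bs

bundle = bs.simulate_cohort(bs.SimConfig(seed=42))           # two cohorts, 560 samples
tpm = [bs.fpkm_to_tpm(m) for m in bundle.expression.values()]
merged, cohorts = bs.intersect_and_merge(tpm, bs.GeneSpace(frozenset(bundle.gene_space)))
corrected = bs.combat_adjust(bs.log2_transform(merged), bs.BatchDesign(cohorts))
emb = bs.embed(corrected, seed=42)

records = bs.filter_primary_unique(
    [bs.SurvivalRecord(**r) for r in bundle.survival.to_dict("records")],
    bundle.metadata.set_index("sample_id", drop=False),
)
ann = bs.nn_survival_annotate(emb, records)
subtype = pd.Series({r.sample_id: r.subtype for r in records})
print("annotated", int(ann.notna().sum()), "of", len(ann), "glioma samples")
for st in ["GLIOBLASTOMA_IDH_WT", "ASTROCYTOMA_IDH_MUT", "OLIGODENDROGLIOMA_IDH_MUT_CODEL"]:
    vals = ann[subtype[subtype == st].index].dropna()
    print(f"{st:35s} median annotation {np.median(vals):5.2f} y")
```

prints

```
annotated 398 of 400 glioma samples
GLIOBLASTOMA_IDH_WT                 median annotation  1.16 y
ASTROCYTOMA_IDH_MUT                 median annotation  8.33 y
OLIGODENDROGLIOMA_IDH_MUT_CODEL     median annotation 16.50 y
```

The annotation recovers the simulated subtype survival gradient (configured
medians 1.2 / 8 / 14 years) purely from embedding neighborhoods — the same
gradient readout the landscape provides on real cohorts.

The same flow is available from the shell: `brainscape simulate`, `harmonize`,
`correct`, `embed`, `classify`, `survival-annotate`, `pathways`, `overlays`,
and `brainscape run-all --config config.json` for the whole pipeline (the
JSON config points at the input files and per-stage parameters).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
simulates a full multi-cohort bundle from the given seed and runs every
pipeline stage end to end — harmonization, ComBat, UMAP, subtype calls,
survival annotation, GSVA scoring, differential pathway testing and the
omics overlays — writing its result JSON to `--out`.
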