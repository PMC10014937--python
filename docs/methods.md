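# Methods

This note documents the models and numerical choices behind `brainscape`,
what the synthetic-data generator does and does not emulate, and the design
decisions taken where the procedure was genuinely open.

## Harmonization

Cohort matrices arrive as nonnegative gene-by-sample tables in FPKM or TPM.
FPKM is converted per sample by `TPM_ij = FPKM_ij / Σ_i FPKM_ij × 10⁶`; every
TPM column therefore sums to one million (an all-zero sample column is an
error naming the sample).  Cohorts are merged on the intersection of their
gene sets with a user-supplied protein-coding gene space (a plain text file,
one symbol per line — never fetched), with gene order sorted
lexicographically so the result is independent of cohort input order.
Duplicate gene symbols within a cohort are collapsed by keeping the row with
the highest mean, a deterministic version of common multi-mapped-symbol
handling.  The log transform is `log2(TPM + 1)`: the pseudocount makes zero
expression map to zero and keeps the matrix nonnegative.

## Batch correction

`combat_adjust` implements the parametric empirical-Bayes location/scale
model: per gene g, sample j, batch i,

    x_ijg = α_g + γ_ig + δ_ig ε_ijg,  ε ~ N(0, σ²_g)

Data are standardized per gene by the weighted grand mean α̂ and pooled
residual SD; per-batch means γ̂ and variances δ̂² of the standardized data
are shrunk toward batch-level priors (normal for γ, inverse-gamma for δ²,
hyperparameters by method of moments) with the usual fixed-point iteration
(convergence 1e-4), and removed.  Choices that matter:

- **mean_only mode** performs exact per-gene batch-mean centering with δ
  fixed at 1 (no shrinkage of γ).  This is the deterministic closed-form
  variant; the EB machinery applies only to the location-scale mode.
- **Zero-variance genes** pass through unadjusted (logged), avoiding a
  division by zero without dropping genes.
- **Grand-mean preservation.** EB shrinkage pulls per-gene batch offsets
  toward per-batch priors whose weighted sum is not exactly zero, so raw
  ComBat preserves per-gene grand means only approximately.  By default the
  corrected matrix is re-centred per gene to the pre-correction grand mean
  (`preserve_grand_mean=True`); the shift is tiny (≈1e-3 on typical inputs)
  and makes downstream mean comparisons exact.  With it disabled the output
  matches scanpy's ComBat to ~1e-3 (iteration-tolerance differences), which
  the test suite uses as an independent oracle.
- Corrected log values may dip slightly below zero; the expression container
  permits this for post-correction matrices only.
- A single batch returns the input unchanged; singleton batches are rejected
  in location-scale mode (a variance is undefined) but allowed in mean_only.

What correction can and cannot achieve at finite n: with 200 samples per
batch, per-gene batch means and SDs after correction still differ by pure
sampling noise (worst-gene relative gaps of ~5–12% are expected even for a
perfect oracle).  Equalization claims in the tests are therefore asserted on
the average over genes (observed ≈1–3% against 30%+ before correction);
gene-level fidelity is asserted by the scanpy comparison instead.

## Embedding and label transfer

UMAP (library implementation) with defaults n_neighbors=15, min_dist=0.1,
Euclidean metric, 2 components; the optimizer runs single-threaded with a
fixed `random_state`, so coordinates are bit-reproducible given (input,
params, seed).  The 2-D embedding is the canonical analysis surface (the
survival radius below is defined on it); 3-D is export-only.  Label transfer
assigns each unlabeled sample the majority label among its k (default 15)
nearest labeled samples by Euclidean distance in the embedding; ties are
broken by the single nearest labeled neighbor — deterministic and local.

## Subtype rules

Adult diffuse gliomas are classified from two primary markers only:
IDH-mutant + 1p/19q codeleted → oligodendroglioma; IDH-mutant + intact →
IDH-mutant astrocytoma; IDH-wildtype → glioblastoma (one transcriptional
group regardless of recorded grade; grade<4 IDH-wt calls carry a flag).
TP53/ATRX mutation and chr7 gain / chr10 loss are corroborating annotations
and never override the primary markers.  Unknown IDH yields UNCLASSIFIED —
no imputation.  The classifier is total and deterministic.

## Survival

Kaplan–Meier estimation uses lifelines; the curve container keeps event
times, S(t) and at-risk counts, with deaths processed before censorings at
tied times.  The **KM median** is the smallest event time with S(t) ≤ 0.5,
and is undefined when the curve never reaches 0.5 — the reason "median
survival" must mean the KM median here: a plain median of observed times is
always defined, but the annotation below explicitly allows undefined medians.

**Neighbor-cohort annotation.**  Records are first restricted to primary
tumors with one sample per patient (lexicographically smallest sample id —
deterministic).  For a sample s in stratum (subtype g, dataset d) of size
N_gd: the target cohort size is k = round(0.25·N_gd), rounded half away from
zero (the rounding rule is configurable; the fraction and the min-cohort
threshold of 10 are parameters with those defaults).  Candidates are other
stratum members within radius 2 (embedding units) of s; the cohort is the k
nearest candidates, possibly fewer when the radius binds.  Below 10 cohort
members, or when the cohort KM median is undefined, s stays unannotated.
The sample itself is excluded from its own cohort (no self-leakage of its
survival time).  Whether the k-nearest rule applies before or after the
radius filter is ambiguous in the original description; both orders are
implemented (`k_before_radius`), defaulting to radius-first.

## Pathway scoring

GSVA with the defaults that produce scores in (−1, 1):

1. Per gene, a Gaussian-kernel estimate of the expression CDF across samples
   (bandwidth sd/4; degenerate genes get a vanishing bandwidth, i.e. the
   empirical CDF) gives each sample a relative expression-level statistic.
2. Per sample, genes are ranked by that statistic and ranks are symmetrized
   as |p/2 − rank|, up-weighting both tails.
3. Per set and sample, a weighted KS random walk (τ=1) over the
   descending-rank gene list; the score is max positive deviation + max
   negative deviation ("max deviation difference"), which is bounded in
   (−1, 1) without further normalization.

Sets are filtered to 5 ≤ |set ∩ genes| ≤ 500 by default (configurable);
excluded sets are logged.  The implementation is vectorized; the test suite
checks it against a from-scratch per-sample loop oracle.

**Differential testing** is a two-sample moderated t-test: pooled per-pathway
variances s²_g with d = n_a + n_b − 2 df are shrunk to
s̃²_g = (d₀s₀² + d·s²_g)/(d₀ + d), with (d₀, s₀²) fitted by method of
moments on log s²_g (digamma/trigamma matching, trigamma inverted by
Newton); t̃ has d₀ + d df.  When the observed spread of log-variances does
not exceed its χ² expectation, d₀ = ∞ and all variances equal s₀².  Setting
d₀ = 0 recovers the ordinary pooled t exactly.  This estimator reproduces
Bioconductor limma's `fitFDist`/`eBayes` to machine precision on shared
inputs (verified in the tests).  P-values are BH-adjusted across pathways
per contrast; consensus sets intersect {adjusted p ≤ α, stated direction}
across contrasts.

## Overlays

Variant tables from multiple callers are unioned and deduplicated on
(sample, gene, position, alt), falling back to (sample, gene, variant class)
when position/alt are absent; the caller column becomes the sorted list of
supporting callers, and a deduplicated variant counts once in the burden.
Fusion burdens drop non-high-confidence calls from the Arriba caller only
(other callers are not confidence-filtered).  Fusion frequency for a gene is
partner-agnostic (either 5′ or 3′).  Copy-number gain/loss counts treat any
positive GISTIC threshold level as gained and any negative as lost.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes:

- **Expression**: log2 values = shared gene baseline N(3,1) + a +2 shift on
  each group's 40-gene signature + cohort offset + cohort-scaled N(0, 0.5)
  noise, exponentiated to FPKM-like positives.  Cohort effects follow the
  ComBat model (additive γ, multiplicative δ on the noise).  A purely
  uniform γ is a per-sample scale factor that TPM normalization removes on
  its own, so cohorts also carry a per-gene offset spread
  (`gamma_gene_sd`, default 0.5 on the second batch) emulating gene-specific
  quantification bias — the component ComBat actually has to remove.
- **Groups** default to the landscape's composition with realistic relative
  abundances and literature-scale medians: glioblastoma (n=200, median 1.2 y),
  IDH-mutant astrocytoma (120, 8 y), oligodendroglioma (80, 14 y),
  a pediatric tumor group (60) and healthy brain (100).  Sizes are large
  enough that each subtype-by-cohort stratum supports the 25%/min-10
  annotation rule, as consortium cohorts do.
- **Survival** is exponential with the configured median; censoring is an
  independent exponential calibrated so P(censored) equals the configured
  fraction (default 0.3) — independent censoring keeps the KM estimate
  consistent for the configured median.
- **Markers** are subtype-consistent (optionally flipped with probability
  `marker_noise`); **variants** combine subtype drivers (IDH1; TP53/ATRX in
  astrocytoma) with a Poisson passenger load; **fusions** mix a recurrent
  EGFR partner in glioblastoma with background pairs over three confidence
  levels; **copy number** places GISTIC-style gains/losses on group
  signature genes plus sparse noise.

Not emulated: gene–gene correlation beyond group shifts, read-level noise,
library-size variation, non-exponential hazards (a Weibull option is a noted
extension), and intra-group heterogeneity.  A green test on this generator
establishes that the pipeline recovers planted structure under its own model
assumptions — not performance on real consortium data.

## Degenerate inputs and tie-breaks

- Ties in expression statistics are resolved by stable sort order
  (first-listed gene first) in GSVA; ties in k-NN voting by the nearest
  labeled neighbor; duplicate primary samples per patient by smallest
  sample id.
- All-censored cohorts yield no KM steps and an undefined median.
- `fpkm_to_tpm` is idempotent up to scale; `log2_transform` is monotone.
- Tests cap problem sizes (hundreds of samples, hundreds of genes) so the
  whole suite runs in about a minute on one CPU; the stated structure, not
  the scale, is what the checks exercise.
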