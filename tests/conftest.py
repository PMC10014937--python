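import numpy as np
import pandas as pd
import pytest

import brainscape as bs


def make_matrix(values, genes=None, samples=None, unit=bs.Unit.TPM, dataset="D"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=genes, columns=samples)
    return bs.ExpressionMatrix(df, unit, dataset)


@pytest.fixture(scope="session")
def tiny_config():
    """A small, fast bundle: strata intentionally below the survival
    annotation thresholds are irrelevant for these unit fixtures."""
    groups = [
        bs.GroupSpec("glioblastoma", 30, subtype=bs.simulate.GBM,
                     median_survival_years=1.2, mutation_rate=6.0,
                     fusion_rate=1.0, fusion_gene="EGFR",
                     cn_gain_genes=10, cn_loss_genes=10),
        bs.GroupSpec("astrocytoma", 25, subtype=bs.simulate.ASTRO,
                     median_survival_years=8.0),
        bs.GroupSpec("oligodendroglioma", 20, subtype=bs.simulate.OLIGO,
                     median_survival_years=14.0),
        bs.GroupSpec("healthy_brain", 25, mutation_rate=0.0, fusion_rate=0.0),
    ]
    return bs.SimConfig(n_genes=200, groups=groups, signature_size=20, seed=11)


@pytest.fixture(scope="session")
def tiny_bundle(tiny_config):
    return bs.simulate_cohort(tiny_config)


@pytest.fixture(scope="session")
def corrected_tiny(tiny_bundle):
    tpms = [bs.fpkm_to_tpm(m) for m in tiny_bundle.expression.values()]
    merged, datasets = bs.intersect_and_merge(
        tpms, bs.GeneSpace(frozenset(tiny_bundle.gene_space))
    )
    logx = bs.log2_transform(merged)
    return bs.combat_adjust(logx, bs.BatchDesign(datasets)), datasets


@pytest.fixture(scope="session")
def tiny_embedding(corrected_tiny):
    corrected, _ = corrected_tiny
    return bs.embed(corrected, bs.EmbedParams(), seed=5)
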