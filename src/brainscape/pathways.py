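"""Single-sample gene-set enrichment (GSVA) and moderated-t differential
pathway testing.

GSVA turns a log-expression matrix into per-sample pathway scores in
[-1, 1]: a score near 1 means the pathway's genes sit at the top of that
sample's expression ranking (up-regulation), near -1 the bottom
(down-regulation).  The algorithm follows the published default variant:

1. For each gene, a kernel estimate of the expression CDF across samples
   (Gaussian kernel, bandwidth sd/4) gives a relative expression-level
   statistic per sample.
2. Within each sample, genes are ranked by that statistic and the ranks are
   symmetrized around the middle of the list, up-weighting both tails.
3. For each gene set, a weighted Kolmogorov-Smirnov-like random walk (tau=1)
   runs down the sample's ranked gene list; the score is the maximum
   positive deviation plus the maximum negative deviation ("max deviation
   difference"), which lies in (-1, 1).

Differential testing between phenotype groups uses a two-sample moderated
t-statistic: per-pathway pooled variances are shrunk toward a common prior
variance s0^2 with d0 prior degrees of freedom, both estimated from the
marginal distribution of log sample variances (method of moments via
digamma/trigamma matching), and p-values are Benjamini-Hochberg adjusted
across pathways.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "gsva_scores",
    "moderated_t_test",
    "consensus_pathways",
]


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"empty gene set: {name}")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def filter_by_size(
        self, genes_present: set[str], min_size: int, max_size: int
    ) -> "GeneSetCollection":
        kept: dict[str, frozenset[str]] = {}
        for name, members in self.sets.items():
            overlap = members & genes_present
            if min_size <= len(overlap) <= max_size:
                kept[name] = frozenset(overlap)
            else:
                logger.warning(
                    "gene set %s excluded by size filter (%d genes in matrix)",
                    name,
                    len(overlap),
                )
        return GeneSetCollection(
            kept, {n: self.descriptions.get(n, "") for n in kept}
        )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: tab-separated name, description, genes...

    Duplicate genes within a line are deduplicated; duplicate set names and
    lines with fewer than three fields are errors.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        name, desc, *genes = fields
        genes = [g for g in genes if g]
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
        sets[name] = frozenset(genes)
        descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def _kernel_cdf_statistic(X: np.ndarray, chunk: int = 128) -> np.ndarray:
    """Gaussian-kernel estimate of each gene's expression CDF across samples.

    z[g, j] = mean_k Phi((x[g, j] - x[g, k]) / h_g), h_g = sd_g / 4.
    Degenerate (constant) genes get ties at 0.5 via a vanishing bandwidth.
    """
    n_genes, n = X.shape
    sd = X.std(axis=1, ddof=1) if n > 1 else np.ones(n_genes)
    h = np.maximum(sd / 4.0, 1e-12)
    Z = np.empty_like(X, dtype=float)
    for start in range(0, n_genes, chunk):
        sl = slice(start, min(start + chunk, n_genes))
        diff = (X[sl, :, None] - X[sl, None, :]) / h[sl, None, None]
        Z[sl] = special.ndtr(diff).mean(axis=2)
    return Z


def _symmetric_ranks(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample gene ordering (descending statistic) and tail-symmetric
    rank weights |p/2 - rank|, where the top gene has rank p."""
    p, n = Z.shape
    order = np.argsort(-Z, axis=0, kind="stable")  # position 0 = highest statistic
    ranks = np.empty_like(order)
    pos = np.arange(p)[:, None]
    np.put_along_axis(ranks, order, p - pos, axis=0)  # top gene -> rank p
    weights = np.abs(ranks - p / 2.0)
    return order, weights


def _walk_scores(
    order: np.ndarray, weights: np.ndarray, member_mask: np.ndarray, tau: float = 1.0
) -> np.ndarray:
    """Max-deviation-difference KS walk score for one gene set, all samples."""
    p, n = order.shape
    in_set = member_mask[order]  # (p, n): is the gene at each position in the set
    w = np.take_along_axis(weights, order, axis=0) ** tau
    w_in = np.where(in_set, w, 0.0)
    denom_in = w_in.sum(axis=0)
    step_out = (~in_set).astype(float) / (p - member_mask.sum())
    walk = np.cumsum(w_in / np.where(denom_in > 0, denom_in, 1.0), axis=0) - np.cumsum(
        step_out, axis=0
    )
    return walk.max(axis=0).clip(min=0.0) + walk.min(axis=0).clip(max=0.0)


def gsva_scores(
    m: ExpressionMatrix,
    sets: GeneSetCollection,
    min_size: int = 5,
    max_size: int = 500,
    tau: float = 1.0,
) -> pd.DataFrame:
    """GSVA pathway-by-sample score matrix with values in [-1, 1].

    Sets are restricted to genes present in the matrix and filtered to
    ``min_size <= |set ∩ genes| <= max_size``.
    """
    if m.shape[1] < 3:
        raise ValueError("GSVA needs at least 3 samples")
    genes = m.genes
    usable = sets.filter_by_size(set(genes), min_size, max_size)
    if len(usable) == 0:
        raise ValueError("no gene set survives the size filter")
    X = m.values.to_numpy(dtype=float)
    Z = _kernel_cdf_statistic(X)
    order, weights = _symmetric_ranks(Z)
    gene_pos = {g: i for i, g in enumerate(genes)}
    scores = {}
    for name, members in usable.sets.items():
        mask = np.zeros(len(genes), dtype=bool)
        mask[[gene_pos[g] for g in members]] = True
        scores[name] = _walk_scores(order, weights, mask, tau=tau)
    out = pd.DataFrame(scores, index=m.samples).T
    out.index.name = "pathway"
    return out


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior for sample variances.

    Under the hierarchical model s2 ~ s0^2 * chi2_df/df / (chi2_d0/d0), the
    log variances satisfy  Var(log s2) = trigamma(df/2) + trigamma(d0/2) and
    E(log s2) = log s0^2 + digamma(df/2) - log(df/2)
                        - digamma(d0/2) + log(d0/2).
    Returns (d0, s0_squared); d0 may be inf (no excess spread).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = z.var(ddof=1) if len(z) > 1 else 0.0
    excess = e_var - special.polygamma(1, df / 2.0)
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0_sq)


def moderated_t_test(
    scores: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    d0: float | None = None,
    s0_squared: float | None = None,
) -> pd.DataFrame:
    """Two-group moderated t-test per pathway with BH adjustment.

    ``d0``/``s0_squared`` override the empirical-Bayes hyperprior (``d0=0``
    recovers the ordinary pooled two-sample t-test exactly).

    Returns a DataFrame indexed by pathway with columns mean_diff (A - B),
    t, p_value, p_adjusted and direction ('up'/'down' in group A).
    """
    group_a, group_b = list(group_a), list(group_b)
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:5]}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    for s in group_a + group_b:
        if s not in scores.columns:
            raise ValueError(f"sample {s!r} not in score matrix")
    A = scores[group_a].to_numpy(dtype=float)
    B = scores[group_b].to_numpy(dtype=float)
    na, nb = A.shape[1], B.shape[1]
    d = na + nb - 2
    diff = A.mean(axis=1) - B.mean(axis=1)
    ss = ((A - A.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (B - B.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / d
    if d0 is None or s0_squared is None:
        d0_hat, s0_hat = estimate_variance_prior(s2, d)
        d0 = d0_hat if d0 is None else d0
        s0_squared = s0_hat if s0_squared is None else s0_squared
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_squared)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_squared + d * s2) / (d0 + d)
        df_total = d0 + d
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p = np.clip(p, 0.0, 1.0)
    p_adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "mean_diff": diff,
            "t": t,
            "p_value": p,
            "p_adjusted": p_adj,
            "direction": np.where(diff >= 0, "up", "down"),
        },
        index=scores.index,
    )


def consensus_pathways(
    tables: list[pd.DataFrame], alpha: float, direction: str
) -> set[str]:
    """Pathways significant (BH-adjusted p <= alpha) in the stated direction
    in every table."""
    if not tables:
        raise ValueError("need at least one table")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    result: set[str] | None = None
    for table in tables:
        hits = set(
            table.index[
                (table["p_adjusted"] <= alpha) & (table["direction"] == direction)
            ]
        )
        result = hits if result is None else result & hits
    return result or set()
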