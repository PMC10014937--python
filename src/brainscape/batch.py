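"""Empirical-Bayes batch correction (parametric ComBat) for log-expression.

The model for gene g, sample j in batch i is

    x_ijg = alpha_g + gamma_ig + delta_ig * eps_ijg

with additive batch offsets gamma and multiplicative batch scales delta.
Per-gene batch estimates are shrunk toward batch-level priors (normal for
gamma, inverse-gamma for delta^2, hyperparameters by method of moments) and
then removed, restoring the grand mean and pooled scale.  ``mean_only`` mode
fixes delta at 1 and corrects location only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, Unit

logger = logging.getLogger(__name__)

__all__ = ["BatchMode", "BatchDesign", "combat_adjust"]


class BatchMode(str, Enum):
    MEAN_ONLY = "mean_only"
    LOCATION_SCALE_EB = "location_scale_eb"


@dataclass
class BatchDesign:
    """Sample-to-batch assignment plus the correction mode."""

    batches: pd.Series  # sample_id -> batch label
    mode: BatchMode = BatchMode.LOCATION_SCALE_EB

    @classmethod
    def from_csv(cls, path: str | Path, mode: BatchMode | str = BatchMode.LOCATION_SCALE_EB) -> "BatchDesign":
        df = pd.read_csv(path, dtype=str)
        if not {"sample_id", "batch"} <= set(df.columns):
            raise ValueError("batch design CSV needs columns sample_id, batch")
        return cls(df.set_index("sample_id")["batch"], BatchMode(mode))

    def validate_against(self, samples: list[str]) -> pd.Series:
        missing = [s for s in samples if s not in self.batches.index]
        if missing:
            raise ValueError(f"samples without batch label: {missing[:5]}")
        labels = self.batches.loc[samples]
        counts = labels.value_counts()
        if self.mode is BatchMode.LOCATION_SCALE_EB and (counts < 2).any():
            singletons = counts[counts < 2].index.tolist()
            raise ValueError(
                f"batch(es) with a single sample in location_scale_eb mode: {singletons}"
            )
        return labels


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _it_sol(s_data, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4, max_iter=500):
    """Iterative solution of the EB posterior for one batch (parametric prior)."""
    n = s_data.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = ((s_data - g_new[:, None]) ** 2).sum(axis=1)
        d_new = _postvar(sum2, n, a, b)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def combat_adjust(
    m: ExpressionMatrix,
    design: BatchDesign,
    preserve_grand_mean: bool = True,
) -> ExpressionMatrix:
    """Remove batch location/scale effects from a log2(TPM) matrix.

    Zero-variance genes are passed through unadjusted (logged).  With
    ``preserve_grand_mean`` the corrected matrix is re-centred per gene to the
    pre-correction weighted grand mean, making mean preservation exact rather
    than approximate under EB shrinkage.

    Output keeps the gene and sample order of the input.
    """
    if m.unit is not Unit.LOG2TPM:
        raise ValueError(f"expected LOG2TPM input, got {m.unit.value}")
    labels = design.validate_against(m.samples)
    X = m.values.to_numpy(dtype=float)
    batch_names = list(pd.unique(labels))
    if len(batch_names) == 1:
        # nothing to correct against
        return ExpressionMatrix(
            m.values.copy(), m.unit, m.dataset, allow_negative=m.allow_negative
        )

    idx_per_batch = [np.flatnonzero((labels == b).to_numpy()) for b in batch_names]
    n_per_batch = np.array([len(ix) for ix in idx_per_batch])
    N = X.shape[1]

    # per-gene per-batch means; weighted grand mean; pooled residual variance
    batch_means = np.stack([X[:, ix].mean(axis=1) for ix in idx_per_batch], axis=1)
    alpha = batch_means @ (n_per_batch / N)
    resid = X.copy()
    for i, ix in enumerate(idx_per_batch):
        resid[:, ix] -= batch_means[:, [i]]
    var_pooled = (resid**2).sum(axis=1) / N
    zero_var = var_pooled <= 0
    if zero_var.any():
        logger.info("%d zero-variance gene(s) left unadjusted", int(zero_var.sum()))
    sd = np.sqrt(np.where(zero_var, 1.0, var_pooled))

    Z = (X - alpha[:, None]) / sd[:, None]

    adjusted = Z.copy()
    mean_only = design.mode is BatchMode.MEAN_ONLY
    for i, ix in enumerate(idx_per_batch):
        Zi = Z[:, ix]
        n_i = len(ix)
        g_hat = Zi.mean(axis=1)
        g_bar = g_hat.mean()
        t2 = g_hat.var(ddof=1) if len(g_hat) > 1 else 0.0
        if mean_only:
            # exact per-gene batch-mean centering; delta fixed at 1
            g_star = g_hat
            d_star = np.ones_like(g_hat)
        else:
            d_hat = Zi.var(axis=1, ddof=1)
            m_d, v_d = d_hat.mean(), d_hat.var(ddof=1) if len(d_hat) > 1 else 0.0
            if v_d > 0 and t2 > 0:
                a = (2.0 * v_d + m_d**2) / v_d  # inverse-gamma shape
                b = (m_d * v_d + m_d**3) / v_d  # inverse-gamma rate
                g_star, d_star = _it_sol(Zi, g_hat, d_hat, g_bar, t2, a, b)
            else:
                # degenerate prior (e.g. one gene): no shrinkage
                g_star, d_star = g_hat, np.maximum(d_hat, 1e-12)
        adjusted[:, ix] = (Zi - g_star[:, None]) / np.sqrt(d_star)[:, None]

    out = adjusted * sd[:, None] + alpha[:, None]
    out[zero_var, :] = X[zero_var, :]
    if preserve_grand_mean:
        out = out - out.mean(axis=1, keepdims=True) + alpha[:, None]
        out[zero_var, :] = X[zero_var, :]
    # corrected log values may dip slightly below zero; skip the nonnegativity check
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix.corrected(values, m.unit, m.dataset)
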