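"""UMAP embedding of the corrected expression matrix and neighbor-based
label transfer.

The embedding treats samples as points in gene space (all protein-coding
genes, log2(TPM+1), batch-corrected) and projects them to 2-D or 3-D with
UMAP.  Determinism is part of the contract: the same input, parameters and
seed always yield the same coordinates.  Unlabeled samples (e.g. cohorts
lacking molecular subtyping) can then inherit labels from their nearest
labeled neighbors in embedding space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .io import ExpressionMatrix

__all__ = ["EmbedParams", "Embedding", "embed", "knn_label_impute"]


@dataclass(frozen=True)
class EmbedParams:
    """UMAP hyperparameters (library defaults; the 2-D embedding is the
    canonical analysis surface, 3-D is export-only)."""

    n_components: int = 2
    n_neighbors: int = 15
    min_dist: float = 0.1
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        if self.n_components not in (2, 3):
            raise ValueError("n_components must be 2 or 3")
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be positive")
        if not (0.0 <= self.min_dist < 1.0):
            raise ValueError("min_dist must be in [0, 1)")


@dataclass
class Embedding:
    """Per-sample coordinates plus the parameters and seed that produced them."""

    coords: pd.DataFrame  # index sample ids, columns x, y[, z]
    seed: int
    params: EmbedParams = field(default_factory=EmbedParams)

    def __post_init__(self) -> None:
        if not np.isfinite(self.coords.to_numpy()).all():
            raise ValueError("non-finite embedding coordinates")
        if self.coords.shape[1] != self.params.n_components:
            raise ValueError("coordinate dimension does not match params")

    @property
    def samples(self) -> list[str]:
        return list(self.coords.index)

    def to_csv(self, path: str | Path) -> None:
        out = self.coords.copy()
        out.index.name = "sample_id"
        out.to_csv(path)
        sidecar = Path(path).with_suffix(".json")
        sidecar.write_text(
            json.dumps({"seed": self.seed, "params": asdict(self.params)}, indent=2)
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "Embedding":
        coords = pd.read_csv(path, index_col="sample_id")
        side = json.loads(Path(path).with_suffix(".json").read_text())
        return cls(coords=coords, seed=side["seed"], params=EmbedParams(**side["params"]))


def embed(
    m: ExpressionMatrix, params: EmbedParams | None = None, seed: int = 0
) -> Embedding:
    """Embed samples (columns of ``m``) into ``params.n_components`` dimensions.

    Deterministic given (input, params, seed): the UMAP optimizer is run
    single-threaded with a fixed random state.
    """
    import umap  # deferred: numba compilation is expensive at import time

    params = params or EmbedParams()
    n_samples = m.shape[1]
    if n_samples < params.n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors+1={params.n_neighbors + 1} samples, got {n_samples}"
        )
    X = m.values.to_numpy(dtype=np.float32).T
    if not np.isfinite(X).all():
        raise ValueError("non-finite expression values")
    reducer = umap.UMAP(
        n_components=params.n_components,
        n_neighbors=params.n_neighbors,
        min_dist=params.min_dist,
        metric=params.metric,
        random_state=seed,
        n_jobs=1,
    )
    coords = reducer.fit_transform(X).astype(np.float64)
    cols = ["x", "y", "z"][: params.n_components]
    return Embedding(
        coords=pd.DataFrame(coords, index=m.samples, columns=cols),
        seed=seed,
        params=params,
    )


def knn_label_impute(
    e: Embedding, labels: dict[str, str] | pd.Series, k: int = 15
) -> pd.Series:
    """Transfer labels to unlabeled samples by k-nearest-neighbor majority vote.

    Each unlabeled sample receives the majority label among its ``k`` nearest
    labeled samples (Euclidean distance in the embedding); ties are broken by
    the label of the single nearest labeled neighbor.  Labeled samples keep
    their labels.
    """
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    labels = labels.dropna()
    labeled = [s for s in e.samples if s in labels.index]
    if not labeled:
        raise ValueError("no labeled samples")
    if k < 1:
        raise ValueError("k must be positive")
    if k > len(labeled):
        raise ValueError(f"k={k} exceeds number of labeled samples ({len(labeled)})")
    unlabeled = [s for s in e.samples if s not in labels.index]
    out = pd.Series(index=e.samples, dtype=object, name="label")
    out.loc[labeled] = labels.loc[labeled]
    if unlabeled:
        nn = NearestNeighbors(n_neighbors=k).fit(e.coords.loc[labeled].to_numpy())
        dist, idx = nn.kneighbors(e.coords.loc[unlabeled].to_numpy())
        labeled_arr = np.asarray(labels.loc[labeled])
        for row, sample in enumerate(unlabeled):
            votes = labeled_arr[idx[row]]
            values, counts = np.unique(votes, return_counts=True)
            winners = values[counts == counts.max()]
            if len(winners) == 1:
                out.loc[sample] = winners[0]
            else:
                # tie: the nearest labeled neighbor decides
                out.loc[sample] = labeled_arr[idx[row][np.argmin(dist[row])]]
    return out
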