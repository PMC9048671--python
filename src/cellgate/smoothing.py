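"""kNN smoothing of signature scores.

Single-cell measurements are sparse: a marker can drop out of a cell that
truly expresses it. Averaging each cell's signature score over its k
nearest neighbours in a low-dimensional embedding borrows strength from
transcriptionally similar cells and shrinks within-population score
variance without moving scores outside the convex hull of the raw values.

The neighbour space is the conventional one: per-cell total-count scaling
to a fixed target sum, log1p, selection of the most variable features,
per-feature standardisation, and a truncated principal-component
projection. Everything is deterministic given the seed (exact kNN, full
SVD), so repeated runs are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .data_model import FeatureMatrix
from .scoring import ScoreMatrix

__all__ = [
    "SmoothingParams",
    "NeighborGraph",
    "embed_cells",
    "knn_graph",
    "smooth_scores",
    "KNNSmoother",
]


@dataclass
class SmoothingParams:
    """Neighbour-space configuration.

    k : neighbourhood size (the cell itself is included, so k=1 makes
        smoothing the identity).
    n_hvg : number of most-variable features kept (ADT panels skip
        selection — their feature spaces are already small).
    n_pcs : embedding dimensionality (capped by matrix rank).
    target_sum : per-cell count total after scaling.
    """

    k: int = 10
    n_hvg: int = 800
    n_pcs: int = 30
    target_sum: float = 10_000.0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n_hvg < 2 or self.n_pcs < 1:
            raise ValueError("n_hvg must be >= 2 and n_pcs >= 1")


@dataclass
class NeighborGraph:
    """For each cell, the indices of its k nearest cells (self first)."""

    k: int
    neighbor_indices: np.ndarray
    embedding_dims: int

    def __post_init__(self) -> None:
        self.neighbor_indices = np.asarray(self.neighbor_indices, dtype=int)
        if self.neighbor_indices.ndim != 2:
            raise ValueError("neighbor_indices must be 2-D (cells x k)")
        n = self.neighbor_indices.shape[0]
        if self.neighbor_indices.shape[1] != min(self.k, n):
            raise ValueError("each neighbor list must have length min(k, n)")
        if n and not (self.neighbor_indices[:, 0] == np.arange(n)).all():
            raise ValueError("first neighbor must be the cell itself")
        if n and (
            self.neighbor_indices.min() < 0 or self.neighbor_indices.max() >= n
        ):
            raise ValueError("neighbor index out of range")

    @property
    def n_cells(self) -> int:
        return self.neighbor_indices.shape[0]


def _log_normalise(matrix: FeatureMatrix, target_sum: float) -> sp.csr_matrix:
    X = matrix.values.astype(float).tocsr()
    totals = np.asarray(X.sum(axis=1)).ravel()
    scale = np.divide(
        target_sum, totals, out=np.zeros_like(totals), where=totals > 0
    )
    X = sp.diags(scale) @ X
    X.data = np.log1p(X.data)
    return X.tocsr()


def _feature_variances(X: sp.csr_matrix) -> np.ndarray:
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    var = np.maximum(sq - mean**2, 0.0)
    # scale-relative floor: a constant feature's variance is pure
    # floating-point jitter and must not count as variable
    var[var <= 1e-10 * np.maximum(mean**2, 1e-30)] = 0.0
    return var


def embed_cells(
    matrix: FeatureMatrix,
    n_hvg: int = 800,
    n_pcs: int = 30,
    seed: int = 0,
    target_sum: float = 10_000.0,
) -> np.ndarray:
    """Low-dimensional embedding used to define cell neighbourhoods.

    Deterministic given the seed; two identical cells receive identical
    embedding rows.
    """
    if matrix.n_cells < 2:
        raise ValueError("embedding needs at least 2 cells")
    X = _log_normalise(matrix, target_sum)
    variances = _feature_variances(X)
    variable = np.flatnonzero(variances > 0)
    if variable.size < 2:
        raise ValueError("fewer than 2 features with nonzero variance")
    if matrix.modality_tag != "adt" and variable.size > n_hvg:
        # stable top-k: sort by (-variance, index)
        order = np.lexsort((variable, -variances[variable]))
        keep = np.sort(variable[order[:n_hvg]])
    else:
        keep = variable
    dense = np.asarray(X[:, keep].todense(), dtype=float)
    dense -= dense.mean(axis=0)
    sd = dense.std(axis=0)
    sd[sd == 0] = 1.0
    dense /= sd
    n_comp = int(min(n_pcs, dense.shape[1], matrix.n_cells - 1))
    pca = PCA(n_components=n_comp, svd_solver="full", random_state=seed)
    return pca.fit_transform(dense)


def knn_graph(embedding: np.ndarray, k: int) -> NeighborGraph:
    """Exact Euclidean kNN with the cell itself as first neighbour.

    Distance ties are broken by lower cell index (stable sort).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    emb = np.asarray(embedding, dtype=float)
    if emb.ndim != 2:
        raise ValueError("embedding must be 2-D")
    n = emb.shape[0]
    m = min(k, n)
    dist = cdist(emb, emb)
    # force self strictly first, then stable argsort breaks ties by index
    np.fill_diagonal(dist, -1.0)
    order = np.argsort(dist, axis=1, kind="stable")
    return NeighborGraph(
        k=k, neighbor_indices=order[:, :m], embedding_dims=emb.shape[1]
    )


def smooth_scores(scores: ScoreMatrix, graph: NeighborGraph) -> ScoreMatrix:
    """Replace each cell's score by the mean over its neighbour list."""
    if scores.smoothed:
        raise ValueError("scores are already smoothed")
    if graph.n_cells != len(scores.cell_ids):
        raise ValueError(
            f"graph covers {graph.n_cells} cells but scores cover "
            f"{len(scores.cell_ids)}"
        )
    smoothed = scores.values[graph.neighbor_indices].mean(axis=1)
    return ScoreMatrix(
        values=smoothed,
        signature_names=list(scores.signature_names),
        cell_ids=scores.cell_ids,
        smoothed=True,
    )


class KNNSmoother(BaseEstimator):
    """Sklearn-style smoother: fit builds the graph, transform averages.

    fit(X) with X a FeatureMatrix computes ``embedding_`` and ``graph_``;
    transform accepts a ScoreMatrix (returning a smoothed ScoreMatrix) or
    a plain cells x signatures array (returning an array).
    """

    def __init__(
        self,
        k: int = 10,
        n_hvg: int = 800,
        n_pcs: int = 30,
        target_sum: float = 10_000.0,
        random_state: int = 0,
    ):
        self.k = k
        self.n_hvg = n_hvg
        self.n_pcs = n_pcs
        self.target_sum = target_sum
        self.random_state = random_state

    def fit(self, X: FeatureMatrix, y=None):
        self.embedding_ = embed_cells(
            X,
            n_hvg=self.n_hvg,
            n_pcs=self.n_pcs,
            seed=self.random_state,
            target_sum=self.target_sum,
        )
        self.graph_ = knn_graph(self.embedding_, self.k)
        return self

    def transform(self, scores):
        if isinstance(scores, ScoreMatrix):
            return smooth_scores(scores, self.graph_)
        arr = np.asarray(scores, dtype=float)
        return arr[self.graph_.neighbor_indices].mean(axis=1)
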