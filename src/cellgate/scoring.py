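"""Per-cell rank-based signature scoring.

Each cell's features are ranked by descending value (ties averaged), with
every rank beyond ``max_rank`` collapsed to ``max_rank + 1``. For a
signature of n positive genes with capped ranks r_1..r_n, the score is
the complement of the normalised Mann-Whitney U statistic::

    R = sum(r_i);  U = R - n(n+1)/2;  S = 1 - U / (n * max_rank)

so a signature occupying the top n ranks scores exactly 1 and one whose
genes all fall past the rank cap scores 0. Because only ranks enter, the
score is invariant to any strictly monotone per-cell transform of the
raw values — no prior normalisation is required.

Negated genes (``CD3D-``) within a signature are scored identically as a
group and subtracted: ``score = max(0, S_pos - w_neg * S_neg)``, clipped
to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

from .data_model import FeatureMatrix
from .gating_model import GatingModel, Signature

__all__ = [
    "ScoringParams",
    "ScoreMatrix",
    "rank_features",
    "ucell_score",
    "score_signatures",
    "UCellScorer",
]

DEFAULT_MAX_RANK = 1500


@dataclass
class ScoringParams:
    """Knobs of the rank scorer.

    max_rank : rank cap; ranks past it carry no information. 1500 suits
        transcriptome-scale feature spaces; for small feature spaces
        (e.g. ADT panels) the effective cap is lowered automatically to
        ``n_features - 1`` so that it remains attainable.
    w_neg : weight of the negated-gene score subtraction.
    """

    max_rank: int = DEFAULT_MAX_RANK
    w_neg: float = 1.0

    def __post_init__(self) -> None:
        if self.max_rank < 1:
            raise ValueError("max_rank must be >= 1")
        if self.w_neg < 0:
            raise ValueError("w_neg must be >= 0")


@dataclass
class ScoreMatrix:
    """Cells x signatures scores in [0, 1], raw or kNN-smoothed."""

    values: np.ndarray
    signature_names: list
    cell_ids: np.ndarray
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("score matrix must be 2-D")
        if self.values.shape != (len(self.cell_ids), len(self.signature_names)):
            raise ValueError(
                f"score shape {self.values.shape} inconsistent with "
                f"{len(self.cell_ids)} cells x "
                f"{len(self.signature_names)} signatures"
            )
        if self.values.size and (
            self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9
        ):
            raise ValueError("scores must lie in [0, 1]")

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.signature_names.index(name)
        except ValueError:
            raise KeyError(f"no signature column {name!r}") from None
        return self.values[:, j]


def rank_features(cell_expression: np.ndarray, max_rank: int) -> np.ndarray:
    """Descending mean-tie ranks of one cell's features, capped.

    Ranks strictly greater than ``max_rank`` are replaced by
    ``max_rank + 1`` (after tie averaging).
    """
    if max_rank < 1:
        raise ValueError("max_rank must be >= 1")
    x = np.asarray(cell_expression, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D expression vector")
    ranks = rankdata(-x, method="average")
    return np.where(ranks > max_rank, max_rank + 1.0, ranks)


def _capped_rank_block(block: np.ndarray, max_rank: int) -> np.ndarray:
    ranks = rankdata(-block, method="average", axis=1)
    np.minimum(ranks, max_rank + 1.0, out=ranks)
    # tie-averaged ranks can land between max_rank and max_rank+1; those
    # too have fallen past the cap
    ranks[ranks > max_rank] = max_rank + 1.0
    return ranks


def _group_score(ranks: np.ndarray, cols: Sequence[int], max_rank: int) -> np.ndarray:
    n = len(cols)
    R = ranks[:, list(cols)].sum(axis=1)
    U = R - n * (n + 1) / 2.0
    return 1.0 - U / (n * max_rank)


def _resolve_signature(
    signature: Signature, index: dict, case_insensitive: bool
) -> tuple:
    if case_insensitive:
        folded = {k.casefold(): v for k, v in index.items()}

        def lookup(sym: str):
            return folded.get(sym.strip().casefold())
    else:

        def lookup(sym: str):
            return index.get(sym.strip())

    pos, neg, absent = [], [], []
    for gene in signature.genes:
        j = lookup(gene.symbol)
        if j is None:
            absent.append(gene.to_token())
        elif gene.sign > 0:
            pos.append(j)
        else:
            neg.append(j)
    if absent:
        warnings.warn(
            f"signature {signature.name!r}: dropping genes absent from the "
            f"matrix: {absent}"
        )
    if not pos:
        raise ValueError(
            f"signature {signature.name!r} has no usable positive genes "
            "in this feature space"
        )
    return pos, neg


def score_signatures(
    matrix: FeatureMatrix,
    signatures: Sequence[Signature],
    params: ScoringParams | None = None,
    chunk_size: int = 512,
    case_insensitive: bool = False,
) -> ScoreMatrix:
    """Raw (unsmoothed) signature scores for every cell.

    Ranking is done on raw values in chunks of cells; the matrix is
    densified one chunk at a time.
    """
    params = params or ScoringParams()
    max_rank = min(params.max_rank, matrix.n_features - 1)
    if max_rank < 1:
        raise ValueError("matrix needs at least 2 features to rank")
    index = matrix.feature_index()
    resolved = [
        _resolve_signature(sig, index, case_insensitive) for sig in signatures
    ]
    n_cells = matrix.n_cells
    out = np.empty((n_cells, len(signatures)), dtype=float)
    for start in range(0, n_cells, chunk_size):
        stop = min(start + chunk_size, n_cells)
        block = np.asarray(matrix.values[start:stop].todense(), dtype=float)
        ranks = _capped_rank_block(block, max_rank)
        for j, (pos, neg) in enumerate(resolved):
            s = _group_score(ranks, pos, max_rank)
            if neg:
                s = s - params.w_neg * _group_score(ranks, neg, max_rank)
            out[start:stop, j] = s
    np.clip(out, 0.0, 1.0, out=out)
    return ScoreMatrix(
        values=out,
        signature_names=[sig.name for sig in signatures],
        cell_ids=matrix.cell_ids,
        smoothed=False,
    )


def ucell_score(
    matrix: FeatureMatrix,
    signature: Signature,
    params: ScoringParams | None = None,
) -> np.ndarray:
    """Score one signature; returns a vector over cells."""
    return score_signatures(matrix, [signature], params).values[:, 0]


class UCellScorer(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer mapping a FeatureMatrix to signature scores.

    Parameters
    ----------
    signatures : list of Signature, or a GatingModel whose signatures are
        scored.
    max_rank, w_neg : see :class:`ScoringParams`.
    case_insensitive : case-folded gene matching fallback (off by default).
    """

    def __init__(
        self,
        signatures=None,
        max_rank: int = DEFAULT_MAX_RANK,
        w_neg: float = 1.0,
        case_insensitive: bool = False,
    ):
        self.signatures = signatures
        self.max_rank = max_rank
        self.w_neg = w_neg
        self.case_insensitive = case_insensitive

    def _signature_list(self) -> list:
        if isinstance(self.signatures, GatingModel):
            return list(self.signatures.signatures)
        if not self.signatures:
            raise ValueError("no signatures configured")
        return list(self.signatures)

    def fit(self, X: FeatureMatrix, y=None):
        sigs = self._signature_list()
        index = X.feature_index()
        for sig in sigs:
            _resolve_signature(sig, index, self.case_insensitive)
        self.signature_names_ = [s.name for s in sigs]
        self.n_features_in_ = X.n_features
        return self

    def transform(self, X: FeatureMatrix) -> np.ndarray:
        return self.score_matrix(X).values

    def score_matrix(self, X: FeatureMatrix) -> ScoreMatrix:
        return score_signatures(
            X,
            self._signature_list(),
            ScoringParams(max_rank=self.max_rank, w_neg=self.w_neg),
            case_insensitive=self.case_insensitive,
        )
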