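"""Hierarchical thresholded gating: pure/impure calls per cell.

Each gating level applies a fixed threshold to kNN-smoothed signature
scores: a cell passes iff the maximum over the level's positive
signatures is >= ``pos_threshold`` (a cell exactly at threshold is
"detected", hence inclusive) AND every ``use_as=negative`` signature is
strictly below ``neg_threshold`` (any exclusion marker vetoes). Level k
is evaluated only on cells that passed level k-1, and by default the
embedding, neighbour graph and smoothing are recomputed on the surviving
subset first — neighbourhoods among immune cells only, when purifying
macrophages from immune cells. The final verdict is "Pure" iff a cell
passed every level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .data_model import FeatureMatrix
from .gating_model import GatingLevel, GatingModel, validate_against_features
from .scoring import DEFAULT_MAX_RANK, ScoreMatrix, ScoringParams, score_signatures
from .smoothing import SmoothingParams, embed_cells, knn_graph, smooth_scores

__all__ = ["GateParams", "PurityCall", "gate_level", "run_gating", "GatePurifier"]

PURE = "Pure"
IMPURE = "Impure"


@dataclass
class GateParams:
    """Decision thresholds on smoothed scores, both in [0, 1]."""

    pos_threshold: float = 0.2
    neg_threshold: float = 0.2
    recompute_graph_per_level: bool = True

    def __post_init__(self) -> None:
        for name in ("pos_threshold", "neg_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class PurityCall:
    """Per-cell, per-level pass flags plus the final Pure/Impure label.

    Invariants: ``final == "Pure"`` iff all levels are True for that
    cell, and a cell false at level k is false at every later level.
    """

    cell_ids: np.ndarray
    per_level: np.ndarray
    final: np.ndarray

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.per_level = np.asarray(self.per_level, dtype=bool)
        self.final = np.asarray(self.final, dtype=object)
        n = len(self.cell_ids)
        if self.per_level.ndim != 2 or self.per_level.shape[0] != n:
            raise ValueError("per_level must be (n_cells x n_levels)")
        if len(self.final) != n:
            raise ValueError("one final label per cell required")
        expected = np.where(self.per_level.all(axis=1), PURE, IMPURE)
        if n and not (self.final == expected).all():
            raise ValueError("final labels inconsistent with per-level flags")
        if n and self.per_level.shape[1] > 1:
            later = self.per_level[:, 1:]
            earlier = self.per_level[:, :-1]
            if np.any(later & ~earlier):
                raise ValueError(
                    "a cell passing level k+1 must have passed level k"
                )

    @property
    def n_levels(self) -> int:
        return self.per_level.shape[1]

    @property
    def pure_mask(self) -> np.ndarray:
        return self.final == PURE

    def pure_counts_per_level(self) -> list:
        return [int(c) for c in self.per_level.sum(axis=0)]


def gate_level(
    smoothed: ScoreMatrix,
    level: GatingLevel,
    params: GateParams,
    active: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean pass mask for one level over smoothed scores.

    Cells outside ``active`` remain False.
    """
    if not smoothed.smoothed:
        raise ValueError("gate_level requires kNN-smoothed scores")
    pos = np.column_stack(
        [smoothed.column(s.name) for s in level.positive_signatures]
    )
    ok = pos.max(axis=1) >= params.pos_threshold
    for sig in level.negative_signatures:
        ok &= smoothed.column(sig.name) < params.neg_threshold
    if active is not None:
        ok = ok & np.asarray(active, dtype=bool)
    return ok


class GatePurifier(BaseEstimator):
    """Marker-based cell purifier (transductive binary classifier).

    Given a hierarchical gating model, ``fit`` scores each signature per
    cell with the capped-rank statistic, smooths the scores over a kNN
    graph, and walks the gating hierarchy; ``fit_predict`` returns the
    "Pure"/"Impure" label per cell.

    Parameters mirror the three stages: scoring (``max_rank``,
    ``w_neg``), smoothing (``k``, ``n_hvg``, ``n_pcs``, ``target_sum``),
    gating (``pos_threshold``, ``neg_threshold``,
    ``recompute_graph_per_level``). ``random_state`` seeds the embedding.

    Fitted attributes
    -----------------
    purity_call_ : PurityCall with per-level flags and final labels.
    labels_ : array of "Pure"/"Impure".
    raw_scores_ : unsmoothed ScoreMatrix over all model signatures.
    smoothed_scores_ : level-1 smoothed ScoreMatrix (full cell set).
    """

    def __init__(
        self,
        model: GatingModel | None = None,
        pos_threshold: float = 0.2,
        neg_threshold: float = 0.2,
        recompute_graph_per_level: bool = True,
        max_rank: int = DEFAULT_MAX_RANK,
        w_neg: float = 1.0,
        k: int = 10,
        n_hvg: int = 800,
        n_pcs: int = 30,
        target_sum: float = 10_000.0,
        case_insensitive: bool = False,
        random_state: int = 0,
    ):
        self.model = model
        self.pos_threshold = pos_threshold
        self.neg_threshold = neg_threshold
        self.recompute_graph_per_level = recompute_graph_per_level
        self.max_rank = max_rank
        self.w_neg = w_neg
        self.k = k
        self.n_hvg = n_hvg
        self.n_pcs = n_pcs
        self.target_sum = target_sum
        self.case_insensitive = case_insensitive
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------
    def _smooth_subset(
        self, matrix: FeatureMatrix, raw: ScoreMatrix, index: np.ndarray
    ) -> ScoreMatrix:
        sub = matrix.subset_cells(index)
        emb = embed_cells(
            sub,
            n_hvg=self.n_hvg,
            n_pcs=self.n_pcs,
            seed=self.random_state,
            target_sum=self.target_sum,
        )
        graph = knn_graph(emb, self.k)
        raw_sub = ScoreMatrix(
            values=raw.values[index],
            signature_names=list(raw.signature_names),
            cell_ids=raw.cell_ids[index],
            smoothed=False,
        )
        return smooth_scores(raw_sub, graph)

    # -- estimator API -----------------------------------------------------
    def fit(self, X: FeatureMatrix, y=None):
        model = self.model
        if model is None or not isinstance(model, GatingModel):
            raise ValueError("a GatingModel must be supplied via `model`")
        if X.n_cells == 0:
            raise ValueError("matrix has zero cells")
        report = validate_against_features(
            model, X.feature_ids, case_insensitive=self.case_insensitive
        )
        if not report.usable:
            raise ValueError(
                f"model {model.name!r} unusable on this matrix: signatures "
                f"{report.unusable} lost all their positive genes"
            )
        gate = GateParams(
            pos_threshold=self.pos_threshold,
            neg_threshold=self.neg_threshold,
            recompute_graph_per_level=self.recompute_graph_per_level,
        )
        raw = score_signatures(
            X,
            model.signatures,
            ScoringParams(max_rank=self.max_rank, w_neg=self.w_neg),
            case_insensitive=self.case_insensitive,
        )
        n, n_levels = X.n_cells, len(model.levels)
        per_level = np.zeros((n, n_levels), dtype=bool)
        active = np.ones(n, dtype=bool)
        fail_safe = False
        smoothed_full = None
        if not gate.recompute_graph_per_level:
            graph = knn_graph(
                embed_cells(
                    X,
                    n_hvg=self.n_hvg,
                    n_pcs=self.n_pcs,
                    seed=self.random_state,
                    target_sum=self.target_sum,
                ),
                self.k,
            )
            smoothed_full = smooth_scores(raw, graph)
        first_smoothed = None
        for li, level in enumerate(model.levels):
            index = np.flatnonzero(active)
            if index.size == 0:
                break
            if fail_safe:
                per_level[index, li] = True
                continue
            if gate.recompute_graph_per_level:
                if index.size < 2:
                    warnings.warn(
                        f"only {index.size} cell(s) reach level "
                        f"{level.index}; remaining levels fail-safe to Pure"
                    )
                    per_level[index, li] = True
                    fail_safe = True
                    continue
                smoothed = self._smooth_subset(X, raw, index)
                ok_sub = gate_level(smoothed, level, gate)
                per_level[index[ok_sub], li] = True
            else:
                smoothed = smoothed_full
                per_level[:, li] = gate_level(smoothed, level, gate, active)
            if li == 0:
                first_smoothed = smoothed
            active = per_level[:, li].copy()
        final = np.where(per_level.all(axis=1), PURE, IMPURE).astype(object)
        self.raw_scores_ = raw
        self.smoothed_scores_ = first_smoothed
        self.purity_call_ = PurityCall(
            cell_ids=X.cell_ids, per_level=per_level, final=final
        )
        self.labels_ = self.purity_call_.final
        self.n_features_in_ = X.n_features
        return self

    def fit_predict(self, X: FeatureMatrix, y=None) -> np.ndarray:
        return self.fit(X).labels_


def run_gating(
    matrix: FeatureMatrix,
    model: GatingModel,
    scoring: ScoringParams | None = None,
    gate: GateParams | None = None,
    smooth: SmoothingParams | None = None,
    seed: int = 0,
) -> PurityCall:
    """Functional wrapper over :class:`GatePurifier`."""
    scoring = scoring or ScoringParams()
    gate = gate or GateParams()
    smooth = smooth or SmoothingParams()
    est = GatePurifier(
        model=model,
        pos_threshold=gate.pos_threshold,
        neg_threshold=gate.neg_threshold,
        recompute_graph_per_level=gate.recompute_graph_per_level,
        max_rank=scoring.max_rank,
        w_neg=scoring.w_neg,
        k=smooth.k,
        n_hvg=smooth.n_hvg,
        n_pcs=smooth.n_pcs,
        target_sum=smooth.target_sum,
        random_state=seed,
    )
    return est.fit(matrix).purity_call_
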