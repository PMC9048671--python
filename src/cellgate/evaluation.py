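"""Confusion-matrix metrics and batch evaluation of gating models.

A purification run is scored against annotated truth as a binary
classification of the target population: precision = tp/(tp+fp),
recall = tp/(tp+fn), and the Matthews correlation coefficient

    MCC = (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn))

which balances all four confusion cells and is the metric of choice when
the target population is a minority. When a denominator vanishes the
metric is reported as 0 (MCC) or 0.0 (precision/recall) and flagged
undefined rather than NaN, so downstream aggregation stays stable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import CellLabels, FeatureMatrix
from .gating_engine import GateParams, PurityCall, run_gating
from .gating_model import GatingModel
from .scoring import ScoringParams
from .smoothing import SmoothingParams

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "EvalDataset",
    "EvalRow",
    "EvalReport",
    "confusion",
    "metrics",
    "evaluate_models",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class Metrics:
    precision: float
    recall: float
    mcc: float
    precision_defined: bool = True
    recall_defined: bool = True
    mcc_defined: bool = True


def confusion(
    calls: PurityCall, truth: CellLabels, target_label: str
) -> ConfusionCounts:
    """Tally Pure/Impure calls against truth, joined by cell id.

    Cells present on only one side are dropped (with a warning); an
    empty intersection is an error.
    """
    call_series = pd.Series(calls.pure_mask, index=calls.cell_ids)
    truth_series = truth.as_series()
    common = call_series.index.intersection(truth_series.index)
    dropped = (len(call_series) - len(common)) + (len(truth_series) - len(common))
    if len(common) == 0:
        raise ValueError("no overlapping cell ids between calls and truth")
    if dropped:
        warnings.warn(
            f"{dropped} cell(s) present on only one side were dropped"
        )
    pred = call_series.loc[common].to_numpy(dtype=bool)
    is_target = (truth_series.loc[common] == target_label).to_numpy(dtype=bool)
    return ConfusionCounts(
        tp=int(np.sum(pred & is_target)),
        fp=int(np.sum(pred & ~is_target)),
        fn=int(np.sum(~pred & is_target)),
        tn=int(np.sum(~pred & ~is_target)),
    )


def metrics(counts: ConfusionCounts) -> Metrics:
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    prec_den = tp + fp
    rec_den = tp + fn
    precision = tp / prec_den if prec_den else 0.0
    recall = tp / rec_den if rec_den else 0.0
    factors = [tp + fp, tp + fn, tn + fp, tn + fn]
    if any(f == 0 for f in factors):
        mcc, mcc_defined = 0.0, False
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(math.prod(factors))
        mcc_defined = True
    return Metrics(
        precision=precision,
        recall=recall,
        mcc=mcc,
        precision_defined=prec_den > 0,
        recall_defined=rec_den > 0,
        mcc_defined=mcc_defined,
    )


@dataclass
class EvalDataset:
    """An annotated dataset for model evaluation.

    ``target_labels`` names the truth label each model purifies: a single
    string (all models target it), a mapping model-name -> label, or None
    to use each model's own name as its target label.
    """

    name: str
    matrix: FeatureMatrix
    truth: CellLabels
    target_labels: str | Mapping[str, str] | None = None

    def target_for(self, model_name: str) -> str:
        if self.target_labels is None:
            return model_name
        if isinstance(self.target_labels, str):
            return self.target_labels
        try:
            return self.target_labels[model_name]
        except KeyError:
            raise KeyError(
                f"dataset {self.name!r} defines no target label for model "
                f"{model_name!r}"
            ) from None


@dataclass
class EvalRow:
    model: str
    dataset: str
    target_label: str
    counts: ConfusionCounts
    metrics: Metrics


@dataclass
class EvalReport:
    """One row per (model, dataset) plus unweighted summary means."""

    rows: list

    @property
    def mean_precision(self) -> float:
        return float(np.mean([r.metrics.precision for r in self.rows]))

    @property
    def mean_mcc(self) -> float:
        return float(np.mean([r.metrics.mcc for r in self.rows]))

    def to_frame(self, include_summary: bool = True) -> pd.DataFrame:
        records = [
            {
                "model": r.model,
                "dataset": r.dataset,
                "target_label": r.target_label,
                "tp": r.counts.tp,
                "fp": r.counts.fp,
                "fn": r.counts.fn,
                "tn": r.counts.tn,
                "precision": r.metrics.precision,
                "recall": r.metrics.recall,
                "mcc": r.metrics.mcc,
            }
            for r in self.rows
        ]
        if include_summary and self.rows:
            records.append(
                {
                    "model": "SUMMARY",
                    "dataset": "",
                    "target_label": "",
                    "tp": "",
                    "fp": "",
                    "fn": "",
                    "tn": "",
                    "precision": self.mean_precision,
                    "recall": float(
                        np.mean([r.metrics.recall for r in self.rows])
                    ),
                    "mcc": self.mean_mcc,
                }
            )
        return pd.DataFrame.from_records(records)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(Path(path), sep="\t", index=False)


def evaluate_models(
    db: Mapping[str, GatingModel],
    datasets: Sequence[EvalDataset],
    scoring: ScoringParams | None = None,
    gate: GateParams | None = None,
    smooth: SmoothingParams | None = None,
    seed: int = 0,
) -> EvalReport:
    """Run every model on every dataset and tally metrics.

    Rows are ordered by model name then dataset name; identical inputs
    and seed give an identical report.
    """
    rows = []
    for model_name in sorted(db):
        model = db[model_name]
        for ds in sorted(datasets, key=lambda d: d.name):
            calls = run_gating(
                ds.matrix, model, scoring=scoring, gate=gate,
                smooth=smooth, seed=seed,
            )
            target = ds.target_for(model_name)
            counts = confusion(calls, ds.truth, target)
            rows.append(
                EvalRow(
                    model=model_name,
                    dataset=ds.name,
                    target_label=target,
                    counts=counts,
                    metrics=metrics(counts),
                )
            )
    return EvalReport(rows=rows)
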