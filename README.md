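# cellgate

Marker-based purification of cell populations from single-cell feature
matrices, using hierarchical gating models of positive and negative
markers — the computational analogue of a flow-cytometry gating strategy.

## The problem

A recurring task in single-cell analysis is to isolate one population of
interest (B cells, NK cells, tumour-infiltrating macrophages, ...) from a
heterogeneous dataset. Experts know the defining markers, but applying
them by hand means clustering, inspecting, and thresholding over several
ad-hoc steps. `cellgate` automates that practice: you declare the markers
— optionally arranged in levels, with negations — and every cell is
called **Pure** (belongs to the target population) or **Impure**. No
reference profiles or training data are needed, and the same machinery
applies to RNA counts, CITE-seq antibody (ADT) counts, or ATAC-derived
gene-activity matrices.

## The method

For a gating model with signatures of marker genes, each cell is
processed in three stages:

1. **Rank-based signature scoring.** Within each cell, features are
   ranked by decreasing value (ties averaged), with ranks capped at
   `max_rank` (default 1500). For a signature of *n* positive genes with
   capped ranks *r₁..rₙ*,

       U = Σᵢ rᵢ − n(n+1)/2,   S = 1 − U / (n · max_rank)

   the complement of the normalised Mann–Whitney U statistic: S = 1 when
   the markers occupy the top *n* ranks, S = 0 when they all fall past
   the cap. Because only ranks enter, S is invariant to any monotone
   per-cell transform — no normalisation is required. A gene negated
   with a trailing `-` (e.g. `CD3D-`) contributes by subtraction:
   `S = max(0, S_pos − w_neg · S_neg)`.

2. **kNN smoothing.** Scores are averaged over each cell's k nearest
   neighbours (default k = 10, self included) in a PCA embedding of the
   log-normalised matrix, counteracting dropout sparsity.

3. **Hierarchical thresholded gating.** At each level of the model a
   cell passes iff its best positive-signature smoothed score is
   ≥ `pos_threshold` (default 0.2) and every `negative` signature is
   below `neg_threshold`. Level k is evaluated only on survivors of
   level k−1 (with the neighbour graph rebuilt on the surviving subset),
   e.g. gate on immune cells via *PTPRC*, then purify macrophages via
   *CD68*/*FCGR1A*. A cell is Pure iff it passes every level.

Models are plain tab-separated text (columns `levels, use_as, name,
signature`; genes separated by `;`, negation by a trailing `-`), so a
model database is just a directory of TSV files under version control.

## Worked example

```python
from cellgate import build_model, confusion, metrics, preset, run_gating

# simulate a blood-like mixture of B, NK, T and monocyte populations
data = preset("pbmc-like", seed=1)

# the one-liner NK model: two positive markers, one negative marker
nk = build_model("NK", ["NCAM1", "KLRD1", "CD3D-"])

calls = run_gating(data.matrix, nk, seed=1)
print(f"{calls.pure_mask.sum()} of {data.matrix.n_cells} cells called Pure")

m = metrics(confusion(calls, data.truth, "NK"))
print(f"precision={m.precision:.3f} recall={m.recall:.3f} mcc={m.mcc:.3f}")
```

prints

```
505 of 2000 cells called Pure
precision=0.990 recall=1.000 mcc=0.993
```

i.e. of the 2000 simulated cells (500 true NK) the model calls 505 Pure,
almost all of them genuine NK cells — the `CD3D-` negation is what keeps
KLRD1-expressing T cells out (drop it and precision falls to ~0.5 on the
`nk-vs-t` preset).

The same pipeline is available as sklearn-style estimators
(`GatePurifier`, `UCellScorer`, `KNNSmoother` with
`fit`/`fit_predict`/`transform` and `get_params`/`set_params`) and as a
CLI:

```bash
cellgate simulate --preset pbmc-like --seed 1 --outdir pbmc/
cellgate run --matrix pbmc/ --model models/NK.tsv --out labels.tsv --seed 1
cellgate evaluate --model-db models/ --manifest manifest.tsv --out report.tsv --seed 1
```

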