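# Methods

This note records the model behind `cellgate`, the parameters that
matter, the design choices that were genuinely open, and what the
synthetic fixtures do and do not demonstrate.

## Scoring: a capped-rank Mann–Whitney statistic per cell

For one cell, let the features be ranked by decreasing measured value,
ties receiving the mean of their rank span, and every rank above
`max_rank` replaced by `max_rank + 1`. For a signature of *n* positive
genes with capped ranks r₁..rₙ the score is

    R = Σ rᵢ,   U = R − n(n+1)/2,   S = 1 − U / (n · max_rank)

clipped to [0, 1]. U is exactly the Mann–Whitney pairwise count of
non-signature features outranking signature features (ties half), which
gives the test suite an independent brute-force oracle. Consequences
worth knowing:

- **Monotone invariance.** Any strictly increasing per-cell transform
  (library-size scaling, log, power) leaves S unchanged, so scoring runs
  on raw counts; no normalisation layer exists in this stage on purpose.
- **The cap is the workhorse.** `max_rank` (default 1500) is what sends
  an absent marker to S ≈ 0: in transcriptome-scale data the thousands
  of undetected genes share one averaged tie rank far beyond the cap.
  The default presumes a feature universe of ~10⁴ or more; for small
  feature spaces (ADT panels), the effective cap is lowered to
  `n_features − 1` automatically so it remains attainable. Callers with
  intermediate-sized matrices (a few hundred features) should pass a
  `max_rank` well below the typical number of detected features per
  cell, or background cells will not score near zero.
- **Tie handling.** All undetected genes share one averaged rank, then
  the cap applies — deterministic and permutation-invariant.
- **Negated genes.** `CD3D-` inside a signature subtracts its own group
  score: `S = max(0, S_pos − w_neg · S_neg)` with `w_neg = 1` by
  default. This is the simplest signed combination consistent with
  trailing-minus semantics; `w_neg` is exposed because other weightings
  are defensible. Whole signatures declared `use_as = negative` are a
  different mechanism: they are thresholded separately by the gating
  engine and veto a level.

## Smoothing: neighbourhood averaging in a PCA embedding

Each signature score is replaced by the unweighted mean over the cell's
k nearest neighbours (k = 10 by default, the cell itself included, so
k = 1 is the identity). Neighbourhoods come from the conventional
pipeline: total-count scaling to 10,000 per cell, log1p, top-800
most-variable features (by variance of the log values; skipped for ADT
panels), per-feature standardisation, and a 30-component PCA (full SVD —
deterministic given the seed). kNN is exact, with distance ties broken
by lower cell index.

Smoothed values are convex combinations of raw values, hence bounded by
the raw min/max per signature; on homogeneous populations smoothing
shrinks score variance, which is its entire purpose — recovering cells
whose markers dropped out. Self-inclusion keeps a cell's own evidence in
its smoothed score. Smoothing over a plain kNN list (rather than a
shared-nearest-neighbour weighting) was chosen for determinism and
transparency; both the neighbourhood size and the embedding knobs are
exposed. For small matrices (hundreds of cells and features) the
defaults over-fit noise: structure carried by a handful of marker genes
is diluted across 30 noise-dominated components, so neighbourhoods mix
populations. Smaller `n_hvg` (~100) and `n_pcs` (~10) concentrate the
signal there; the unit-test fixtures do exactly that.

## Gating: fixed thresholds walked down the hierarchy

A cell passes a level iff the maximum over the level's positive
signatures is ≥ `pos_threshold` AND every negative signature is
< `neg_threshold` (both default 0.2 on smoothed scores; a cell exactly
at the positive threshold counts as detected, hence the inclusive
boundary for positives and exclusive for negatives). Multiple positive
signatures at one level are alternatives (OR); any negative signature
vetoes. Negative signatures act at their own level only.

Level k is evaluated only on survivors of level k−1. By default the
embedding, graph and smoothing are recomputed on the surviving subset
first, matching the sequential semantics (neighbourhoods among immune
cells only, when purifying macrophages from immune cells); an off-switch
trades that for speed. If a level leaves fewer than two cells, no
neighbourhood can be built: the survivors fail-safe to Pure for the
remaining levels with a warning rather than being silently discarded.
Final label: Pure iff all levels passed — so the pure set is nested
across levels by construction, and raising `pos_threshold` can only
shrink it.

Thresholds on smoothed (not raw) scores are used for negative
signatures as well, for symmetry with the positives.

## Evaluation

Precision, recall and the Matthews correlation coefficient are computed
from the Pure/Impure calls joined to truth labels by cell id. A zero
denominator reports the metric as 0 with an `*_defined = False` flag —
never NaN — so report aggregation stays stable. Batch evaluation runs
every model of a database on every annotated dataset (the target truth
label defaults to the model's name) and appends unweighted means across
rows.

## Synthetic data: what it emulates, and what it does not

The generator draws counts per gene from a negative binomial
(gamma–Poisson; variance μ + μ²/θ) with a flat baseline mean, multiplied
by `marker_fold` for a population's marker program, then zeroes entries
with probability `dropout_extra` — the minimal model reproducing the
overdispersed, sparse structure the smoothing stage exists to mitigate.
Cells are shuffled; truth labels are exact by construction.

Preset defaults: 500 cells per population, 15,000 features, baseline
mean 0.25, dispersion 1.5, extra dropout 0.10, marker fold 30. These
were chosen to emulate 10x-style data at desk scale: roughly 2,500–3,000
detected genes per cell; canonical markers detected at count ≥ 2 in
~75–85 % of their own population and ~3 % elsewhere; and — critically —
the count-1 noise floor falling beyond the 1500-rank cap, as it does in
real transcriptomes. The feature universe must be transcriptome-sized
relative to `max_rank` for the method's semantics to hold at all: with
only a few thousand features an undetected marker's tie rank lands under
the cap and every cell scores ~0.2, erasing the contrast the gate
thresholds. Each population over-expresses a 7–10 gene program
containing its canonical markers, because real cell types differ in
coordinated programs, not single genes — and because an embedding needs
more than one axis of covariance to separate populations. Gating models
still see only the canonical genes.

Presets: `pbmc-like` (B / NK / T / Mono), `tumor-like` (malignant
without the pan-immune marker PTPRC, T, macrophage — the two-level
scenario), `nk-vs-t` (NK and T sharing KLRD1, so that only the `CD3D-`
negation separates them), and `ionocyte-like` (a rare 25-cell
FOXI1+/CFTR+ population).

What passing on these fixtures does **not** show: robustness to
gene–gene correlation beyond block programs, batch effects, doublets,
ambient contamination, or continuous differentiation gradients — real
data has all of these and the fixtures none. The fixtures establish
that the pipeline's machinery (scoring, smoothing, hierarchy, vetoes)
behaves as specified under controlled noise, not that any particular
precision figure transfers to a given real dataset.

## Numerical and interface choices

- Feature-id matching is exact and case-sensitive after whitespace
  stripping; an optional case-folded fallback is off by default (silent
  case-folding can conflate distinct symbols).
- Ranking densifies the matrix in chunks of 512 cells, bounding memory.
- PCA uses the full SVD solver: slower than randomised but bit-for-bit
  reproducible, which makes CLI runs byte-identical under a fixed seed.
- MTX round-trips preserve integer counts exactly and reals to 17
  significant digits; gzipped inputs are sniffed by extension.
- Level numbering in model files must be consecutive from 1 — a gap is
  almost always an editing error, so it is rejected rather than
  compacted.
- The estimators (`UCellScorer`, `KNNSmoother`, `GatePurifier`) follow
  sklearn conventions (constructor params, `fit`, trailing-underscore
  attributes) but take a `FeatureMatrix` rather than a bare array, since
  signatures must be resolved against feature identifiers.

## Known limitations

- The purifier is transductive: calls depend on the dataset's own
  neighbour structure, so adding cells can change existing calls.
- One model targets one population; multi-label annotation with
  conflict resolution is out of scope.
- Exact kNN is quadratic in cells; fine at the tool's target scale
  (10³–10⁴ cells), not tuned for atlases.
- Thresholds are global per run (overridable per run, not per
  signature level-by-level).
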