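# Methods

## Model overview

The package predicts DNA binding activity in two task modes selected by
a flag: binary classification of short sequences (is this 14-bp segment
a transcription-factor binding site?) and regression of a recombination
frequency in [0, 1] from a numeric structural-feature table. Both modes
share one decision framework: encode/preprocess, fit three candidate
models — a tuned random forest, a tuned XGBoost, and the package's
weighted deep forest — and keep whichever scores best on a held-out
validation split.

## Sequence encoding

A sequence of length `L` maps to `4L + 64` binary features: a
positional one-hot block (codes `A=1000, T=0100, C=0010, G=0001`, so the
block has exactly `L` ones) and a trinucleotide presence block. The
trinucleotide window width of 3 mirrors the codon, the smallest
biologically meaningful multi-base unit; the window slides with stride 1
and an observed triplet sets its indicator to 1 regardless of
multiplicity. Presence rather than counts is the default because a
14-bp sequence offers only 12 windows and counts add little beyond
noise; a `counts=True` flag exists for longer sequences. Triplet columns
are ordered lexicographically over (A, C, G, T) — an arbitrary but
reproducible choice recorded in the output header. Inputs are
uppercased; `U` is accepted as `T` with a warning; any other character
is a hard error, since no ambiguity-code semantics are defined for the
downstream encodings.

## Preprocessing

* **Augmentation** adds the reverse, the complement and the reverse
  complement of every record, labels inherited. The output is exactly
  4× the input: duplicates (e.g. from palindromes) are deliberately
  kept, so cardinality arithmetic stays exact.
* **Low-variance filter** drops a feature when its modal value covers
  strictly more than 80% of samples (a column at exactly 80% is kept).
* **Min-max normalization** rescales each feature to [0, 1]; constant
  columns map to 0 with a warning. When used inside a fitted pipeline
  the training extrema are frozen and reapplied to new data.
* **Response thresholding** labels a sample positive when its
  normalized recombination frequency strictly exceeds 0.46 (ties are
  negative). The cut is configurable.
* **Oversampling** draws minority-class rows with replacement (seeded)
  until the classes balance; majority rows are never discarded.
  Balancing happens before the split by default, which can place
  duplicates of one source row on both sides of the split — a known
  leakage caveat; split first manually if that matters for your use.
* **Split**: seeded uniform 4:1, train size `floor(0.8 n)`, disjoint
  and exhaustive.

## Feature weighting

Weights come from an auxiliary random forest. For every split node, the
Gini impurity `G = 1 − p₊² − p₋²` of the parent and children yields a
node score; scores are summed per split feature over all trees and
normalized to sum to 1. The default node score is the size-weighted
impurity decrease `G_p − (n_L/n)G_L − (n_R/n)G_R`, which is non-negative
and matches the split criterion the trees actually optimize. An
`as_printed` convention subtracting raw child impurities
(`G_p − G_L − G_R`) is kept for auditability; it can go negative and is
not the default. Node class counts are recovered from the fitted tree
structure itself, so the computation is independent of the library's
own `feature_importances_` (which additionally scales by node fraction
and averages over trees — a different, though monotonically similar,
statistic). For regression tasks the same walk uses the variance (MSE)
impurity recorded at each node; this is the natural extension since
Gini is undefined there.

## Weighted varied-granularity scanning and the cascade

A frame of length `m` slides with stride 1 over the feature vector and
the weight vector, giving two `(n−m+1, m)` matrices whose Hadamard
product is the scanner input: windows dominated by heavy features carry
proportionally larger values. Each window, labelled with its parent
instance's label, is scored by two scanners — a completely-random-trees
forest (`max_features=1` extra-trees) and an ordinary random forest,
the usual pairing for multi-grained scanning. Their per-window
probability pairs concatenate row-major into a vector of length
`4(n−m+1)` (`2(n−m+1)` for regression, one prediction per window per
scanner). That notation is read as a flat one-dimensional vector, not a
2-row matrix.

The cascade stacks layers of one extra-trees and one random forest.
During fitting each layer's contribution to the next layer's input is
estimated out-of-fold (3-fold by default) to avoid feeding the cascade
its own training fit; at prediction time the fully-fitted layer forests
are used. Depth grows until the out-of-fold score (accuracy, or
negative MSE) fails to improve for 2 consecutive layers, capped at
`max_layers`. The weight vector and the scanners are computed once on
the training data and frozen for every later transform, so validation
and test data never influence them.

Default window length: 3 for encoded sequences (the triplet rationale
again); for unordered numeric tables, where no natural scale exists,
`⌈√n⌉` — wide enough for windows to mix several features, narrow enough
to keep many windows.

## Model selection

The hyperparameter search is a seeded cyclic random search with
interval refinement: the trial budget is split into (by default 4)
cycles; each cycle samples uniformly inside the current bounds —
`n_estimators ∈ [50, 2000]`, `max_depth ∈ [1, 25]`, and for XGBoost
`learning_rate ∈ [10⁻³, 0.3]` on a log scale — scores each
configuration by k-fold cross-validation of the primary metric on the
training portion, then halves the bounds around the incumbent best.
The full-scale budget is 800 trials; tests and examples use a fast
profile of a few trials, which is sufficient for the well-separated
synthetic problems.

The deep forest is not tuned; it runs with its defaults. Candidates are
compared on the held-out 20% validation split by an ordered metric
priority — classification: accuracy, then AUC, then F1; regression:
RMSE (ascending), then PCC — with later metrics breaking ties in
earlier ones. A candidate that fails to fit is recorded and skipped;
selection errors out only if all three fail. With a fixed seed the
whole procedure, including the search trajectory, is deterministic.

## Evaluation metrics

Confusion metrics (accuracy, recall, precision, F1) follow the standard
count formulas; degenerate denominators return 0 with a warning. AUC is
the area under the empirical ROC curve (equivalently the tie-aware
Mann–Whitney pair statistic). Two regression metrics exist in two
variants each: `rmse_as_printed` averages `√((y−y′)²)` term by term —
algebraically the MAE — while `rmse_standard` is `√(mean squared
error)`; `varscore_as_printed` applies a literal `1/n` factor to
`1 − V(y−y′)/V(y)` while `explained_variance` omits it and equals 1 for
perfect predictions. Run reports use the standard variants and label
the choice. Variances use the population convention (divide by `n`).
Probabilities are thresholded at 0.5 for confusion metrics unless a
threshold is supplied.

## Synthetic data

`simulate_tfbs` plants a consensus motif (default `GGGCGG`, the SP1
GC-box) at a uniform random offset in otherwise-random fixed-length
sequences, mutating each motif position independently (default
probability 0.1); negatives are random sequences rejected while they
contain the exact consensus. `simulate_attc` builds a feature table
with three statistical roles: low-variance nuisance columns (one value
planted in exactly 90% of rows, guaranteed above the 80% filter cut),
sparse informative standard-normal columns, and pure noise; the
response is a logistic function of the informative columns plus
Gaussian noise (sd 0.05), clipped to [0, 1]. Defaults — 292 features,
14 low-variance, 10 informative — mirror the dimensionality of real
structural-feature mutant libraries, and column names imitate the
folding-energy / positional-entropy / pairing-probability families of
such tables, but the names are cosmetic: no thermodynamics is computed.

What passing tests therefore show: the pipeline recovers planted
sequence motifs and planted informative features, its counts and shapes
are exact, and its metrics agree with independent oracles. What they do
not show: performance on real binding-site data, where motifs are
softer, features are correlated, and class structure is messier than
the generator's independence assumptions.

## Problem sizes and numerical choices

Tests run the end-to-end selection at 600 training / 200 test sequences
over 5 seeds with the fast search profile, and feature-ranking recovery
at 400 samples × 60 features over 5 seeds — sizes chosen to exercise
every code path at desk scale. Weight normalization is checked to
1e-9; probability rows to 1e-9; oracle equivalences to 1e-10. All
randomness flows from explicit integer seeds; forests run
single-threaded so results are bit-reproducible across machines.

## Known limitations

* Binary classification only; multi-class Gini weighting is out of scope.
* Oversampling before splitting risks duplicate leakage (flagged above).
* The cascade's out-of-fold early stopping adds a `cv`-fold fit cost
  per layer; for large tables reduce `n_cascade_estimators` or
  `max_layers`.
* Model bundles are joblib pickles: portable across identical library
  versions only, and not a security boundary — load only bundles you
  created.
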