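# Methods

`plantrbp` predicts whether a plant protein binds RNA, from its amino-acid
sequence alone. The pipeline has four stages: composition encoding,
stacked base-learner prediction columns, correlation pruning of those
columns, and an embedding-free convolutional classifier. This note
records the model, its assumptions, the defaults and why, the numerical
choices, and what the synthetic benchmarks do and do not demonstrate.

## Composition encoding (KPC)

A protein of length L over the 20-letter alphabet contains L − k + 1
overlapping k-peptide windows. The k-peptide composition assigns to the
i-th of the 20^k possible k-peptides the frequency

    f_i = N_i / (L − k + 1),

where N_i is its window count. k = 1 is the amino-acid composition (AAC,
20 dims), k = 2 the dipeptide composition (DPC, 400 dims), k = 3 the
tripeptide composition (TPC, 8000 dims). The default encoding
concatenates k = 1 and k = 2 into a 420-dim vector: AAC carries global
composition, DPC local adjacency patterns, while TPC is supported but
sparse at desk scale and off by default. Each per-k block sums to 1 to
within 1e−9 by construction; no further scaling is applied — the values
are already frequencies in [0, 1].

The alphabet ordering `ACDEFGHIKLMNPQRSTVWY` is fixed and k-peptide
feature names are lexicographic in it, so column identity is stable
across runs and files. The encoding itself is order-agnostic beyond the
k-window, hence invariant to residue shuffling at k = 1.

Sequences with nonstandard residues (B, J, O, U, X, Z, gaps, stops) are
sanitized by dropping the offending residues (`drop_residue`, the
default, which only shortens L) or the whole record (`drop_record`). A
sequence shorter than the largest requested k cannot be encoded and is
rejected at encoding time with its identifier.

## Stacked prediction columns

Four base learners — an RBF-kernel SVM, logistic regression, linear
discriminant analysis, and LightGBM — are each trained on the 420-dim
encoding, and their positive-class scores are appended as four extra
feature columns (`SVM_Pred_Result`, …), giving the 424-dim fused vector.
A wider pool of eleven candidate learners (adding XGBoost, random
forest, GBDT, k-NN, decision tree, naive Bayes, bagging) is available
for the selection stage.

Training-set columns are produced **out-of-fold**: rows are split into
five stratified folds and each row is scored by a model fit on the other
four, so no feature value derives from a model that saw its own row.
This is the defensible default for stacked features; an in-sample mode
(`oof=False`) exists as an explicit toggle for comparison, since
in-sample stacking inflates downstream gains. Unseen data are scored by
models refit on the full training set, the standard stacking practice.

Numerical choices:

- SVM scores are a logistic (Platt) calibration of the SVC margin,
  fitted on the training margins. This costs one SVC fit instead of an
  internal cross-validated calibration; the out-of-fold protocol already
  protects the meta-level from the in-sample optimism of the calibrator.
- SVM, LR, LDA, and k-NN receive standardized inputs (mean/variance fit
  on training folds only); tree ensembles consume raw frequencies.
- Hyperparameters default to library defaults with a fixed seed.
  `tune_learner` reproduces the tuning *procedure* — random search over
  per-learner spaces, scored by mean 5-fold AUC, ties to the first draw —
  rather than any particular tuned values.

## Correlation pruning

Prediction columns of different learners are often nearly collinear.
All pairwise Pearson correlations among the candidate columns are
computed; pairs with |r| > 0.80 are resolved by dropping the member with
the lower single-column out-of-fold AUC. Pairs are processed in
descending |r| (name order breaks ties) so the outcome is deterministic
when three or more columns are mutually correlated; a column already
dropped is skipped in later pairs. An allow-list exempts pairs from
pruning; by default it contains the SVM/LDA pair, whose mechanisms
(margin maximization vs. linear discriminants) are complementary enough
to justify keeping both despite high correlation. Zero-variance columns
are reported separately and excluded from the correlation table — an
undefined correlation is never silently reported as 0. After selection
the implementation re-audits every kept non-allow-listed pair against
the threshold.

Only the prediction columns are pruned by default; raw k-peptide columns
can be passed as candidates too (their single-column AUC is then the
column used directly as a ranking score), which is a generalization
beyond the default workflow.

## Convolutional classifier

The fused vector (424 dims by default) is treated as a one-dimensional
single-channel feature map. Three parallel 1D convolutions with kernel
sizes 3, 4, 5 (64 filters each, valid padding, ReLU) scan adjacent
feature dimensions; global max pooling reduces each branch to a 64-dim
vector. The three pooled vectors are fused by scaled dot-product
self-attention over the branch set — the three vectors act as query,
key, and value; per-query weights are softmax-normalized — and the
attended tokens are concatenated (192 dims). With `use_attention=False`
the fusion is plain concatenation. A 64-unit ReLU dense layer with
dropout 0.5 and a sigmoid output complete the classifier. There is no
embedding layer anywhere: the input is already a designed feature
vector. Attention is placed after pooling, over the three pooled
branch vectors, which is the only placement consistent with fusing
"three 64-dimensional vectors"; it is on by default.

A baseline variant (`OriginalTextCNN`) keeps the classic text-CNN
design — residues integer-encoded (vocabulary 21 = 20 residues +
padding), a learned embedding table, the same conv/pool/attention/dense
stack — to quantify what replacing the embedding with composition
features buys.

Training: binary cross-entropy, Adam at 1e−3, batches of 32, at most 50
epochs. Early stopping is strict: an epoch counts against the patience
budget (5) unless validation loss is strictly below the best seen;
training restores the best-epoch weights. One integer seed drives weight
initialization, minibatch shuffling, and dropout masks, so runs are
reproducible within one software environment. The network is implemented
directly in NumPy — forward, backward, and the optimizer — and the
analytic gradients are regression-tested against central finite
differences (< 1e−5 relative error). Feature maps are float32 in
(batch, filter, position) layout so pooling reduces over the contiguous
axis; a float64 mode exists for gradient checking. Training-curve
loss/accuracy are running minibatch averages (dropout active);
validation metrics come from full inference-mode passes.

Unstated architecture details were fixed as: ReLU activations, one
64-unit hidden dense layer, dropout 0.5, Adam 1e−3, batch 32 — all
exposed in `TextCNNConfig`, none hard-coded.

## Evaluation

Metrics are percent-scale: ACC, SN (recall), SP, Precision,
F1 = 2TP/(2TP+FP+FN), MCC by its standard four-cell formula, and AUC by
rank-based ROC integration. Zero-denominator cases return an explicit
undefined marker naming the zero term — never a silent 0 — because a
perfect-specificity fold can zero TP+FP. A support-weighted averaging
mode for F1/Precision matches the convention used for independent-set
reporting on balanced data.

Cross-validation is stratified k-fold; the **entire** pipeline —
stacking, selection, classifier training — is refit on each fold's
training portion, so no test row influences any fitted component. Fold
summaries report mean ± population (ddof = 0) standard deviation; the
population convention is the one that reproduces the reference
benchmark's printed summary row from its printed per-fold values, and
sample std is available via a flag.

Feature-set comparisons use one-tailed paired t-tests (alternative:
the later set is better) on per-fold ACC and MCC, with Shapiro–Wilk
computed on the paired differences as the normality check. Identical
per-fold vectors make both tests undefined and are reported as such.

## Ablation (D0–D4)

`run_ablation` evaluates the incremental feature sets — D0 the bare
420-dim encoding, then +SVM (D1), +LR (D2), +LDA (D3), +LightGBM (D4),
widths 420..424 — under identical fold partitions, a validity
requirement of the paired tests. Per fold, the four learners are stacked
once on the training portion (out-of-fold columns for training rows,
full-model scores for held-out rows) and each feature set trains its own
classifier on the same partition; the per-fold classifier seed is offset
by the fold index so the five sets within a fold share initialization
conditions while folds differ.

## Synthetic benchmarks

The generator emulates the statistical structure this method exploits —
class-differential k-peptide composition — without any claim of
biophysical realism. Both classes draw residues i.i.d. from a shared
background (uniform by default; a SwissProt-like composition preset is
provided) with log-normal lengths (mean 350, sd 150 residues, clipped to
[50, 2000] — typical protein scale). Positives additionally have motif
peptides substituted at non-overlapping slot positions: for each motif
of length m, Binomial(⌊L/m⌋, effect_size · p) slots are rewritten. The
default motifs are arginine/glycine-rich 3-peptides (RGG, GGR, RGR at
p = 0.05 each), a nod to the RGG-box repeats of real RNA-binding
domains. Substitution, not insertion, keeps the length law identical
across classes, so composition is the only class signal. At
effect_size = 0 the classes are identically distributed, giving a null
benchmark for calibration; the strong-signal preset uses effect_size = 5.

What passing these benchmarks shows: the pipeline recovers planted
composition differences and stays calibrated at chance on null data.
What it does not show: performance on real plant proteomes, where the
signal is weaker, confounded with phylogeny and length, and not purely
compositional. The real benchmark (2496 + 2496 training pairs, 543 + 543
independent pairs from the RBPLight release) is external data;
`scripts/external_benchmark.py` documents how to run against it and
prints this run's metrics next to the published reference values.

## Problem sizes used by the checks

The acceptance script and end-to-end tests use 1000 + 1000 sequences for
the 5-fold strong-signal and null cross-validations, and 250 + 250
sequences with 5 folds for the ablation table — sizes chosen so the full
pipeline (including five classifier trainings per feature set) runs
comfortably on a single CPU while leaving the statistical conclusions
unambiguous. Unit tests use smaller draws with a scaled-down classifier
configuration (8 filters, 16 dense units).

## Known limitations

- Composition features are order-free beyond the k-window; motifs longer
  than 3 and positional effects are invisible by design.
- The NumPy classifier is CPU-only and single-threaded beyond BLAS; it
  is sized for desk-scale data (thousands of sequences), not proteomes.
- Bit-reproducibility is promised within one software environment only;
  BLAS reduction order may differ across builds (inference probabilities
  agree to ~1e−6 in float32).
- The tuned hyperparameters of the reference run are not public; only
  the tuning procedure is reproduced.
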