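# plantrbp

Sequence-only prediction of plant RNA-binding proteins (RBPs).

RBPs regulate RNA stability, splicing, transport, and translation, and in
plants they shape development and stress response. Annotating them
experimentally is slow, and many sequence-based predictors lean on
evolutionary profiles (PSSMs) that are expensive to compute at proteome
scale. `plantrbp` implements a lightweight alternative for
bioinformaticians who need desk-scale RBP annotation from FASTA files
alone:

1. **k-peptide composition (KPC) encoding.** Each protein of length L is
   represented by the frequencies f_i = N_i / (L − k + 1) of its
   k-peptides, concatenated for k = 1 (AAC, 20 dims) and k = 2 (DPC,
   400 dims) into a 420-dim vector; k = 3 (TPC, 8000 dims) is supported.
2. **Stacked base learners.** An RBF-kernel SVM, logistic regression,
   linear discriminant analysis, and LightGBM each contribute a
   positive-class score column (out-of-fold on training data, so no row
   is scored by a model that saw it), extending the vector to 424 dims.
3. **Correlation pruning.** Prediction-column pairs with Pearson
   |r| > 0.80 are resolved by dropping the lower-AUC member, with an
   allow-list for justified exceptions (by default the SVM/LDA pair).
4. **Embedding-free convolutional classifier.** The fused vector feeds
   parallel 1D convolutions (kernel sizes 3/4/5, 64 filters each),
   global max pooling, scaled dot-product self-attention over the three
   pooled branch vectors, and a dense head — trained with early stopping
   (patience 5, ≤ 50 epochs). Implemented natively in NumPy; CPU-only.

Performance is reported as ACC, MCC, F1, SN, SP, Precision, and AUC under
stratified k-fold cross-validation in which the *entire* pipeline is
refit per fold. A synthetic-data generator with planted composition
motifs makes every stage testable without downloads, and an incremental
D0–D4 ablation with paired one-tailed t-tests quantifies what each
prediction column adds.

See `docs/methods.md` for the full model description and design choices.

## Worked example

Generate a synthetic benchmark whose positive class is enriched for
arginine/glycine-rich 3-peptide motifs, train the full pipeline, and
inspect the fit:

```python
from plantrbp import RBPEnsembleModel, RunConfig, strong_signal_spec, generate

sequences = generate(strong_signal_spec(n_pos=200, n_neg=200, seed=1))
model = RBPEnsembleModel(sequences, RunConfig(seed=1))
results = model.fit()
print(results.summary())
```

```
RBP ensemble model fit
==========================================================
sequences: 400   ks=[1, 2]   fused features: 421

base learners (out-of-fold AUC):
  SVM_Pred_Result           1.0000   dropped
  LR_Pred_Result            1.0000   kept
  LDA_Pred_Result           0.9975   dropped
  LightGBM_Pred_Result      1.0000   dropped

pruned by correlation (|r| > 0.8):
  LightGBM_Pred_Result vs LR_Pred_Result: r=+1.000, AUC 1.000 < 1.000
  LDA_Pred_Result vs LR_Pred_Result: r=+0.995, AUC 0.997 < 1.000
  SVM_Pred_Result vs LR_Pred_Result: r=+0.986, AUC 1.000 < 1.000

classifier: stopped epoch 50, best epoch 50, val loss 0.0001, val acc 1.0000
```

On this strongly separable benchmark every learner reaches AUC ≈ 1, so
their score columns are nearly collinear and the pruning stage keeps
only one of them (the SVM/LDA allow-list pair is only exempt when both
members survive against *each other*; here both fall to the higher-AUC
LR column first): the fused width is 421 rather than the 424 seen on
realistic, harder data, where the four columns disagree enough to
survive. Cross-validated metrics and independent-set scoring:

```python
summary = model.cross_validate(n_folds=5)   # refits everything per fold
print(summary.table())                      # per-fold + mean ± std rows
table = results.predict(new_sequences)      # id, probability, label
```

The same workflow is available from the shell:

```bash
plantrbp simulate --out-dir data --n-pos 1000 --n-neg 1000 --strong --seed 1
plantrbp train    --pos data/pos.fasta --neg data/neg.fasta --out-dir run --seed 1
plantrbp ablate   --pos data/pos.fasta --neg data/neg.fasta --out-dir run --seed 1
plantrbp predict  --bundle run --fasta queries.fasta --out predictions.tsv
```

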