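# amyhex

Classification of amyloid-forming hexapeptides from sequence alone.

Short hexapeptide "hot spots" can trigger aggregation of a whole protein
into amyloid fibrils, the hallmark of amyloidoses and a central theme in
neurodegenerative disease. `amyhex` re-implements, end to end and in
plain scientific Python, a published pipeline for predicting whether a
hexapeptide is amyloidogenic:

* a **descriptor engine** that maps every hexapeptide to a named
  4125-dimensional vector across 15 descriptor families — AAindex and
  z-scale positional encodings, pseudo amino-acid composition (PAAC) and
  its amphiphilic variant (APAAC), quasi-sequence-order (QSOrder) and
  sequence-order coupling numbers (SOCNumber), normalized Moreau–Broto,
  Moran and Geary autocorrelations, grouped compositions (GAAC, EGAAC,
  GDPC), dipeptide deviation from expectation (DDE), and CTD
  composition/distribution descriptors;
* two **classifiers written from first principles**:
  * *kernel naive Bayes* — per class c and feature j an independent
    Gaussian kernel density estimate on the whole real line,
    f̂(x | c, j) = (1/n_c) Σᵢ φ((x − xᵢ)/h_cj)/h_cj, with a
    normal-reference (Silverman) bandwidth per class and feature;
    prediction by argmax of log-prior plus summed log densities;
  * *GentleBoost* — an additive model F(x) = Σₜ ν·fₜ(x) of shallow
    weighted least-squares regression trees fitted to the ±1 labels,
    with weight updates w ← w·exp(−y·ν·fₜ(x));
* the **balanced-dataset protocol**: class balancing by seeded
  downsampling, per-class train/test splits (350 + 33 per class),
  stratified k-fold cross-validation (k ∈ {5, 10, 15}), and the
  resampled-robustness protocol that rebuilds 100 distinct train/test
  pairs and retrains on each;
* the **metric suite**: ACC, SN, SP, Q = (SN+SP)/2, MCC, error rate,
  and ROC/AUC by threshold sweep.

Because the original curated corpora (AmyLoad, WALTZ-DB 2.0, Pep424,
AmyPro) are external resources, the package ships a deterministic
synthetic-fixture generator (`amyhex.fixtures`) that emulates the corpus
shapes (516 amyloid / 900 non-amyloid hexapeptides) with a planted,
exactly recomputable hydrophobicity rule, so every stage of the pipeline
is testable offline.

## Worked example

The `amyhex` command ties the pipeline together. Starting from nothing —
a synthetic 100/100 labelled fixture — through features, training with
the shipped `exp2` preset (kernel naive Bayes, 5-fold CV), prediction
and evaluation:

```bash
$ amyhex fixture --n-per-class 100 --seed 7 --out-fasta demo.fasta --out-labels demo.tsv
wrote 200 records to demo.fasta / demo.tsv

$ amyhex extract --table demo.tsv --out demo_features.tsv
wrote 200x4125 feature matrix to demo_features.tsv

$ amyhex train --features demo_features.tsv --preset exp2 --seed 7 \
      --model-out knb.json --report-out cv_report.json
CV (k=5, pooled): ACC=0.8150 SN=0.8700 SP=0.7600 MCC=0.6338

$ amyhex predict --model knb.json --features demo_features.tsv --out predictions.tsv
wrote 200 predictions to predictions.tsv

$ amyhex evaluate --pred predictions.tsv --truth demo.tsv --out eval_report.json
TN=99 FP=1 FN=0 TP=100  ACC=0.9950 AUC=0.9950
```

The extract step produces exactly 4125 named columns per hexapeptide
(plus `id` and `label`). The train step reports pooled 5-fold
cross-validation metrics — here 81.5% accuracy on 100-per-class
training data; the final evaluate line scores the fitted model on its
own training records (hence the near-perfect 99.5%: kernel densities
peak at their training points — use a held-out split for honest
numbers). Every command writes a `.config.json` snapshot next to its
output so the run can be reproduced exactly.

The same pipeline is available as a library: `gen_labelled_fixture`,
`extract_all`, `KernelNBClassifier` / `GentleBoostClassifier`,
`kfold_cv`, `make_robustness_pairs`, `robustness_run`.

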