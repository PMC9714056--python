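# Methods

## Problem and scope

`amyhex` classifies hexapeptides as amyloid-forming (positive) or not
(negative). The unit of analysis is a 6-residue sequence over the 20
standard amino acids; mixed lengths are out of scope (a single fixed
length per run). The package covers the whole experimental loop: feature
extraction, classifier training, metric reporting, and the stability
protocols (cross-validation and resampled retraining).

## Descriptor engine

Every hexapeptide is mapped to a named 4125-dimensional vector. The 15
families and their dimensions under the default configuration
(λ = 5, nlag = 5, window = 5):

| family | dim | notes |
|---|---|---|
| AAINDEX | 3186 | 531 AAindex indices × 6 positions |
| ZSCALE | 30 | 5 z-scales × 6 positions |
| EGAAC | 10 | 2 sliding windows × 5 groups |
| DDE | 400 | 20 × 20 dipeptides |
| GAAC | 5 | 5-way grouped composition |
| GDPC | 25 | grouped dipeptide composition |
| CTDC | 39 | 13 properties × 3 groups |
| CTDD | 195 | 13 × 3 × 5 distribution points |
| PAAC | 25 | 20 + λ |
| APAAC | 30 | 20 + 2λ |
| QSOrder | 50 | 2 matrices × (20 + nlag) |
| SOCNumber | 10 | 2 matrices × nlag |
| NMBroto / Moran / Geary | 3 × 40 | 8 properties × nlag each |

λ, nlag and the EGAAC window are not independently specifiable for the
published layout: 5 is the maximum admissible value for hexapeptides
(correlations need λ ≤ L−1, the window needs w ≤ L), and exactly this
choice makes the family dimensions sum to 4125. All three remain
configurable (`DescriptorConfig`), and the total dimension is a
deterministic function of the configuration.

Weights: PAAC/APAAC use w = 0.05 and QSOrder uses 0.1 — the customary
defaults of the descriptor literature, exposed in the configuration.

Conventions worth stating:

* PAAC/APAAC/QSOrder composition terms use frequencies with joint
  normalization x_u = f_u / (Σf + w·Σθ), so each normalized block sums
  to exactly 1.
* CTDD reports, for each property × group, the sequence position (as a
  percentage of length) of the first occurrence and of the occurrences
  at the ceil(q·n) index for q = 25/50/75%, plus the last; an absent
  group contributes five zeros.
* DDE uses the standard-genetic-code codon counts (61 sense codons) for
  the expected dipeptide frequency, Tm = (C_a/61)(C_b/61), with
  variance Tv = Tm(1−Tm)/(L−1).
* Moran and Geary autocorrelations of a constant (homopolymer) property
  sequence are defined as 0 rather than 0/0; constancy is detected as
  max = min, not via a float-epsilon variance.
* Column names follow `family.property.position_or_lag` (e.g.
  `aaindex.ANDN920101.pos3`, `qsorder.grantham.tau2`), fixed and
  documented so feature matrices are diffable across runs.

### Property tables

Numeric tables ship as plain-text TSV with a SHA-256 manifest, verified
at load:

* **AAindex**: the 531 AAindex1 entries with complete values for the 20
  standard residues (of 544 total). The 8 autocorrelation properties are
  the usual accessions (CIDH920105, BHAR880101, CHAM820101, CHAM820102,
  CHOC760101, BIGC670101, CHAM810101, DAYM780201), standardized over the
  20-residue table.
* **Grantham distances**: recomputed from Grantham's formula
  (α = 1.833, β = 0.1018, γ = 0.000399, scaled to mean 100) using the
  composition/polarity/volume indices; spot-checked against the
  published table (L–I ≈ 5, C–W ≈ 215).
* **Physicochemical distance matrix**: the second QSOrder/SOCNumber
  matrix is a *synthetic stand-in* for the Schneider–Wrede matrix
  (`physchem_distance_synthetic.tsv`): Euclidean distance over the three
  standardized PAAC properties, scaled to max 1. It is constructed in
  the same spirit (hydrophobicity/hydrophilicity/side-chain geometry)
  but is not the published matrix; descriptors built on it are
  internally consistent and dimensionally identical.
* z-scales (5 × 20), PAAC properties (hydrophobicity, hydrophilicity,
  side-chain mass), the 13 CTD three-way groupings, the 5-way GAAC
  partition and codon counts are the standard published values.

## Classifiers

### Kernel naive Bayes

Per class c and feature j, the class-conditional density is a Gaussian
KDE over the whole real line (unbounded support) with bandwidth
h_cj = σ_cj (4 / 3n_c)^{1/5} (normal-reference rule, sample σ).
Bandwidths are floored at 0.05 × the pooled per-feature standard
deviation (+1e-12): without the floor, near-constant class-feature pairs
produce spike kernels whose tails contribute log-density deficits of
hundreds to billions of nats, letting a single feature veto the other
4124. Per-feature densities are floored at 1e-300 before the log — this
keeps the 4125-term log-sum finite while preserving the genuine
evidence carried by far-tail values (raising this floor measurably hurts
accuracy, so it is purely an underflow guard). Priors are class
frequencies; posteriors are normalized exponentials of
log-prior + Σ log densities; posterior ties resolve to the negative
class (the conservative call for a screening tool).

Implementation note: most descriptor features take few distinct values
(positional encodings ≤ 20, compositions ≤ 7), so the KDE mixture is
collapsed exactly onto its unique values with multiplicity weights;
features with > 32 distinct values use the direct per-sample form. The
kernel arithmetic runs in float32 (per-feature log densities are O(10²),
far inside float32 range) with float64 accumulation; the collapsed and
direct paths agree with a float64 brute force to ~3e-6.

### GentleBoost

Rounds t = 1..T fit a weighted least-squares regression tree f_t to the
±1 labels under weights w, add ν·f_t to the additive score F, and update
w ← w·exp(−y·ν·f_t(x)) with renormalization. Trees are grown best-first
by weighted-SSE reduction with at most `max_split` internal splits;
candidate thresholds are midpoints between consecutive distinct feature
values; leaf values are weighted means, clamped to ±4 so the exponential
weight update stays finite. Ties between equally good splits resolve to
the lowest feature index, then the smallest threshold; F(x) = 0 resolves
to the negative class. The split search is exhaustive (verified against
enumeration), vectorized across all features simultaneously.

Shipped presets `exp1`–`exp8` pair each classifier configuration with a
cross-validation fold count: e.g. `exp1` is GentleBoost with max_split
26, 67 learners, learning rate 0.5915 at k = 5, and `exp2`/`exp5`/`exp8`
are kernel naive Bayes at k = 5/10/15. One preset's learner count was
published only as "Auto"; it is exposed as an explicit integer
defaulting to 30.

Models serialize to versioned portable JSON; loading a corrupt or
future-versioned file raises a clean error naming the versions.

## Evaluation

ACC = (TP+TN)/N, SN = TP/(TP+FN), SP = TN/(TN+FP), Q = (SN+SP)/2,
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
error rate = (FP+FN)/N. Zero-denominator conventions: an undefined SN or
SP reports 0, an MCC with any zero factor reports 0 — reports never
contain NaN, and ACC + error = 1, Q = (SN+SP)/2 hold exactly.

ROC curves sweep all distinct scores (positive-class posterior for
kernel NB, F(x) for GentleBoost); AUC is the trapezoid integral, equal
to the probability that a random positive outscores a random negative
with ties counted half.

Cross-validation is stratified k-fold (per-fold class ratios within one
sample of the global ratio): unstratified folds on balanced sets can
produce degenerate per-fold metrics. Per-fold reports are kept, and the
pooled report is computed from summed confusion counts so every sample
contributes exactly once; pooled counts are labelled as such.

The robustness protocol draws n distinct train/test pairs (equality
judged by the union id-set; 1000 retries per pair before erroring) from
the full pool including the records removed at balancing, recomputes all
descriptors per pair, retrains, and evaluates each model on its own
training set (validation phase) and on the held-out pair test set,
averaging ACC/SN/SP across pairs.

## Synthetic fixtures

The generator stands in for the curated amyloid corpora. Sequences are
i.i.d. uniform over the 20 residues; the planted label rule is *positive
iff ≥ 4 of the 6 residues are hydrophobic*, with the hydrophobic set
taken as the hydrophobic group of the standard CTD hydrophobicity
partition (C, L, V, I, M, F, W). This makes the rule literally encoded
by the CTD composition features (`ctdc.*.g3` ≥ 4/6 ⟺ positive), so
end-to-end learnability checks test parameter/structure recovery rather
than luck. Labels are optionally flipped with probability `noise`, and
rejection sampling fills each class bucket exactly, judged on the final
(possibly flipped) label. `gen_reference_corpus` reproduces the corpus
shape of the aggregated experimental datasets (516 positive / 900
negative) so the balance → split → robustness pipeline runs at the
published sizes (removing exactly 384 negatives, yielding 700 + 66).

What the fixtures do *not* show: real amyloid sequence statistics.
Uniform-random hexapeptides have no positional motifs, no composition
bias, and a deterministic label rule aligned with the feature set, so
passing learnability tests demonstrates that the pipeline can recover a
planted signal — not that it attains any particular accuracy on
experimental data. The published corpus-scale accuracies can only be
checked arithmetically, by feeding the published confusion counts
through the metric suite (which the acceptance script does).

On the synthetic fixture at 200-per-class training, GentleBoost
separates the planted rule essentially perfectly, while kernel naive
Bayes sits close to the 0.9 held-out-accuracy mark and its exact value
moves by a few points with the sampled draw — the finite-sample price of
multiplying 4125 per-feature density estimates, most of which are
individually weak for a counting rule. Cheaper draws (100 per class)
land visibly lower.

## Problem sizes and determinism

The test suite and acceptance script run the robustness protocol's pair
*invariants* at the full 100 pairs (pair generation is cheap) and the
retraining loop at 10 pairs with kernel naive Bayes — the package's
choice of a desk-scale workload that still exercises every moving part
at the published 700/66 shapes. Every stochastic operation takes an
explicit integer seed; derived sub-seeds come from `numpy`
`SeedSequence`, and identical seeds reproduce results bit-for-bit on the
same platform.

## Known limitations

* The second inter-residue distance matrix is a synthetic stand-in (see
  above); absolute QSOrder/SOCNumber values are not comparable to
  pipelines using the published Schneider–Wrede matrix.
* Kernel naive Bayes stores its full training matrix (it is a memory-
  based model); serialized models of 700 × 4125 training sets are tens
  of megabytes of JSON.
* The descriptor engine rejects non-standard residues (B, J, O, U, X,
  Z) rather than imputing them; dataset loaders can drop such records
  with a logged warning.
* Hyperparameter search (the original Bayesian optimizer) is out of
  scope; configurations are shipped as fixed named presets.
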