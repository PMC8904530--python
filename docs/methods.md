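# Methods

`pvpstack` predicts whether a protein sequence is a phage virion
(structural) protein. It is a two-level stacked ensemble: a pool of
first-level classifiers trained on heterogeneous sequence representations,
whose probability outputs become the feature vector of a second-level
random forest.

## Model and procedure

**Inputs.** Protein sequences over the 20 standard residues, optionally
accompanied by per-sequence PSI-BLAST ASCII PSSMs (L x 20 log-odds
matrices). Profiles are consumed, never computed; the three profile
descriptors simply require them.

**Descriptors.** Thirteen fixed-length encoders from four views:

| view | descriptors (dim) |
|---|---|
| composition | AAC (20), DPC (400), DDE (400), PAAC (21), APAAC (22), EAAC (20) |
| physicochemical groups | CTDC (39), CTDT (39), CTDD (195) |
| profile | PSSM_AAC (20), PSSM_COM (400), PSSM_DP (400) |
| index-based | AAI (11) |

DDE measures dipeptide deviation from the codon-usage expectation:
`DDE(ij) = (Dc - Tm)/sqrt(Tv)` with `Dc` the observed dipeptide frequency,
`Tm = (Ci/61)(Cj/61)` from synonymous-codon counts `Ci`, and
`Tv = Tm(1 - Tm)/(L - 1)`. PAAC/APAAC use lambda = 1 and weight w = 0.05 by
default, which fixes their printed dimensions (20 + lambda and
20 + 2 lambda); the composition block uses residue *frequencies* so each
vector sums to exactly 1. EAAC averages window AACs (window 5) into a
single 20-vector so the dimension does not depend on sequence length. CTD
uses the standard 13-property, 3-group partition; transitions count
boundary-crossing adjacent pairs in either direction over L - 1;
distribution reports the position of the 1st and the ceil(q n)-th group
occurrence (q = 25/50/75/100 %) as a percentage of L, with five zeros for
an absent group. PSSM descriptors squash scores through the logistic
function (configurable: identity or min-max) and re-order columns to the
alphabetical residue order used everywhere else. The AAI index set is a
documented default of 11 broadly used scales (hydropathy, hydrophilicity,
mass, volume, polarity, isoelectric point, flexibility, accessibility,
helix/sheet/turn propensity), min-max normalized per index and averaged
over positions; any index set of the same shape can be substituted.

**Baseline pool.** Each descriptor feeds 10 classifier families — DT, ET,
KNN, LR, MLP, NB, PLS, RF, SVM, XGB — giving 130 baseline models for the
full descriptor set, kept in fixed descriptor-major, algorithm-minor order.
ET, LR, MLP, RF, SVM and XGB are tuned by maximizing pooled 10-fold
cross-validated MCC over small grids (trees in {100, 200, 500} and
max-features in {sqrt, log2} for RF/ET; C in 2^-5..2^5 and gamma in
2^-15..2^3 for the RBF SVM; C in {0.01..100} for LR; hidden layer in
{32, 64, 128} and alpha in {1e-4, 1e-3} for MLP; depth {3,5,7}, learning
rate {0.05, 0.1, 0.3}, trees {100, 300} for XGB); DT, KNN, NB and PLS use
library defaults. Grid ties break to the first point in enumeration order,
so training is deterministic given (data, seed, grids). SVM probabilities
come from Platt-style sigmoid calibration; PLS regresses on {0,1} targets
with the clipped response used as probability — both families otherwise
lack the probability outputs the stacking layer needs.

**Meta features.** For the training set, each member's column is produced
*out-of-fold*: within stratified folds shared across members, the member's
chosen configuration is refit on the training part and scores the held-out
part, so no sample's meta feature comes from a model that saw it. (An
in-sample mode exists behind a flag for comparison; it memorizes with
flexible learners and is not used for training.) PF is the n x 130
probability matrix, CF thresholds PF at strictly > 0.5, PCF concatenates
both (260 columns, PF block first). New data is featurized by the pool
members fitted on the full training set.

**Two-step selection and meta model.** An XGBoost classifier ranks meta
columns by gain importance (ties to the lower column index; unused columns
score 0). Top-k subsets for k = 5..100 step 5 are then swept: for each k a
random-forest meta-model is tuned (trees in {100, 300, 500}, max-features
in {sqrt, log2}) by pooled 10-fold CV MCC, and the k with the highest MCC
wins, ties going to the smallest subset (parsimony). Subset sizes
exceeding the number of available columns are dropped with a warning. The
final model is the meta forest refit on the chosen columns; a sequence is
called a virion protein when its meta probability is strictly above 0.5.

## Evaluation

ACC = (TP+TN)/n, Sn = TP/(TP+FN), Sp = TN/(TN+FP), and
MCC = (TP·TN − FP·FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), with MCC defined
as 0 when a denominator factor vanishes. AUC is the Mann–Whitney rank
statistic with midrank tie handling (equivalent to the ROC area; checked
in the tests against explicit trapezoidal integration). Cross-validation
pools out-of-fold predictions and computes one metric set on the pooled
vector rather than averaging per-fold metrics: pooling is
threshold-consistent with an independent test and well-defined even when a
fold has a degenerate confusion matrix. Reported values are rounded
half-even to 3 decimals.

## Synthetic benchmark generator

The generator emulates a balanced two-class protein benchmark: negatives
draw residues i.i.d. uniformly; positives add `delta` probability mass to
each residue in a bias set (default {C, H, K}, renormalized), with lengths
uniform in 50–500 and 250 sequences per class by default. `delta = 0.15`
gives strongly separable classes for composition-aware descriptors;
`delta = 0` is an exchangeable null on which any detected signal is a bug.
An optional first-order (dipeptide) bias mode plants signal visible only
to order-aware descriptors. Synthetic profiles add `concentration`
(default 7) to the true residue's column of integer-rounded Gaussian noise
(sd 2), mimicking integer log-odds whose row argmax tracks the sequence.

What the generator does *not* emulate: homology structure between
sequences, domain architecture, realistic amino-acid background
frequencies, length–class correlation, and profile columns shaped by real
alignments. Passing tests therefore demonstrate that the machinery — the
encodings, the leakage-controlled stacking, the selection — behaves
correctly and recovers planted signal; they do not certify accuracy on
real phage proteomes.

## Numerical and design choices

- Residue order inside composition vectors is alphabetical one-letter
  (A, C, D, ..., Y); PSSM files keep PSI-BLAST column order on disk and are
  re-ordered on encoding.
- Ambiguous residues: B→D, Z→E, U→C, X and other letters dropped (default),
  with a strict mode that rejects them.
- PAAC property scales (hydrophobicity, hydrophilicity, side-chain mass)
  are standardized to zero mean and unit population variance over the 20
  residues before computing correlation factors.
- All stochastic components (fold shuffling, every learner, the generator)
  derive from one integer seed; parallelism is disabled (n_jobs=1) so runs
  are bit-for-bit reproducible.
- Degenerate inputs fail fast with messages naming the offending record,
  descriptor or fold (empty sequences, missing profiles, single-class
  labels, folds exceeding class counts, subset sizes exceeding the column
  count).

## Problem sizes used in the shipped checks

The test suite and the reproduction script run the full 13 x 10 pool on a
60-sequence benchmark and the stacking/selection studies on 150–200
samples, with single-point baseline grids and a 50–100-tree meta forest;
these scaled-down sizes preserve every structural property being measured
(pool cardinality, meta-feature dimensions, leakage control, signal
recovery, stacked-vs-baseline comparison) while keeping single-CPU runs
short. The defaults of the library itself are the full-size settings
described above.

## Known limitations

- The pool trains 10 folds x 130 members for PF generation; on large
  benchmarks this is the dominant cost and is not parallelized by default.
- PLS and SVM probabilities are calibrated approximations, not likelihoods.
- The CTDD occurrence-percentile rounding convention varies between
  published implementations; ours (ceil(q n), minimum 1) is documented
  above and enforced by oracle tests, but other tools may differ at small
  group counts.
- Model archives are joblib pickles: portable across runs of the same
  library versions, not a long-term interchange format.
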