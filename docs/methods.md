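# Methods

## Problem and model

The package addresses binary classification of protein sequences into
cancerlectins (lectins with cancer-associated activity, the positive class)
and ordinary lectins (negative class). The predictor is a Random Forest
trained on a hybrid "multiview" representation of each sequence, with class
imbalance handled by SMOTE and dimensionality reduced by a two-step
filter/wrapper selection. The stages are independent library functions; the
`cancerlectin` CLI and `run_pipeline` compose them.

## Feature views

**CTD (147).** Seven physicochemical properties (hydrophobicity, normalized
van der Waals volume, polarity, polarizability, charge, secondary-structure
propensity, solvent accessibility) each partition the 20 amino acids into
three groups. Per property: composition C_i = N_i/L (3), transition
T_{ij} = (N_{ij}+N_{ji})/L over cross-group dipeptides (3), and distribution
— the 1-based positions of the first, 25%, 50%, 75% and last residue of each
group divided by L (15). Two conventions required a decision:

* *Transition denominator.* The classical T formula is often written with
  denominator L even though a length-L sequence has only L−1 dipeptides. We
  default to L for fidelity to the formulation we implement and expose
  `denominator="L-1"` for the conventional normalization. The two differ by
  the factor L/(L−1), which is immaterial to tree classifiers.
* *Distribution quantile rule.* The residue at rank ⌈q·N⌉ among the N
  ordered occurrences of the group (q ∈ {0.25, 0.5, 0.75}); a group absent
  from the sequence contributes five zeros rather than an error, which keeps
  the dimension fixed for short sequences.

**PseAAC (70).** Classical Type-1 pseudo amino acid composition with λ = 50
tiers and weight w = 0.15: the 20 residue frequencies plus λ sequence-order
correlation factors θ_j, all divided by Σf + wΣθ so the vector sums to one.
θ_j averages, over all residue pairs at lag j, the mean squared difference
of three standardized indices (Tanford hydrophobicity, Hopp–Woods
hydrophilicity, side-chain mass; packaged in
`data/pseaac_indices.tsv`, standardized to zero mean / unit population SD
over the 20 residues). λ = 50 requires L ≥ 51; shorter sequences are
rejected with the required minimum in the message, and `--lambda` lowers the
tier count uniformly when a dataset contains short proteins. The weight's
conventional range is 0.05–0.70 (`PseaacParams` enforces it); the encoder
itself accepts any w ≥ 0 so that the w → 0 limit, plain amino-acid
composition, is checkable.

**Profile features (120).** A PSI-BLAST ASCII PSSM supplies one row of 20
log-odds scores per residue. Scores are mapped to (0,1) with the sigmoid
1/(1+e^(−x)) *before* any summary (both summaries consume scaled values; the
alternative — raw-score centering — is a defensible reading, but scaling
first keeps both feature groups on one scale). PSSM-AAC is the 20 column
means; PsePSSM is the lag-j autocovariance of each column for j = 1..γ
(γ = 5 default), centered on the whole-sequence column mean and normalized
by L−j. Flattening is residue-major, lag-minor. The parser reads the first
20-column block, remaps the file's column order to the canonical
alphabetical residue order, and reports line numbers on malformed input.
Records without a profile are dropped by default; an explicit
`pssm_fallback="pseudo"` substitutes sigmoid-scaled BLOSUM62 rows of the
observed residues — a sequence-only approximation carrying no alignment
information, intended for demonstrations.

**Disorder (28).** Per-residue disorder scores in [0,1] (any predictor's
output; tab-separated position/residue/score files) are summarised as the
global mean and population SD (2), counts of disordered/ordered segments at
threshold 0.5 — the usual disorder decision boundary, configurable — (2),
min/max segment lengths per kind with 0 for an absent kind (4), and the
mean score per amino-acid type with 0 for absent residues (20). A residue is
disordered when score ≥ threshold.

## Imbalance handling

SMOTE appends synthetic minority rows until the classes are exactly equal.
Each synthetic point is x + u·(x_nn − x) for a minority sample x, one of its
k = 5 nearest minority neighbours x_nn (Euclidean on raw features;
`standardize=True` z-scores for the distance computation only) and
u ~ U[0,1]. Base samples are cycled in a seeded random order so the
oversampling amount need not be a multiple of the minority size. Synthetic
rows are flagged in the `FeatureMatrix` and in the CSV output.

`cross_validate` supports three placements: `pre_split` (balance the whole
matrix, then split — synthetic rows can land in test folds, exactly as a
balance-then-cross-validate protocol implies), `per_fold` (balance training
folds only; test folds stay real — the leakage-safe variant), and `off`.
The default is `pre_split`; `per_fold` is the one to prefer for honest
generalization estimates, and the report records which was used.

## Feature selection

**Step 1 — ReliefF filter.** All n instances are visited; for each, the
k = 10 nearest same-class hits and nearest other-class misses (Euclidean on
min-max-scaled features) contribute mean|miss-diff| − mean|hit-diff|, scaled
by 1/n, to every feature's score. Constant features have zero range, hence
exactly zero score. Features with score strictly > 0 are retained, in rank
order.

**Step 2 — SFS wrapper.** Greedy forward selection over the retained
candidates: at each step the candidate maximizing pooled 5-fold Random
Forest accuracy on the current set ∪ {candidate} is added; the stratified
fold splits are fixed once per run so accuracies are comparable across
steps, and accuracy ties resolve toward the better Relief rank (then lower
index). The reported subset is the trace prefix with maximal accuracy. Full
SFS over p candidates costs O(p²) model fits; `sfs_candidates` (pool cap)
and `sfs_cap` (addition cap) bound the cost, and the wrapper forest size
(`sfs_trees`, default 30 in the pipeline) is deliberately smaller than the
final evaluation forest.

## Classifier and evaluation

Random Forest with 100 trees, √M features per split, unlimited depth —
a modern default; every value is logged in the run manifest. Predicted
labels use the ensemble vote fraction with a strict 0.5 threshold (ties →
negative); ROC curves sweep all distinct vote fractions of the pooled
out-of-fold scores, and AUC is the trapezoidal area (the test suite
cross-checks it against the Mann–Whitney rank form). Sn, Sp, Acc and MCC are
computed per fold and pooled from summed confusion counts; MCC is defined
as 0 when a marginal is zero. Folds are stratified, shuffled, and
deterministic given the seed. `compare_classifiers` evaluates alternative
learners under identical folds; Decision Table and RBF-network analogues
from older Java toolkits have no scikit-learn counterpart, so the roster is
RF, AdaBoost, decision tree, 1-NN, logistic regression, Gaussian naive
Bayes and a majority-class dummy.

## Synthetic data

The generator writes everything the pipeline consumes: FASTA pairs, PSSM
files in the genuine PSI-BLAST ASCII layout (so the parser is exercised
against the real dialect, including the percentage block and trailing
statistics), disorder tracks, and a label manifest — byte-identical given
the seed. Sequences are i.i.d. draws from class residue-frequency profiles;
`separation` moves that much probability mass onto the hydrophobic residues
CFILMVW in the positive class. PSSMs add +4 to the observed residue's
column over integer noise in ±2; disorder tracks are window-5 moving
averages of uniform noise around a per-protein baseline drawn from
N(class mean, 0.1), class means 0.55/0.45, clipped to [0,1]. Minimum length
56 keeps every encoder's precondition satisfied (λ+1 = 51, γ+1 = 6).

What the fixtures do *not* emulate: real lectin domain architecture,
alignment-derived conservation (the synthetic PSSM restates sequence
composition), sequence redundancy, or realistic disorder runs. Passing
tests therefore demonstrates the correctness and the directional behavior
of the machinery (SMOTE raises sensitivity on imbalanced data, selection
beats random subsets, separation raises accuracy), not field performance on
real cancerlectins — for that, supply the real FASTA pair plus PSI-BLAST
and disorder-predictor outputs.

## Benchmark sizes and numerical choices

`scripts/acceptance.py` builds a 178-positive / 226-negative synthetic
dataset (the study-scale composition) at weak compositional separation
(0.05) so the task has genuine class overlap rather than saturating every
metric; SFS runs on the top-40 Relief candidates with a 13-addition cap and
a 30-tree wrapper forest, and all final evaluations use 100 trees. These
sizes are the package's demonstration defaults and complete in a few
minutes on one core.

Degenerate inputs: empty groups and absent residue types encode as zeros
(never NaN); all-equal score columns give zero autocovariance; an
already-balanced matrix passes through SMOTE unchanged; Relief retaining
nothing aborts the pipeline with a clear error. All randomness flows from
explicit integer seeds; per-fold forests use seed+fold so folds are
independent but reproducible.

## Known limitations

* Published results on the real dataset are not reproducible here without
  the original sequences plus PSI-BLAST (3 iterations, E = 0.001,
  Swiss-Prot) and VSL2 runs; the package consumes those artifacts, it does
  not produce them.
* The exact PseAAC index constants used by any given study may differ from
  the packaged canonical table; encodings of real data can differ slightly
  under a different constants source.
* `pre_split` SMOTE leaks synthetic copies of training information into
  test folds and overstates accuracy; it is kept as the default for
  protocol fidelity, with `per_fold` provided and recommended for unbiased
  estimates.
* ReliefF neighbor count and sampling size, the SFS tie rule, and the
  disorder segmentation threshold are conventions chosen here (documented
  above) — other choices yield slightly different rankings.
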