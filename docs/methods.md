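# Methods

## Input model and scaling

The unit of input is one protein's PSI-BLAST profile: an L×20 matrix of
integer log-odds scores, columns in the fixed order A R N D C Q E G H I L K
M F P S T W Y V, plus the residue sequence. The parser accepts both common
ASCII dialects (20 numeric columns, or 40 plus two per-row statistics) and
always takes the first 20 numeric columns as log-odds — the PSI-BLAST
convention. Rows with ambiguity residues (X etc.) are kept: PSI-BLAST still
assigns them a score row, and dropping them would silently change L and
every downstream feature. Positions are 1-based in files and 0-based in
memory.

All features operate on the sigmoid-scaled matrix p = 1/(1+e^(−x)). The
logistic function is the conventional choice for mapping log-odds into
(0,1); in float64 it saturates to exactly 0 or 1 for |x| ≳ 37, so outputs
are clamped to the nearest representable value inside the open interval.
Real PSI-BLAST scores stay within roughly ±16, where no clamping occurs.

## Feature definitions and numerical choices

Reduced-alphabet features use a fixed 10-group similarity alphabet
({FYW},{ML},{IV},{ATS},{NH},{QED},{RK},{C},{G},{P}) with group columns
formed as member-column means; the grouping and the merge rule (mean or
sum) are constructor arguments, so alternative alphabets can be swapped in.
Three definitional details deserve note, since variants circulate in the
literature:

- the pseudo-composition D_s centres each reduced column on its **mean**
  (1/L)Σ p_{i,s}; centring on the raw column sum would make D_s grow ~L²
  and is treated as a transcription error in some published statements of
  the formula;
- the dipeptide composition y_{i,j} uses the **cross-column** product
  p_{k,i}·p_{k+1,j}; the same-column variant cannot produce 20×20 distinct
  values;
- the composition x_j averages over **all L rows** (the formula is
  occasionally printed with an L−1 bound and an L divisor, which is
  inconsistent with "averaging each column").

The dipeptide variance term D_{s,t} is computed by direct broadcasting of
(p_{i,s} − p_{i+1,t})² rather than the expanded a²+b²−2ab form, which
suffers catastrophic cancellation when adjacent rows are similar; the
direct form agrees with naive-loop reference implementations to ~1e−15
relative error. Feature names (`rpssm_D_s`, `rpssm_Dst_s_t`, `aac_A`,
`dpc_A_R`, …) and their order are fixed so serialized tables are stable;
CSV output uses 17-significant-digit floats and is read back with
round-trip float parsing, making extract runs byte-identical.

The combined vector is RPSSM (110) then AADP (420). The concatenation
order is irrelevant downstream — both the ranking and the classifiers are
order-agnostic — and is fixed only for file stability.

## MRMD feature ranking

The published description of Max-Relevance-Max-Distance names the two
ingredients but not one canonical formula, so this implementation uses the
reference algorithm's common reading and exposes the knobs: relevance is
|Pearson r(feature, label)|; distance is the feature's mean pairwise
distance to all other z-scored feature columns (Euclidean default, cosine
and Tanimoto options); the score is relevance + weight·distance with
weight 1. Euclidean distances are divided by √n (for z-scored columns this
equals √(2(1−r)) ∈ [0,2]), keeping the two addends on commensurate scales
regardless of sample count. Constant columns get relevance 0 and distance
0 — never NaN — and are excluded from other features' distance means. Ties
are broken by original column index, so rankings are deterministic.

Subset size: when no k is given, a one-standard-error rule picks the
smallest k whose cross-validated accuracy is within one SE of the best
mean over a supplied k grid. The benchmark study never states its final
subset size, so no default k is privileged; the pipeline examples use
k = 100 of 530, large enough to retain both feature families.

## Sampling

Undersampling keeps the minority class in full and draws
round(ratio·n_minority) majority samples without replacement (default
ratio 1:1). It is intended for the training portion only; the held-out
test set keeps its natural imbalance, mirroring how the benchmark's test
statistics are reported. The stratified splitter preserves class
proportions within ±1 sample and guarantees disjoint ID sets.

## Stacked ensemble

Base learners and their fixed hyperparameters: LightGBM (learning rate
0.05, 400 boosting rounds, max depth 7, row subsample 0.8 — "subsample"
read as the row-sampling fraction), RBF-SVM (γ = 0.018, C = 19) and
extremely randomized trees (100 trees, min split 2, min leaf 1). SVM
probabilities come from Platt sigmoid calibration with an internal
stratified 5-fold CV seeded from the global seed. The out-of-fold matrix
stores positive-class **probabilities** (a hard-label mode exists):
probabilities retain ranking information the meta-model can use and are
needed for soft voting anyway. Folds are stratified by class by default so
a balanced training set cannot yield single-class folds; a fold whose
training complement is single-class raises with advice rather than
producing a degenerate base model. The meta-model is logistic regression
(lbfgs, ≤100 iterations) on the n×3 OOF matrix only — no pass-through of
the original features. For inference the three bases are refit on the full
training table, the standard stacking choice when fold models are not
averaged. The decision threshold is 0.5 and exposed.

The no-leakage property — sample i's OOF entries are invariant to changes
in sample i's label — holds for a **fixed** fold assignment; stratified
fold construction itself reads the labels, so the leakage test fixes folds
first, which is why `generate_oof` takes the fold map as an argument.

## Evaluation

SN, SP, ACC (in percent) and MCC follow the standard confusion-matrix
formulas; a zero factor in the MCC denominator yields MCC = 0 by
convention. Two AUC variants are always reported side by side because they
answer different questions: the trapezoidal area under the threshold-swept
ROC curve (equal to the Mann–Whitney rank statistic; tied scores share one
threshold), and the single-operating-point quantity (SN+SP)/2 (balanced
accuracy), which some studies print under the name "AUC" even though it
cannot reproduce a swept ROC curve. Cross-validation std columns use the
sample (n−1) convention. McNemar's test uses the exact two-sided binomial
when the discordant count b+c < 25 and the continuity-corrected chi-square
(|b−c|−1)²/(b+c) otherwise.

## Synthetic data

The generator stands in for the restricted benchmark corpus. Scores are
drawn as rounded Gaussians (mean 0, sd 2 — matching the typical spread of
real log-odds scores), with the positive class shifted by `effect_size`
score units on a designated column subset (default: the first 4 columns)
**before** sigmoid scaling, so the signal propagates through both feature
families exactly as a real evolutionary signal would. Rounding to integers
mimics PSI-BLAST output and is applied after the shift. Residue letters
are the per-row argmax column — plausible but cosmetic, since no feature
reads the sequence. Default sizes (150 + 150 training profiles, lengths
uniform on [30, 80]) keep the full pipeline runnable in seconds; the
benchmark's 2533:9086 imbalance is available as an explicit preset in
tests. What the generator does **not** model: inter-column covariance of
real alignment profiles, positional autocorrelation, domain structure, or
amino-acid biochemistry. Passing tests therefore demonstrate pipeline
correctness and sane statistical behavior (chance-level ROC at zero effect,
monotone improvement with effect size), not real-data performance, which
for the original benchmark additionally depends on a licensed dataset and
a PSI-BLAST database.

## Problem sizes used in the checks

The formula oracles run on 50 random profiles with L ∈ [2, 60]; metric
oracles on 1,000 random confusion tables; the leakage check exhaustively
perturbs all 40 samples of a 10-fold table (with reduced-size base
learners — the property is independent of model scale); the end-to-end
run trains on 300 profiles and tests on 200 at effect size 2.0, with a
400-sample chance control at effect size 0.

## Known limitations

- The ASCII parser targets the PSI-BLAST layout; checkpoint/binary PSSM
  formats and nucleotide profiles are out of scope.
- MRMD is the only selector shipped; recursive-elimination and manifold
  methods are deliberately not included.
- Base families are fixed to the three the stack uses; other learners can
  be compared via `grid_search` and the evaluation utilities but are not
  first-class configs.
- Model archives are joblib pickles: portable across runs on the same
  library versions, not a long-term interchange format.
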