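# Methods

## Model and procedure

The pipeline classifies protein sequences into two classes from
physicochemical composition alone. Its stages, and the assumptions each
makes:

1. **Encoding.** A sequence becomes a vector of mean amino-acid property
   values, one feature per AAindex1 table. This is a pure composition
   statistic: residue order, length and local motifs are invisible to it.
   The implicit assumption is that class membership correlates with global
   amino-acid composition weighted by physicochemical scales. Residues
   outside the 20 standard amino acids (B, Z, X, U, O, J) and residues
   whose table value is missing (`NA`) are excluded from both the
   numerator and the divisor, so the feature is the unbiased mean over
   contributing residues rather than an imputation. A sequence with no
   contributing residue for some table is an error, not a silent zero.

2. **Standardization.** Features are z-scored with training-set statistics
   (sample standard deviation, n−1 denominator). Raw AAindex scales differ
   by orders of magnitude, and both the RBF kernel and the distance-based
   ReliefF are scale-sensitive, so unscaled features would let a few
   large-scale properties dominate. Zero-variance training features are
   kept as all-zero columns (scale forced to 1) so that feature indices
   remain aligned with their accessions. Scaling can be disabled
   (`standardize=False` / `--no-standardize`) to probe its effect.

3. **Feature selection.** Three filter methods, all deterministic given
   their inputs, ranked scores descending with ties broken by ascending
   original feature index:
   - *ReliefF*: every instance is used once in a fixed order (equivalent
     to exhaustive sampling, and row-order invariant); k = 10 nearest hits
     and misses by default, found under the Manhattan distance on
     range-normalized feature differences; miss contributions carry the
     class-prior weight P(miss class)/(1 − P(own class)), which is 1 for
     two classes with empirical priors.
   - *Information gain*: each feature is discretized by the Fayyad–Irani
     recursive MDL binary-split criterion on the training data; the score
     is H(class) − H(class | bins) in bits, 0 when MDL accepts no cut.
     MDL is deliberately conservative at small n: weak splits score 0
     rather than noise.
   - *mRMR*: features are discretized into 3 states at mean ± one sample
     standard deviation; greedy forward selection by the MID (difference)
     criterion I(f; class) − mean I(f; selected). The ranking is the
     selection order and its scores are the stepwise criterion values,
     which are not monotone.

   Selection is fitted once on the full training set and frozen
   (`nested=False`, the default); that is the protocol classically
   reported with this method family, but it lets selection see the CV
   folds' held-out data, so CV accuracies are optimistic. `nested=True`
   re-runs selection inside every fold for honest estimates at the cost of
   one ranking per fold.

4. **Classifier.** A soft-margin SVM with the Gaussian kernel
   K(u, v) = exp(−γ‖u − v‖²). The quadratic program is solved by
   scikit-learn's libsvm backbone; the stored model (support vectors, dual
   coefficients y·α, bias, γ, feature subset, scaling parameters) is
   self-sufficient, and decision values are recomputed from those fields
   directly — a serialized model reproduces in-memory decision values to
   1e−9. A decision value of exactly 0 maps to class −1, documented and
   tested. Hyperparameters are tuned on the lattice C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵},
   γ ∈ {2⁻¹⁵, 2⁻¹³, …, 2³} (the customary libsvm-guide grid) by stratified
   5-fold CV; among cells with equal CV accuracy the smallest C wins, then
   the smallest γ — preferring low model complexity. Stratification keeps
   class balance in every fold; a plain random split is available by
   calling the fold assignment with unstratified labels if ever needed.
   All randomness flows from one explicit seed recorded in model metadata.

5. **Evaluation.** Accuracy, sensitivity and specificity as percentages
   (2 decimals), MCC to 4 decimals, matching the conventional table
   formats. When any confusion-matrix marginal is zero the MCC denominator
   vanishes; the value is reported as 0 with an `mcc_undefined` flag. ROC
   curves come from the continuous decision values (ties grouped), AUC by
   the trapezoid rule, which equals the normalized Mann–Whitney statistic
   without ties.

## Synthetic data: what it emulates and what it does not

The generator emulates a two-class protein study at the classical design
of 300 positive + 300 negative training sequences. Class −1 draws residues
i.i.d. from a base frequency vector (uniform by default; any 20-simplex
vector can be supplied); class +1 shifts a total extra probability mass δ,
split evenly across `n_informative` residues, and renormalizes. δ is thus
the total composition effect size: δ = 0 makes the classes exchangeable,
and because the encoder measures exactly residue composition, selector and
classifier power are analytically controlled by δ. Sequence lengths are
uniform in (50, 300) residues — the scale of typical protein domains — and
0.5% of positions are 'X' to exercise the encoder's non-standard-residue
path. Synthetic property tables draw standard-normal values per residue
with 2% missing entries; 100 tables by default, enough that selecting 50
of 100 is a non-trivial decision while the feature space stays comfortably
explorable.

What passing tests on this data do **not** show about real proteins:
residues here are i.i.d., so there is no domain structure, no homology
between sequences, no length–class correlation, and no correlated
property tables (real AAindex entries are strongly mutually correlated).
Real-data performance therefore cannot be inferred from synthetic
accuracy; the synthetic suite demonstrates correctness and calibration of
the machinery, not biological effect sizes. In particular, with dense
random tables nearly every property loads at least weakly on the shifted
residues, so the ground-truth "informative" list marks properties with a
nonzero analytic class-mean difference, not a sparse subset.

## Numerical choices

- Tie-breaks: everywhere ascending original feature index (selectors),
  smallest C then smallest γ (grid), ascending row index (ReliefF
  neighbor distance ties, via stable sort).
- Feature-matrix TSV uses shortest round-trip float representation, so
  write→read is exact and repeated runs are byte-identical.
- MDL split search requires a strict improvement of 1e−12 to change the
  best cut, making the chosen cut independent of enumeration order.
- Degenerate inputs: constant features get ReliefF weight exactly 0 and
  info-gain 0; constant columns standardize to zeros without division by
  zero; single-class inputs are rejected by every selector, the trainer
  and the ROC code.
- The worked-example confusion matrix used in tests and the acceptance
  script (TP=105, FP=30, TN=160, FN=36) is the unique integer matrix
  consistent with the published percentages for 141 positives and 190
  negatives; the originally stated 18 202 test negatives are
  arithmetically inconsistent with every published specificity value, so
  the reconstruction uses 190. This discrepancy is documented, not
  resolved.

## Problem sizes in tests and the acceptance script

Unit and oracle tests run on fixtures of ≤ 30 instances and ≤ 5 features,
where brute-force re-implementations are exact. Pipeline-level checks use
the design conditions (300+300 train, 100+100 test, 100 properties,
ReliefF top-50): a null calibration averaged over 10 seeds (accuracy must
stay within 50 ± 5 points — the leak detector for the whole pipeline) and
one signal-recovery run at δ = 0.3 (≥ 90% held-out accuracy required;
measured runs land near 98–99%). These sizes were chosen as the smallest
at which the design's claims are meaningfully testable.

## Known limitations

- Composition encoding discards all positional information; two sequences
  that are permutations of each other are indistinguishable by design.
- Selection outside CV (the default protocol) biases CV accuracy upward;
  use `nested=True` for unbiased estimates.
- The exact (C, γ) chosen on real historical datasets is unknowable from
  the published record, so numerical results on such data depend on the
  grid and are not exactly reproducible; only the metric arithmetic and
  the algorithmic contracts are.
- Only AAindex1 (single-residue) indices are supported; pair and matrix
  indices (AAindex2/3), k-mer or pseudo-composition encodings, and
  multi-class problems are out of scope.
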