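# Methods

## The modelling problem

MGMT (O⁶-methylguanine-DNA methyltransferase) repairs alkylated guanine
and blunts alkylating chemotherapy; base analogs that inactivate MGMT
restore drug sensitivity. Potency is measured as ED₅₀ (µM), the dose
producing 50% MGMT inactivation, modelled on the log scale as
pED₅₀ = −log₁₀ ED₅₀. The package supports two complementary analyses
of such a series: a quantitative MLR model of pED₅₀ over molecular
descriptors, and a semi-quantitative binary classification
(inhibitor/non-inhibitor) over fingerprint bits, followed by
substructure mining.

## Curation and labelling

A compound is labelled an inhibitor (P) when its potency exceeds 1/50
of the reference inhibitor O⁶-benzylguanine — i.e. ED₅₀ strictly below
50 × the reference ED₅₀; "more than 1/50" is read strictly, so potency
exactly at the cutoff is N. Censored activities are handled
explicitly: a bound ">x" with x at or above the censoring cutoff
(default 10 µM) is N; "<x" with x at or below the activity cutoff is P;
a bound straddling the cutoff cannot be resolved and is left unlabeled
with a warning. When the reference itself is a bound ("<1 µM"), the
cutoff is taken at the bound, the conservative choice for P labels.

Two split protocols are provided. The regression split ranks compounds
by pED₅₀ and takes one compound per complete block of five into the
test set, giving test sets spread evenly across the activity range; the
within-block offset defaults to the middle position (the rule only
fixes "one in five", not which one) and a trailing partial block
contributes no test compound — this yields 83/20 at n = 103 and 68/16
at n = 84. The classification split is random, stratified by class at
4:1, with each class contributing round(n/5) test compounds; on a
62 P / 67 N set this gives the 104/25 split with 48.1% / 48% positives.
Stratification is assumed because the near-equal class proportions in
both sets are otherwise improbable.

Descriptor pre-filtering drops columns whose modal value exceeds 80%
of rows (near-constant), then scans columns in order and drops the
later member of every pair with |r| > 0.95. Keep-first-in-order is the
tie-break; the operation is idempotent.

## MLR, Q²_LOO and the GA

OLS with intercept; a singular design is rejected with the dependent
columns named. The leave-one-out statistics use the hat-matrix
shortcut: deleted residual eᵢ/(1 − hᵢ), PRESS = Σ of their squares,
Q²_LOO = 1 − PRESS/SS_tot. The shortcut is verified in the test suite
against explicit n-refit enumeration to 1e-9.

Descriptor selection follows the published protocol where it is stated
and standard GA practice where it is not. Stated: Q²_LOO fitness,
population 200, mutation parameter 20, 2000 generations, all-subsets
seeding at up to 2–3 descriptors, and the rule-of-thumb cap
max descriptors = ⌊n_train/5⌋. Our choices for the unstated parts:
the mutation parameter is read as a 20% per-chromosome gene-flip
probability (the source gives no unit); crossover is uniform over the
union of parent genes at rate 80%; selection is tournament (size 2)
over a fitness-sorted population; elitism keeps the best 2; children
exceeding the cap are repaired by random gene removal; equal fitness is
tie-broken lexicographically by descriptor-name list so runs are
deterministic under a seed. Fitness values are cached per subset. The
best-fitness trace is non-decreasing by construction.

## Validation battery

* Fit: R² = 1 − SS_res/SS_tot, R²_adj = 1 − (1−R²)(n−1)/(n−p−1),
  RMSE = √(SS_res/n) (divisor n, the common QSAR reporting convention;
  n−p−1 available by flag), F = (SS_reg/p)/(SS_res/(n−p−1)), and Lin's
  CCC = 2s_xy/(s_x² + s_y² + (x̄−ȳ)²).
* External: Q²_F1 = Q²_ext = 1 − PRESS_ext/Σ(y_test − ȳ_train)²;
  Q²_F2 with the test mean; Q²_F3 = 1 − (PRESS_ext/n_test)/(SS_train/n_train);
  R²_ext the squared Pearson correlation. Q²_F1 ≥ Q²_F2 always, since
  the train mean cannot beat the test mean on the test set's SS.
* Golbraikh–Tropsha: through-origin slopes k = Σyŷ/Σŷ² and
  k′ = Σyŷ/Σy²; R₀² = 1 − Σ(y − kŷ)²/Σ(y − ȳ)² and the primed analogue
  with y and ŷ exchanged (the source names but does not print these
  formulas; the standard definitions are used). Conditions:
  (i) Q²_LOO > 0.5, (ii) R²_ext > 0.6, (iii) closeness 0.1 with slope
  in [0.85, 1.15] in either direction, (iv) |R₀² − R′₀²| < 0.3.
* QUIK: K = Σⱼ|λⱼ/Σλ − 1/m| / (2(m−1)/m) over the eigenvalues of the
  column correlation matrix; a model passes when K_XY − K_X ≥ 0.05.
  The K formula comes from the multivariate-correlation literature the
  rule is built on (only the threshold is stated at the source); it is
  pinned down by its limiting cases (orthogonal → 0, collinear → 1,
  r = 0.5 pair → 0.5) in the tests.
* Y-scrambling permutes the response only (not rows of X), refits the
  chosen descriptor subset and records R² and Q²_LOO per iteration;
  default 2000 iterations.
* MCDM: each criterion is mapped linearly onto [0, 1] between its
  worst and ideal values (clipped) and the score is the arithmetic
  mean — the simplest monotone desirability; weights are configurable.

## Applicability domain

Leverage of a query x against the training design (intercept included)
is h = x′(X′X)⁻¹x; training leverages sum to p + 1. The warning
leverage is h\* = 3(p + 1)/n with p counting descriptors only — this
convention is fixed by the published worked values 3(5+1)/83 = 0.217
and 3(9+1)/68 = 0.441. Standardized residuals divide by the training
RMSE (simple standardization; a studentized variant dividing by
√(1 − h) is available by flag, the source not specifying either), and
|std residual| > 3 flags a response outlier.

## Classification benchmark

The seven learners run at the study's hyperparameters: kNN with k = 5,
Euclidean, distance-weighted; logistic regression; naive Bayes
(Bernoulli, matching binary fingerprint features); a one-hidden-layer
MLP with 200 neurons; SVM with linear kernel and cost 1.00 (the
protocol mentions both RBF and linear and then fixes the linear/1.00
setting, which is the default here; RBF by flag); random forest with
20 trees; and a decision tree with min 3 instances per leaf, no
splitting below 5. Implementations are scikit-learn's; the harness,
metrics and AUC are owned by this package. Cross-validation is
stratified 10-fold with out-of-fold predictions pooled into one
integer confusion matrix per learner (pooling, rather than per-fold
averaging, keeps counts comparable to external-set counts; the source
does not state which it used). AUC is the Mann–Whitney concordance
with mid-rank tie handling, verified against exhaustive pair counting.
Models are ranked by AUC, then CA, then name.

## Substructure mining

For each fingerprint bit, freq_C = (N_frag^C · N_total)/(N_frag · N_C)
measures enrichment in class C (1 = no enrichment), and
IG = H(class) − H(class|bit) in bits (base-2, 0·log 0 = 0) measures
discrimination. Both are computed over the pooled labeled set; the
pooled-set and base-2 choices are derivations, not assumptions — they
exactly reproduce the three reference (IG, freq) worked values on the
62 P / 67 N composition (0.096 / 2.08(11), 0.081 / 1.93(13) with
0.14(1), 0.078 / 2.08(9)), which a training-only or natural-log
computation does not. The frequency statistic is defined at the source
for the inhibitor class only; the N-class analogue substitutes N_N.
A bit is privileged when it occurs in at least `min_count` compounds
(default 5) with freq_P > freq_N (ratio configurable); results are
ranked by IG descending.

## Synthetic data

The QSAR generator plants a sparse linear model: informative
descriptors are iid standard normal, nuisance descriptors are
equicorrelated Gaussian blocks (default block size 10, correlation
0.7 — reproducing the high inter-correlation regime the >95% filter
targets), and the response adds Gaussian noise (default σ = 0.5 pED₅₀
units) to the planted linear signal, whose coefficients are sized so
the noiseless response spans ≥ 5 log units. Defaults mirror the study
dimensions: 104 compounds, 520 descriptors. The fingerprint generator
draws each bit independently per compound at a class-conditional
probability: planted bits at specified P/N rates, background bits at a
common rate (default 0.2), on the 62 P / 67 N default composition.

What the generators do not emulate: real descriptor marginals (Dragon
descriptors are heavy-tailed, discrete or bounded in ways a Gaussian is
not), inter-bit correlation inside real fingerprints (substructure bits
are strongly nested), and structure–activity coupling (fingerprints
and descriptors are generated independently of each other). Passing
tests therefore demonstrate correctness of the statistical machinery
and recoverability of planted signal under realistic dimensions and
noise — not predictive performance on real chemistry.

One integer seed drives everything; sub-streams are derived with
`numpy.random.SeedSequence.spawn`, so full pipeline runs are exactly
reproducible and byte-identical across repeats.

## Problem sizes and numerical choices

The end-to-end pipeline (`run-all`) defaults to reduced GA settings
(population 50, 200 generations) and a 60-descriptor pool, the scale
at which the selection problem is still non-trivial but a complete run
finishes interactively; the study-scale settings (population 200, 2000
generations, 520 descriptors) are available by flag. The GA parameter-
recovery check in the test suite runs 20 seeds at population 50 / 100
generations against a planted 3-descriptor model among 50 correlated
noise descriptors. Y-scrambling in reduced runs uses 200 iterations.

Degenerate inputs fail loudly rather than silently: singular designs
name their dependent columns, a leverage of 1 aborts the LOO shortcut,
constant columns abort correlation-based statistics (K index, R²),
empty classes abort labelling, CV and AUC. All-subsets enumeration is
guarded by a candidate-count limit (default 200 000) with a pointer to
the GA.

## Known limitations

Quantum-chemical and Dragon descriptor computation is out of scope
(descriptor matrices are inputs); of the six fingerprint dialects only
MACCS (plus MW and Ghose–Crippen ALogP) is computed natively via
RDKit, the others being external-tool outputs that are ingested and
validated. The published models' fitted statistics cannot be
recomputed here because the per-compound descriptor values behind them
are not available; their coefficient sets are shipped for prediction
and their printed-value arithmetic (intercepts, h\*, R²_adj) is
verified instead. Exact reproduction of the published classification
counts is likewise out of reach without the per-compound fingerprints;
the benchmark is validated on synthetic data with known ground truth.
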