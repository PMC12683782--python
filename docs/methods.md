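# Methods

## The model

An epigenetic clock maps a vector of DNA-methylation beta values
(β = M/(M+U) ∈ [0,1] at selected CpG probes) to a predicted age in
years.  Every base clock in this package is evaluated under one uniform
contract,

    age = T( b + Σ_j w_j β_j ),

where `w` and `b` are the clock's published coefficients and `T` is its
output transform: the identity for most clocks, and for the pan-tissue
Horvath clock the piecewise log/linear anti-transform

    T(x) = (1 + a)·e^x − 1        for x < 0
    T(x) = (1 + a)·x + a          for x ≥ 0

with the adult-age constant a = 20.  The exponential branch compresses
childhood ages (development is log-like); the linear branch covers
adulthood; the map is continuous and strictly increasing at x = 0.
Deep-network clocks whose weights are not distributable as a table enter
the registry as *external predictors*: their CpG list participates in
overlap analysis and alignment, and their predictions come from a
user-supplied callable.  No per-clock bespoke preprocessing (per-sample
standardization, array renormalization) is applied: betas are assumed
already normalized to [0,1], and the reader validates but never
rescales.  This uniform contract is a deliberate simplification; a clock
whose original publication prescribed extra preprocessing may differ
slightly from its reference implementation here.

## Ensemble stacking

Base-clock predictions are combined two ways:

* **EnsembleNaive** (uniform stacking): the arithmetic mean of a
  selected clock subset.  The recommended default is six of the eight
  base clocks, excluding Hannum — whose optimal meta-weight is strongly
  negative, something a plain average cannot express — and PhenoAge,
  which targets phenotypic rather than biological age.  Users may select
  any subset; a non-default selection is labelled
  `EnsembleNaive(custom)` in the output.
* **EnsembleLR** (dynamic stacking): an affine combination
  `age = b + Σ_c w_c · base_c` with weights learned by ridge regression
  (L2 penalty α = 0.1 on the weights only; the intercept is
  unpenalized and the features — base predictions, all in years — are
  not standardized, preserving the interpretability of the printed
  weights).  The packaged meta-model ships as a versioned JSON parameter
  file with the published weights and intercept (19.28 y); user-trained
  models are written to separate files and never overwrite it.  The
  ridge penalty is the plain unscaled `α‖w‖²` (no division by n).

## Training with age-group rebalancing

Donor cohorts are typically mid-heavy (40–60 y overrepresented).
Training therefore rebalances decade bins [20,30) … [70,80] by SMOTE
*in methylation feature space, before base-clock prediction*: a
synthetic sample is `x_new = x + u·(x_nn − x)` with u ~ Uniform(0,1),
where `x_nn` is one of the k (default 5) nearest same-bin neighbours by
Euclidean distance; the synthetic age is interpolated with the same u,
so it never leaves its parents' age span, and synthetic betas are convex
combinations, hence stay in [0,1].  Each deficient bin is filled to the
largest observed bin count.  Degenerate bins: an empty bin is skipped
with a warning; a single-member bin is duplicated with a warning; k is
reduced to bin size − 1 when necessary.  The feature space is restricted
to the union of the base clocks' CpGs — the only columns prediction
consumes — which keeps the k-NN search tractable at array scale.

After rebalancing, the cohort is split 80/20 (seeded, stratified by age
bin; stratification falls back to a plain shuffle when a bin has fewer
than two members) and the meta-weights are fit on the training fraction;
MeAE/MAE/slope are reported on the held-out fraction, which contains
synthetic samples too — held-out numbers are internal diagnostics, not
estimates of real-data error.

## Imputation

Missing betas are filled at prediction time, per upload, by round-robin
multivariate regression (scikit-learn's iterative imputer with a
Bayesian-ridge estimator): starting from column-mean fills, each
incomplete CpG is regressed on the other columns and its missing entries
replaced by the regression prediction, for a fixed 10 rounds
(`max_iter = 10`, seed 0, no early-stopping tolerance), columns visited
in descending missing count.  Imputed values are clipped to [0,1];
observed cells are never modified, and identical inputs give
bit-identical outputs.  By default the imputer operates on the union of
registered clock CpGs (`clock_union` scope) rather than every measured
column: array-wide round-robin regression is quadratic in columns and
prediction only consumes clock CpGs; `all_columns` remains available.
A CpG with no observed value in the upload cannot be regressed; it is
filled from a caller-supplied prior mean when one exists, and otherwise
raises an error naming the CpG (in the workflow, the affected clock is
reported missing with a warning instead of aborting the run).

## Metrics

Accuracy: MeAE = median|predicted − chronological| and MAE = mean of the
same, in years (even-length median = mean of the two central values).
Robustness: the slope of the ordinary-least-squares fit of predicted (y)
on chronological (x) age — 1 is ideal; range compression appears as
slope < 1 even when MeAE looks fine.  Slope is undefined (NaN) when
chronological age has zero variance.  Epigenetic age acceleration is the
plain difference EAA = predicted − chronological; intrinsic/extrinsic
variants (residual-on-age regression, cell-type adjustment) are out of
scope.  Group contrasts compare mean EAA between exactly two groups via
Welch's t-test (default; no equal-variance assumption) or Mann-Whitney U;
groups under 5 samples are flagged low-power.  Per-CpG aging signal is
the Pearson correlation between a CpG's betas and chronological age,
computed over complete, non-constant columns.

## Synthetic cohorts

The generator produces the minimal structure under which clocks and the
meta-learner are identifiable:

    β_ij = clip( b0_j + s_j · (age_eff_i − 50)/100 + ε_ij , 0, 1 )

with ε ~ N(0, noise_sd²); `s_j` is nonzero for `n_age_cpgs` CpGs (half
positive, half negative, |s| ~ U(0.3, 0.8) beta units per century;
age-CpG baselines drawn in [0.35, 0.65] so the signal rarely clips in
20–80 y), and zero for the remaining noise probes (baselines in
[0.1, 0.9]).  `age_eff` is chronological age plus the sample's group
acceleration, so injected EAA is recoverable by construction.  Ages are
uniform on [20, 80] or a mid-heavy mixture (60% in 40–60, 20% in each
flanking band).  Missingness is MCAR.  Defaults — noise_sd 0.02 beta
units (typical array technical noise), 5–10% missingness in masking
experiments, +10 y injected acceleration at n = 50/group — mirror the
regimes the method is meant to operate in.  Because the generative model
is known, `generate_oracle_clock` returns the exact inverting linear
clock (weights 100/(m·s_j), matching intercept), and perturbed-weight
*distractor* clocks provide realistic weak base models.  The generator
does **not** emulate real array covariance between CpGs, batch effects,
probe chemistry, or cell-type mixtures; passing tests establish the
correctness of the machinery on data satisfying the model's assumptions,
not clock accuracy on real tissue.

## Numerical and design choices

* Problem sizes in tests and the acceptance script (cohorts of 150–1000
  samples, 20–40 CpGs, 200 random clock sets) are the smallest at which
  each property is statistically unambiguous.
* Clock files round-trip bit-exactly (weights serialized with full
  `repr` precision); prediction CSVs round-trip at 6 decimal places.
* CpG ids match case-sensitively with no probe-suffix stripping.
* Ridge training with collinear base predictions is well-posed by
  construction (the L2 penalty); no rank check is performed.
* The SMOTE neighbour search uses exact pairwise distances within each
  bin (bins are small after stratification); ties in distance are
  resolved by `argsort`'s stable order, and the column visit order of
  the imputer (descending missing count, then id sort) makes every
  stochastic step a pure function of its seed.
* The published coefficient lists for the eight base clocks are not
  redistributed; the registry ships a manifest with each clock's source,
  expected CpG count and transform, verifies counts on load, and reads
  the files from a local cache the user populates.  Analyses that need
  the real lists (cross-clock overlap counts, CpG-count verification)
  therefore run only once those files are present.

## Known limitations

* The uniform evaluation contract ignores clock-specific preprocessing
  some original publications prescribe.
* Held-out evaluation after SMOTE mixes synthetic samples into the test
  fold; treat those numbers as pipeline diagnostics.
* The difference-based EAA is unadjusted for covariates (age itself,
  sex, cell composition).
* The imputer is fit per upload only; small uploads with heavy
  missingness have little signal to regress on.
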