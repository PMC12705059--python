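# Methods

## Model

`comorbmtl` estimates two symptom-severity outcomes (tasks) jointly
from one feature space with a weighted least-squares loss and an L2,1
penalty on the coefficient matrix `W` (p features × t tasks):

```
min_W  Σᵢ (1/nᵢ) Σⱼ Rᵢⱼ (xᵢⱼ·Wᵢ − yᵢⱼ)²  +  λ ‖W‖₂,₁
```

The penalty sums the Euclidean norms of W's *rows*, so a whole feature
row is shrunk — and at sufficient λ zeroed — at once.  Coupling between
tasks therefore acts through which features are selected, not through
the per-task weight values.  Features and outcomes are standardized
within each training fold; no intercept is fit (centering absorbs it).

### Density-based weighting

Symptom scores in community samples are strongly right-skewed; an
unweighted squared loss is dominated by the prevalent low scores.
Each training subject j receives weight

```
R_j = C_jˣ · n / Σⱼ C_jˣ ,    C_j = 1 − f_j
```

with `f_j` the relative frequency of subject j's exact outcome value in
the training set (values matched after rounding to 10 decimals;
standardization is a monotone bijection on the ordinal scores so
frequencies are unchanged by it).  The weights always sum to n, so the
data term stays a weighted *mean* squared error and λ remains
comparable across folds of different size.  `x` defaults to 1; 0
disables weighting, 2 and 3 serve sensitivity analyses.  If every
subject shares one outcome value the weights are undefined and the
implementation falls back to unit weights, flagging the fallback.
Weights are recomputed per task and per training fold, never on test
or hold-out data; all evaluation metrics (MSE, MAE) are unweighted.

### Solver

The objective is convex but non-smooth.  It is minimized by an
accelerated proximal-gradient method (FISTA) with a backtracking line
search and the monotone safeguard (the accepted iterate never increases
the objective), initialized at W = 0.  The proximal map of the penalty
is row-wise group soft-thresholding.  Because the loss is quadratic,
per-task Gram matrices are precomputed once per (data, weights) pair;
an iteration then costs O(p²t) regardless of sample size, the step is
seeded at 1/L with L the largest Gram eigenvalue (so backtracking
rarely triggers), and a whole λ path is fitted with warm starts from
the sparse end.  Convergence requires *both* the relative objective
change and the relative iterate change to fall below `rel_tolerance`
(default 1e-8) — the objective alone flattens well before the
coefficients settle.  `lambda_max`, the smallest penalty whose optimum
is exactly W = 0, follows from stationarity at the origin (the largest
row norm of the loss gradient there); fits at or above it return an
exactly zero matrix.  Feature selection reads rows with Euclidean norm
above `selection_tolerance` (1e-10).

## Model selection

**LOCOCV.**  Each fold holds out all subjects of one acquisition
center.  Standardizers (features and outcomes), optional PCA, and
density weights are re-estimated on the training centers of each fold.
The λ grid is {0.01, 0.02, …, 0.99}, the same granularity as the
robustness path.  The selected λ minimizes the mean unweighted test
MSE — mean over folds first, then over tasks (outcomes are
standardized, so task scales are commensurate) — among *admissible*
penalties, i.e. those whose refit on the full development set selects
at least one feature; this matches the model actually carried to
hold-out.  Ties go to the larger λ (the sparser model).  Candidate
models (e.g., different contrasts or feature sets) are ranked by their
selected-λ mean MSE, ties broken by label.

**Penalty-path robustness.**  From the selected λ the penalty is raised
in steps of 0.01 to 0.99, refitting on the full development set, and
each feature's selections and per-task weight signs are recorded.  A
feature is a *comorbidity marker* when it is selected at least once and
carries the same nonzero sign for both tasks at every penalty where it
is selected; *discriminator* when the signs always oppose; *unstable*
on any mixed or exactly-zero sign record.  Requiring sign consistency
at every selected penalty is the conservative, deterministic reading.
For display, features are kept when selected at least 10% as often as
the most robust feature and carrying at least one weight ≥ 10% of the
largest |weight|.

**Robust support.**  A single prediction-optimal penalty routinely
admits weakly correlated null features next to the true ones (the usual
over-selection of cross-validated group-sparse fits).  The pipeline's
support estimate is therefore the *robust support*: features selected
in at least half of the penalty-path fits, relative to the most robust
feature.  On planted-signal simulations this majority rule recovers the
true support essentially exactly where the raw selected set at the
cross-validated λ carries many false positives.

## Inference

**Hold-out permutation test.**  The development-refit model predicts
each hold-out center's subjects (transforms frozen from development).
Within each center and task, the observed MAE is compared with B
permutations of the outcome vector (predictions fixed):
p = (1 + #{null ≤ observed}) / (1 + B), one-sided, strictly positive by
construction and deterministic given the seed.  B defaults to 10,000;
significance is declared at p < 0.05, per center and task, without
multiplicity correction across centers or tasks (a deliberate mirror of
the per-center reporting convention; noted as a limitation).  MAE is
the hold-out statistic; MSE is used only to select λ.

**Paired Wilcoxon.**  Competing models are compared on per-subject
absolute errors from matched cross-validation folds.  Zero differences
are dropped, absolute differences are mid-ranked, and V is the sum of
positive-difference ranks.  For ≤ 25 informative pairs the null is
exact — mid-ranks are doubled to integers and the distribution of 2V is
built by convolution, valid under ties — otherwise the normal
approximation with continuity and tie correction is used (two-sided).

## Stacked ensemble

First-level models (e.g., one psychosocial and several neural) are fit
on the development centers and frozen.  For task i, the second-level
design's column m is model m's estimate of task i — one weight per
signature per outcome.  The second level is trained on the hold-out
sample with LOCOCV inside it, using the same weighted L2,1 machinery;
pooled test-fold MAEs and their permutation significance are reported.
Because the hold-out sample doubles as the ensemble's training
universe, ensemble numbers are cross-validated, not tested on fresh
centers — a design limitation carried over deliberately.  The value of
extra signatures is tested by the paired Wilcoxon on per-subject errors
of the full vs reduced design, each at its own selected λ
(ΔMAE = MAE_full − MAE_reduced).

## Synthetic data generator

The generator emulates the structure the analysis assumes, at desk
scale (defaults: n = 689 subjects, 8 near-equal centers, p = 100
features):

- features: AR(1)-correlated Gaussians (ρ = 0.2) with per-center mean
  shifts (sd 0.2) and scale factors (uniform 0.9–1.1);
- true coefficients: 5 shared rows (same sign for both tasks) and 2
  discriminating rows (opposite signs), magnitude `effect_size`
  (default 0.25 — a modest distributed signal; recovery experiments
  use 0.5, a strong one), remaining rows zero;
- latent outcomes: u = X·w* + γ·g + ε, with g a standard-normal
  subject factor shared by both tasks and ε task-specific noise
  (sd 1);
- ordinal outcomes: monotone binning of u with geometrically widening
  bins (ratio 1.5, first edge at 0.25 latent SD), producing
  right-skewed integer scores on pain-like (0–4), depression-like
  (0–18) or anxiety-like (0–48) scales.  Binning on the latent scale
  keeps the model linear underneath, so support-recovery results are
  interpretable.

The shared-factor loading γ was calibrated once by the module's own
bisection routine (`calibrate_shared_factor`, 60 datasets per
candidate, tolerance 0.003) so that generated outcome pairs reproduce
the weak cross-outcome Spearman correlations of the target population:
γ = 0.75 for pain–depression (ρ ≈ 0.28) and γ = 0.914 for pain–anxiety
(ρ ≈ 0.34); both verified on independent seed batches.

What the generator does *not* emulate: spatial autocorrelation of
voxelwise maps, non-Gaussian feature marginals, site-by-effect
interactions, missing-data mechanisms, and item-level questionnaire
structure.  Passing recovery and calibration tests therefore validates
the estimator and workflow logic, not the neurobiological claims one
could draw from real cohort data.

## Numerical and design choices

- Standardization uses the sample SD (ddof = 1); zero-variance columns
  must be removed upstream (`read_dataset` does this, logging names).
- PCA retains k = min(n_train − 1, p) components by default; component
  signs follow the largest-|loading|-positive convention (signature
  signs depend on it, so it is fixed and documented).  Back-projection
  of model weights through the loadings defaults to standardized-signal
  units; a raw-space variant divides by training SDs for NIfTI export.
  With exactly one selected component the per-task signatures are
  exactly proportional (|r| = 1) — a property of the method, tested as
  such.
- Hold-out outcomes are wrapped in a gated container that raises on
  access until the permutation stage reveals them with a stated
  purpose; the no-leakage contract is structural, not conventional.
- Outcome standardization parameters for hold-out transformation come
  from the development set, preserving the leakage rule stated for
  features.
- All randomness (splits, permutations, simulations) flows from
  explicit seeds; LOCOCV itself is deterministic and bit-for-bit
  reproducible.

## Problem sizes used in the validation suite

Simulation-backed checks run at desk scale, chosen as the package's own
validation conditions: generator calibration at n = 689 over 20 seeds;
permutation-test type-I error over 400 null replicates (n = 200,
p = 20, B = 999); solver-vs-oracle equivalence on 100 random instances
(n ≤ 30, p ≤ 5, t = 2); support recovery over 50 seeds at n = 800,
p = 100 with effect size 0.5.

## Known limitations

- The permutation null permutes outcomes within a hold-out center with
  predictions fixed; exchangeability within center is assumed.
- No site-effect correction beyond center-wise cross-validation.
- The exact Wilcoxon branch is quadratic in the doubled rank total;
  fine for the n ≤ 25 regime it serves.
- LOCOCV admissibility is checked on the full-development refit, not
  per fold; with very small centers a per-fold check could differ.
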