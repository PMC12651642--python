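# Methods

`thalrisk` implements a hybrid multi-criteria decision-making (MCDM) and
machine-learning workflow for thalassemia risk assessment from tabular
survey data: expert-weighted criteria (AHP), per-patient ideal-point
scoring (TOPSIS), Pareto-style risk stratification, a leakage-safe
cross-validated classifier benchmark, and statistical validation of model
explanations.  This note records the model, its assumptions, the defaults
that matter, and the design choices made where the design was genuinely
open.

## Cohort schema and encoding

The survey schema has 16 features: demographics (Age in years, BMI, Parity
in births), hereditary flags (family history of thalassemia, genetic
marker presence, known carrier status), socioeconomic context
(socioeconomic status, education level, urban/rural residence) and the
complete-blood-count indices (Hb g/dL, Hct %, MCV fL, MCH pg, MCHC g/dL,
RDW %, RBC count in million cells/µL).  `Patient_ID` and `Diagnosis`
columns are metadata (record ids and optional labels), never model
features.

Encoding preserves order where order exists: binary answers map to 0/1 in
level order, ordinal levels (socioeconomic status Low/Middle/High,
education in five steps) map to consecutive integer codes, and the only
nominal feature (residence) is one-hot encoded.  The code map is recorded
so categorical values decode exactly.  Readers accept common alternative
spellings for binary answers (0/1 flags, `Non-Car.` abbreviations) because
printed records use them interchangeably.

No imputation is implemented.  The framework assumes complete data; any
missing cell (empty or `NA`) above a configurable tolerance (default 0)
is an error, and `missingness()` reports per-feature counts for auditing.

## AHP weighting

Expert judgments are stored as the integer upper triangle of a reciprocal
pairwise-comparison matrix on the Saaty 1–9 scale; reciprocals are derived
exactly rather than read from 3-decimal roundings, because the published
normalized matrix is only reproducible with exact reciprocal arithmetic.
When a full printed matrix is supplied, the entry ≥ 1 of each pair is
taken as authoritative and its reciprocal recomputed (`from_matrix`).

Weights use the column-normalization / row-averaging method: a′_ij =
a_ij / Σ_i a_ij, then w_i = mean_j a′_ij.  Consistency uses the
weighted-sum estimate λ_max = mean_i (A w)_i / w_i, CI = (λ_max − n)/(n −
1), CR = CI/RI with the standard random-index table (RI(10) = 1.49).  The
principal eigenvalue is also computed, but only as a diagnostic
cross-check — the two agree to roughly two decimals on realistic
matrices, and the ratio-average form is the primary statistic.  CR < 0.1
is an acceptability gate: the pipeline refuses inconsistent judgments
unless explicitly overridden.  For n ≤ 2, CR is defined as 0.

The packaged 10-criterion expert matrix yields Hct 0.2989 down to MCV
0.0428 with CR = 0.0915.

## TOPSIS scoring and stratification

Criteria are min–max scaled on the cohort being scored, multiplied by the
AHP weights, and compared by Euclidean distance against the positive
ideal (columnwise maximum of the weighted matrix) and negative ideal
(columnwise minimum).  Relative closeness C = D⁻/(D⁺ + D⁻) ∈ [0, 1];
higher closeness means higher assessed risk.  Since the full-cohort
min–max attains 0 and 1 in every column, the ideals reduce to (w_j, 0).

All criteria are treated as benefit-direction, following the published
formulation; a per-criterion `directions` flag can reflect chosen criteria
(1 − x) for cost-direction semantics, since clinically *low* MCV or Hb
indicates risk.  The flag is off by default to remain faithful to the
printed equations.

Stratification thresholds: closeness ≥ 0.66 → High Risk, < 0.33 → Low
Risk, else Medium Risk.  The 0.66 boundary belongs to High and 0.33 to
Medium.  Ranking is by descending closeness with stable ordinal ties, so
output files are reproducible.

A known caveat: the published worked example's closeness values cannot be
recovered by direct evaluation of the printed normalized excerpt and
weights (direct evaluation of its first record gives ≈ 0.66, not the
printed 0.7064), indicating an unprinted processing variant upstream.
The implementation follows the printed equations; the published closeness
excerpt is used to verify category assignment, not numeric equality.

## Synthetic cohorts

The generator emulates the two-population structure the framework
assumes: a carrier fraction (default prevalence 0.20, reflecting an
enriched antenatal screening context and the carrier share of the packaged
example records) whose hematology shows the classic trait phenotype —
MCV 66 vs 82 fL, MCH 21 vs 27 pg, RDW 16 vs 13.5 %, RBC 5.4 vs 4.6 M/µL,
Hb 10.2 vs 11.3 g/dL — with shared demographics, and hereditary flags
enriched in carriers via odds multipliers (family history ×4, genetic
marker ×30).

Continuous features are bounded normals: a per-patient latent
erythropoietic factor carries the strong positive correlation real CBC
panels show (Hct, Hb and RBC are arithmetically linked; loadings 0.85,
0.80, 0.50; MCV 0.60, MCH 0.70, MCHC 0.45; RDW loads negatively at
−0.35), each feature adds independent noise, and draws are clipped to
wide clinical bounds that cover every value in the packaged example
records.  The latent factor matters downstream: with independent draws
the joint upper tail of the weighted criteria is vanishingly thin and the
closeness distribution collapses into the Medium stratum, whereas the
physiologic correlation spreads patients across all three strata the way
a real mixed cohort does.

Randomness: one root seed; each feature draws from a substream keyed on
its name (CRC-32), so adding a feature never perturbs the others, and the
same seed reproduces a cohort bit-for-bit.

What the generator does *not* emulate: measurement error structure,
copula-calibrated correlations fitted to a real cohort, longitudinal
visits, or site effects.  Passing tests therefore demonstrate the
pipeline's correctness and its behavior under a plausible carrier-mixture
model — not clinical performance on real survey data.

## Feature relevance and the Combined Importance Index

Two relevance views: mean impurity-decrease from a random forest
(renormalized to sum to 1; 200 trees by default, 100 inside CV folds for
speed) and a univariate separability score.  The univariate default
(`raw_ratio`) is the raw ratio F_j = S_B/S_W of between-class to
within-class sums of squares, with no degrees-of-freedom scaling; the
`df_adjusted` variant multiplies by (n − k)/(k − 1) to recover the
classical one-way ANOVA statistic.  The two differ by a positive constant
at fixed n and k, so rankings coincide — the literal form is kept as the
default for fidelity, the adjusted one for comparability.  A
`mutual_information` variant delegates to a k-NN estimator.  Zero
within-class variance with class separation yields +inf, which saturates
the normalized scale at 1 rather than raising.

Each score table is min–max rescaled to [0, 1] (constant tables map to
0); the Combined Importance Index is the arithmetic mean of ≥ 2 rescaled
tables, ranks descending with ties broken by input order.  The fusion
accepts any score tables — including an attribution-derived table — so
both a model ⊕ univariate and an attribution ⊕ univariate reading are
supported; the default pairs impurity importance with the univariate
score.  Top-k selection (default k = 10 of the 16 features) feeds the
classifier stage.

## Benchmark protocol

Risk labels are TOPSIS strata — a deterministic function of the input
features.  The benchmark therefore measures how well classifiers recover
a known functional, and near-ceiling held-out accuracy is the expected
outcome, not evidence of clinical validity; the harness exists to compare
models and conditions under identical folds.

Protocol per fold of a stratified k-fold plan (default k = 20):

1. min–max extremes, TOPSIS ideals, and training strata labels are fit on
   the training part only;
2. held-out samples are scaled with the frozen extremes (unclipped, so
   out-of-range values stay visible) and scored against the frozen
   ideals with the same thresholds;
3. feature scoring and top-k selection run on training data only;
4. classifiers train on the selected, training-extreme-scaled features —
   multiplied by the AHP weights under the `with_mcdm` condition
   (non-criterion features keep weight 1) — and are evaluated on the
   held-out fold.

Fold assignment is stratified on provisional whole-cohort strata so the
folds are balanced; the evaluated labels are always re-derived per fold
from training statistics.  Toggling the condition changes only the
feature weighting, keeping the comparison paired.  A training fold that
degenerates to one stratum is recorded as failed with a diagnostic and
the run continues.  `verify_no_leakage()` re-derives every fold's frozen
statistics from the recorded training indices and fails loudly on any
mismatch.

Backends: `random_forest` (scikit-learn), `extreme_gradient_boosting`
(XGBoost) and `ordered_boosting` (LightGBM's gradient boosting; chosen as
the package's third boosting backend).  Metrics follow the standard
confusion-matrix formulas: per-class one-vs-rest precision/recall/F1/MCC,
macro averaging by default (micro available) because macro is robust to
the imbalanced strata; the overall multiclass MCC uses the generalized
contingency-table form, which reduces to the binary formula for two
classes.  Zero-denominator conventions: the affected metric is 0 and
flagged.  Grid search maximizes inner-CV mean accuracy with ties resolved
to the first grid point.

## Explanations and their statistical validation

Global attributions delegate to the boosting backends' native tree-path
Shapley decompositions (XGBoost `pred_contribs`, LightGBM
`pred_contrib`), so additivity — base value plus contributions equals the
prediction margin — holds by construction; for multiclass models one
class margin is decomposed at a time.  Local explanations use a
perturbation surrogate authored in-package: Bernoulli(½) feature masks
around the instance (masked features replaced by the background mean), an
exponential kernel exp(−d²/σ²) on mask distance (default σ = 0.75·√m),
and a kernel-weighted ridge regression of the predicted class probability
on the masks; coefficients are the signed local weights.

Validation: per-feature Kruskal–Wallis H across risk classes, and a
symmetric features × features matrix of two-sided Mann–Whitney U
p-values over per-sample attribution distributions.  Signed attributions
are compared by default (absolute values via flag), pooled across classes
by default (per-class by filtering the cohort by stratum first).  Method
rule: exact null enumeration when both groups have ≤ 8 tie-free
observations, normal approximation with tie correction otherwise; an
all-constant pair returns p = 1 with a tie flag.  Raw p-values are
reported by default; optional Benjamini–Hochberg adjustment is applied to
the upper triangle and the correction tag is always recorded.  The
heatmap export maps p monotonically to grayscale (darker = lower p) and
writes the matrix alongside as CSV.

## Numerical choices and degenerate inputs

- Reciprocity, column-stochasticity and weight normalization are enforced
  to 1e-9; λ_max ≥ n holds for reciprocal matrices to the same slack.
- Zero-range criteria are an error when fitting extremes (they carry no
  ordering information); frozen-extreme scaling is left unclipped.
- A cohort whose samples all coincide makes closeness 0/0 and is rejected.
- Ranking and rank-1-based importance ties are stable in input order.
- Classifier inputs are scaled per fold; constant training columns scale
  with span 1 to avoid division by zero.

## Problem sizes used in the shipped checks

The test suite and the worked examples run on the packaged 10-record
example cohort, synthetic cohorts of 200–1000 records, and a 10,000-record
cohort for moment/prevalence convergence checks; the circularity
benchmark uses n = 1000 under 20-fold CV with a 60-tree in-fold forest
for feature scoring.  These sizes were chosen so the full suite exercises
every stage, including the heavier statistical checks, in a few minutes
on a single CPU.

## Known limitations

- Risk labels are circular by construction (strata derive from the same
  features the classifiers see); reported accuracies characterize the
  pipeline, not diagnostic performance.
- The benefit-direction TOPSIS formulation scores *high* hematologic
  values as high-risk; the cost-direction flag exists but is off by
  default for fidelity to the published equations.
- Group judgment aggregation (multiple experts), eigenvector-method
  weights as the primary path, incomplete judgment matrices, alternative
  MCDM rankers, and imputation are out of scope.
- The synthetic generator's defaults are engineering choices describing a
  plausible screening population, not estimates of any real cohort.
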