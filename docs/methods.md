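# Methods

This note documents the statistical models behind `uromet`, the
defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical details that affect results.

## Study design being modeled

The package targets two-group untargeted GC-MS urine metabolomics: a
cohort of cases (label y = 1, e.g. interstitial cystitis patients) and
controls (y = 0), measured on a few hundred features of which a
minority are library-annotated metabolites and the rest are
unidentified signals.  Intensities are positive, roughly log-normal,
and analyzed on the log2 scale; fold changes are reported on the linear
scale.  Default cohort geometry everywhere is 42 cases / 21 controls
and 200 annotated + 290 unknown features.

## Synthetic data generator

Log2 intensities are drawn group-wise from multivariate normals
z | y=0 ~ N(0, Ω₀⁻¹) and z | y=1 ~ N(δ, Ω₁⁻¹), where δ is the vector
of planted log2 fold changes and (Ω₀, Ω₁) is a pair of sparse
precision matrices.  Output is linear scale,
`base_intensity · 2^z` (default base 1000), so the pipeline's log2 step
is exercised and all values are strictly positive.

Edges are planted as off-diagonal precision entries of magnitude
`edge_strength` (default 0.3; the recovery benchmarks use 0.4) with
random sign: `n_common_edges` pairs shared by both matrices and
`n_diff_edges` additional pairs present only in the case matrix.
Edges are planted among the annotated features because the network
stage models annotated metabolites only.  Positive definiteness is
enforced by diagonal loading: each diagonal entry is raised to the
larger of the two matrices' absolute off-diagonal row sums plus a
margin of 0.1 whenever it falls short, and the *same* loaded diagonal
is written into both matrices.  The shared diagonal matters: loading
each matrix separately changes the case diagonal wherever a
differential edge attaches, which perturbs the case-group conditional
slopes at *common*-edge pairs as well — a real, but unplanted,
differential signal that would make the ground truth ambiguous.  With a
shared diagonal the group-wise conditionals differ exactly at the
planted differential pairs.  A consequence worth knowing: the effective
partial correlation of a planted edge is `edge_strength / loaded
diagonal`, i.e. at most `edge_strength`.

The generator emulates cohort geometry, effect sizes and correlation
structure.  It does **not** emulate: missing values, batch or drift
effects, heteroscedastic technical noise (an optional log-normal noise
SD exists, default off), chromatographic artifacts, or non-Gaussian
marginal shapes beyond log-normality.  Passing recovery tests on this
generator therefore demonstrates correctness of the estimators under
the generative model, not robustness to real-data pathologies.

The 30-row published screening table (names, linear fold changes,
t-test p-values, BH-adjusted values, 12 annotated rows) is packaged
verbatim as a fixture for reconstruction tests.

## Preprocessing

Pipeline order: per-sample normalization (linear scale) → log2 →
PCA outlier screen → univariate statistics (t-test on log2, fold
change on linear) → autoscaling only ahead of multivariate steps.
All operations are pure; containers are immutable and arrays read-only.

* **Normalization** defaults to pass-through ("ones"), since the
  reference workflow adjusted urine volumes to creatinine at the bench,
  not in software.  A `"total"` policy (scale each sample's sum to the
  cohort median sum) and explicit per-sample factors are available.
* **Autoscaling** centers each feature and divides by the n−1 sample
  SD.  Zero-variance features are dropped with a warning rather than
  raising — the robust choice for degenerate synthetic inputs.
* **PCA outlier screen**: scores on autoscaled data, squared score
  distance Σ_k t²_k/λ̂_k over the retained components (default 2),
  flagged above the χ²(k) quantile at 1 − α (default α = 0.025),
  single pass.  This is a standard Hotelling-type rule chosen because
  the reference workflow names no rule; both k and α are configurable.
  Whether the original exclusion used autoscaled or merely centered
  data is unknown; autoscaled is assumed.

## Univariate screen

Fold change is the ratio of arithmetic group means on the normalized
linear scale (the MetaboAnalyst-style convention), computed separately
from the log2-scale pooled-variance Student t-test (the workflow names
Student's test specifically, not Welch).  Volcano selection uses
strict inequalities: FC > 1.20 or FC < 0.83, and p < 0.1.

BH adjustment takes an explicit total-test count `m_total ≥ #p`:
supplied p-values are treated as the smallest among `m_total` tests and
the absent tests are imputed at p = 1 in the highest ranks, where their
step-up ratios are ≥ 1 and can never bind.  This is what makes the
printed FDR column of the fixture reconstructible from only its 30
printed p-values with m_total = 490 — except the final tie block (rows
25–30), whose printed value is controlled by an unprinted p-value at
rank > 30 and is therefore not reconstructible in principle.

## PLS-DA

NIPALS PLS1 against the centered 0/1 label (equivalent to ±1 coding up
to scale for two classes): per component the weight vector is
w ∝ X_dᵀ y_d, scores t = X_d w, followed by deflation of X (and y) by
the score projections.  Default 3 components.  Prediction maps new data
through the rotation W(PᵀW)⁻¹ and labels a sample 1 iff the predicted
centered label exceeds 0.  Leave-one-out CV refits both the autoscaling
and the model inside each fold (no leakage); every class must have ≥ 2
members so no fold empties a class.

Model significance uses the separation distance — between-group over
within-group sum of squares of the score matrix, summed over
components, +∞ when within-group scatter is exactly zero — under B
label permutations (default B = 2000) with the valid estimator
p = (1 + #{permuted ≥ observed})/(B + 1).  The B/W form is the
standard definition of this statistic; the original software reports it
without a formula.  Degenerate permutation refits (zero label
covariance) count as +∞, i.e. as extreme, which keeps the test
conservative.

## Sparse local graphical model

For each metabolite i the design is [X₋ᵢ | y | y·X₋ᵢ] with the target
and all columns centered; X is autoscaled beforehand and the
interaction columns are standardized *after* forming the product
(zero-variance interaction columns are kept as dead zeros).  The α
block and β block carry L1 penalties λ_α, λ_β; the intercept and the y
main effect are unpenalized so that pure mean shifts are absorbed by
β_i0 rather than leaking into β edges.  The solver is a covariance
(Gram) update coordinate descent with glmnet-style 1/(2n) scaling,
convergence tolerance 1e-7 on the maximum coefficient change, warm
starts along the path; coefficients with |θ| > 1e-8 count as nonzero.

Penalty selection sweeps one shared scalar λ for both blocks over 50
log-spaced values from λ_max (the smallest penalty with an all-zero
penalized block, computed after partialling out the unpenalized
columns) down to 0.01·λ_max.  The default criterion is the extended
BIC, n·log(RSS/n) + k·log n + 2γ·k·log d with γ = 0.5 and d the number
of candidate columns, evaluated on an **unpenalized OLS refit** of each
distinct active set along the path.  Two reasons, both visible in
recovery simulations: (i) with ~40 candidate columns the classical BIC
threshold sits at the noise maximum, admitting spurious coefficients;
the extended term is the standard correction for sparse neighborhood
selection; (ii) scoring the *shrunk* lasso fit lets columns correlated
with a true predictor absorb its shrinkage residual at small λ
("shrinkage bleed"), which inflated false differential edges —
shrinkage-free refit RSS removes that incentive.  γ = 0 recovers the
classical BIC penalty; 5-fold CV with a fixed shuffle seed and the
one-standard-error rule is available as an alternative.

Networks are assembled with the neighborhood-selection "or" rule:
edge (i, j) is present iff the coefficient is nonzero in either node's
regression, weighted by the mean of the nonzero estimates ("and" is
available).  Edge weights are on the standardized-design coefficient
scale and should be read as relative, not as partial correlations.
Networks are built over annotated metabolites by default.  Modules are
connected components (or radius-1 neighborhoods) of the differential
network around a seed metabolite, with node up-regulation flags joined
from the volcano screen.

At the planted benchmark conditions (p = 20 annotated features,
500 + 500 samples, strength 0.4, 10 common + 5 differential edges) the
pipeline's measured recovery — recomputed by `scripts/acceptance.py`
and asserted in the test suite — reaches median differential-edge
recall and precision ≥ 0.8 over 20 seeds, with no differential edges
invented when none are planted.

## Enrichment

Over-representation uses the hypergeometric upper tail P(X ≥ k) (the
standard ORA convention) for the overlap k between the query and each
library set intersected with the measured universe; BH adjustment runs
across the sets with nonzero universe intersection.  The universe is
the measured annotated metabolites, not all library members —
configurable.  No pathway library is shipped; libraries are
version-dependent external inputs in GMT format.

## Pipeline, outputs, determinism

The `run` pipeline composes the stages above in order and writes only
plain-text artifacts: TSV tables, SIF/GraphML networks, and a
z-scored selected-feature matrix with row/column orders from
average-linkage Euclidean hierarchical clustering (the heatmap is
exported as data, not an image, for bit-exact testability).  One seed
drives every stochastic step; two runs with the same config and seed
produce byte-identical numeric artifacts (the run log carries
wall-clock timestamps and is the one exception).

## Problem sizes used by the test suite

Simulation-backed tests run at sizes chosen to make their statistical
claims sharp while keeping the suite quick: null-uniformity and
type-I checks pool 20 seeds; permutation calibration uses 200
replicates at B = 199; edge-recovery benchmarks use the 500 + 500 / 20-
feature conditions above; LOO null calibration uses 40 balanced
samples, because leave-one-out's well-known pessimistic bias (each
held-out sample drags its class mean away from itself) pushes null
accuracy visibly below chance at very small n — this is a property of
LOO, not a defect of the fit.

## Known limitations

* Student's pooled t-test is assumed adequate; no Welch fallback,
  nonparametric alternative, or covariate adjustment.
* The graphical model's differential edges are one-directional by
  construction in the generator (present in cases, absent in controls);
  the estimator itself is symmetric in the sign of change.
* Edge weights are not partial correlations; only supports are
  benchmarked.
* The permutation test refits the PLS model but not the preceding
  feature selection; when the feature subset was chosen using the
  labels (the volcano default), the permutation p-value is conditional
  on that subset and should be read accordingly.
* The enrichment stage reproduces machinery, not any specific published
  FDR values, which depend on the pathway-library version.
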