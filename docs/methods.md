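# Methods

## Model and procedure

The pipeline treats each acoustic feature marginally. For a feature with
per-class samples x₁…x_N, the class-conditional density is the Gaussian
Parzen-window estimate

    f̂(x) = (1 / (N h)) Σᵢ φ((x − xᵢ)/h),

with the normal-reference bandwidth h = 1.06 · SD · N^(−1/5). The SD uses
the unbiased (N−1) estimator; the rule is the classical optimum for
near-Gaussian data and deliberately oversmooths multimodal densities
slightly, which biases overlap estimates upward by roughly +0.01 to +0.02
at N ≈ 1000 (measured against the closed form for Gaussian pairs).

Both class densities are evaluated on one shared uniform grid of 512
points spanning the pooled data range extended by four times the larger
bandwidth on each side; at that margin the truncated tail mass is below
10⁻⁴, so trapezoidal integrals of a single density land in [0.99, 1.01].
Densities are never renormalised — the integral-≈-1 property is asserted
as a correctness check; silently rescaling would hide grid bugs.

Two statistics compare the curves on that grid, both by the trapezoid
rule (refinement-stable to 10⁻³ at 512 points):

* ICPR = ∫ min(f̂₊, f̂₋) dx, the class-overlap mass. Bounded in [0, 1],
  symmetric, invariant under common affine rescaling of the feature
  (the bandwidth scales with the SD, so the whole construction is
  scale-equivariant), and equally meaningful for unimodal and multimodal
  densities. The random-guess anchor — overlap equal to the summed
  non-overlap mass — sits at exactly 2/3.
* MKLD = ∫ f̂₊ ln(f̂₊/f̂₋) + ∫ f̂₋ ln(f̂₋/f̂₊), the symmetrised
  Kullback–Leibler divergence. The directed integrals are undefined where
  a density vanishes, so inside the logarithms each density is floored at
  10⁻¹² times the pair's maximum density; each integrand term f·ln(f/g)
  is taken as 0 where f itself is 0. The floor's magnitude is arbitrary
  below ~10⁻⁶; third-decimal MKLD values can shift under a different
  floor choice, which is why selection uses the coarse threshold 1.

Selection keeps features with ICPR strictly below 0.6 or MKLD strictly
above 1.0 (strict inequalities; a feature exactly at a threshold is not
selected). Report rows are ordered by ascending ICPR. A zero-spread
feature cannot be scored (the bandwidth rule fails) and is recorded as
unselectable with a diagnostic rather than raising.

## Correlated-feature collapsing

Pearson correlations are computed over all rows (both classes pooled).
Features are grouped either by connected components of the graph with
edges |r| > 0.8 — absolute value, so strong negative correlation also
links features, a behaviour-neutral generalisation on data whose strong
correlations are all positive — or by the fixed canonical grouping of the
22-feature panel: the six jitter-type features with NHR, the six
shimmer-type features, and DFA with PPE.

Each group is collapsed by the two-class Fisher direction
w ∝ S_W⁻¹(μ₊ − μ₋), where S_W is the pooled within-class scatter. A
ridge of 10⁻⁸ · trace(S_W)/p is added: the shimmer block contains an
exactly collinear pair (Shimmer:APQ3 and Shimmer:DDA, r = 1), so raw S_W
is singular. Coefficients are normalised to unit Euclidean length and
sign-fixed so the projected patient mean exceeds the control mean; the
ridge makes the direction scale-invariant only up to ~10⁻⁵, which is
inconsequential because all downstream statistics are themselves
scale-invariant.

For the real UCI panel the package ships fixed reference coefficient
vectors for the three combined features (`REFERENCE_LDA_COEFFICIENTS`).
A Fisher direction is defined only up to a positive scalar, and any such
scalar leaves ICPR/MKLD unchanged; the fixed vectors pin down the exact
combined columns so that selection-table values are bit-reproducible.
`append_group_projections(mode="fit")` fits fresh directions instead.

## Classifiers

* **GLRA** — logistic regression fitted by IRLS (Newton with step
  halving, so the log-likelihood is monotone non-decreasing), stopping at
  a relative log-likelihood change below 10⁻⁸ or 100 iterations.
  Features enter unstandardised by default (standardisation is an
  option). Complete separation — all fitted probabilities pinned at 0/1
  with every case correct — is flagged (`converged=False`, diagnostic
  message) rather than raised; the last iterate still ranks cases.
  Standard errors come from the observed information matrix. A reference
  coefficient vector for the real cohort is shipped as a fixture only; a
  fresh ML fit is not expected to reproduce it.
* **RBF-SVM** — the standard soft-margin dual with kernel
  exp(−‖u−v‖²/(2σ²)), σ = 1 by default. The box constraint C defaults
  to 1 and is exposed (`regularization=`): no principled value is fixed
  by the problem, so the default is the common convention and should be
  treated as a tunable. The QP is delegated to scikit-learn's SMO solver;
  the kernel parameterisation and the sign decision rule are fixed here.
* **Bagging** — 50 CART trees (Gini, grown to purity, all features
  considered at every split: bootstrap aggregation, not a random forest),
  each on a bootstrap resample of the full training size, drawn from a
  single seeded generator that also seeds the trees' internal
  tie-breaking, so fits are bit-reproducible. Prediction is majority
  vote; exact ties (possible at even tree counts) go to the control
  class, a deterministic convention that favours specificity. The
  positive-vote fraction is the ROC score. The error curve reports the
  misclassification rate of the first-t-trees vote for t = 1…50.

## Evaluation

Sensitivity is the patient (+1) detection rate, specificity the control
(−1) rate; MCC is defined as 0 when a marginal is empty. ROC curves sweep
the unique scores with ties grouped (equivalent to the normalised
Mann–Whitney statistic, verified by brute force over class pairs); AUC is
the trapezoidal area. The Youden cutoff maximises J = sensitivity +
specificity − 1, ties broken toward higher specificity.

Cross-validation defaults to stratified 5-fold with a seeded shuffle
(195 rows split into five folds of exactly 39). Because subjects
contribute several recordings, instance-level folds are optimistic; a
`subject_aware` option places all recordings of a subject in one fold
(greedy size-balancing, seeded), at the cost of slightly uneven folds.
Held-out predictions are pooled across folds before computing the single
confusion matrix and ROC curve, so results are integer counts over the
whole cohort. Classifier comparison uses the two-sided Wilcoxon
signed-rank test on paired per-instance correct/incorrect indicators
(per-fold accuracy pairing is available): zeros dropped, exact null for
up to 25 untied informative pairs, normal approximation with tie
correction otherwise. With 0/1 indicators ranks are heavily tied, so
exact published p-values are not reproducible without the original fold
assignment; none are asserted.

## Synthetic cohorts

The generator draws each class from a multivariate Gaussian with
block-equicorrelated structure; defaults emulate the real cohort: 48
control / 147 patient rows and three blocks (six jitter-type features
with NHR, six shimmer-type, DFA+PPE) at within-block r = 0.95, matching
the observed 0.83–1.00 range. Class differences are per-feature location
shifts (in control-SD units) and SD ratios; designed informative features
use a 3-SD shift, whose true-density ICPR is 2Φ(−1.5) ≈ 0.13 — far below
the 0.6 threshold — while null features sit near 1. An optional
two-component equal-variance Gaussian mixture makes patient marginals
bimodal, emulating the multimodality that nonlinear measures such as RPDE
show in patients (weight 0 by default).

What the generator does not emulate: the real features' skewness and
physical units, between-feature correlation across blocks, repeated
recordings per subject beyond shared IDs, and class-dependent correlation
structure. Passing selection-recovery tests on these cohorts therefore
shows the statistics separate what they were designed to separate under
Gaussian block correlation; it does not by itself certify performance on
real voice data — that is what the real-cohort reproduction (which
requires the UCI file, see README) checks.

## Numerical and design choices

* Grid 512 points, ±4 bandwidths; doubling the grid moves ICPR by <10⁻³.
* Density permutation invariance and translation equivariance hold to
  machine precision; single-draw ICPR at N=1000 carries sampling noise of
  SD ≈ 0.01–0.02, so accuracy claims are tested on replicate means.
* CSV round trips use 17-significant-digit writes and round-trip float
  parsing, making load/save lossless.
* Missing values are rejected, never imputed.
* Selection on the real panel runs over the 11 post-collapse candidates
  (eight uncombined features plus the three LDA features), not the raw 22.

## Limitations

Marginal (one-feature-at-a-time) selection ignores joint information;
only linear correlation drives the grouping; the bandwidth rule
oversmooths strongly non-Gaussian features, inflating ICPR slightly; CV
fold assignment and SVM C affect real-data classification metrics at the
1–2% level, so cross-study comparisons should fix both.
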