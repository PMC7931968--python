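# Methods

## Problem and model

The package classifies chemical exposures as DNA-damage-inducing (DDI) or
not from gene-by-sample matrices of log2 treated/control expression ratios.
Aneugens, which damage chromosomes through the mitotic spindle rather than
DNA, belong to the non-DDI class. Two classes only; multi-class operation is
out of scope by design.

### Responsive-gene filter

Before training, genes are filtered for responsiveness: in each treatment
condition a two-sample Welch t-test (unequal variances, unadjusted p-values)
compares treated against control replicates on the log2 scale, and the
linear fold change is 2^(mean_treated − mean_control). A gene qualifies in a
condition when p < 0.01 and the fold change is ≥ 1.7 in either direction,
and is retained when it qualifies in ≥ 3 conditions. All three thresholds
are configurable (`FilterCriteria`). The choice of Welch over the pooled
t-test, and of log-scale testing, follows common microarray practice; no
multiple-testing correction is applied because the filter is a screen, not
an inference.

### Nearest shrunken centroids

For class k and gene j with class centroid x̄_kj, overall centroid x̄_j,
pooled within-class SD s_j (denominator n − K) and offset s0:

    d_kj  = (x̄_kj − x̄_j) / (m_k (s_j + s0)),   m_k = sqrt(1/n_k + 1/n)
    d′_kj = sign(d_kj) · max(|d_kj| − Δ, 0)
    x̄′_kj = x̄_j + m_k (s_j + s0) d′_kj

s0 is the median of {s_j}; without it near-constant genes produce unstable
standardized differences. The `sqrt(1/n_k − 1/n)` normalizer used by some
implementations is selectable (`m_variant="minus"`). Priors default to class
proportions; uniform or explicit priors are configurable. A gene "survives"
at Δ when d′_kj ≠ 0 for at least one class; with two classes and equal class
sizes d_DDI,j = −d_nonDDI,j exactly, so survival is symmetric. Values of |d|
exactly equal to Δ shrink to zero (strict max), matching the
soft-thresholding formula.

Test samples are scored with the discriminant over surviving genes

    δ_k(x) = Σ_j (x_j − x̄′_kj)² / (s_j + s0)² − 2 log π_k

and posteriors p_k = exp(−δ_k/2) / Σ_l exp(−δ_l/2), evaluated after
shifting by the max log-term so large discriminants cannot underflow.

### Cross-validation

Stratified k-fold (default 10): within each class, indices are shuffled by a
seeded generator and split into k chunks, remainders going to the earliest
folds. A fold that would leave fewer than two training samples in either
class raises an error suggesting a smaller k. Identical seeds give
bit-identical folds.

### Three-pronged sample classification

- **PA**: positive when P(DDI) > 0.9, negative below 0.1, marginal in the
  open band between — the positive cutoff is the documented convention; the
  symmetric negative cutoff and hence the marginal band are this package's
  choice, since only the positive threshold is conventionally stated.
- **2DC**: the test profile is appended to the reference profiles
  (surviving genes only), pairwise Euclidean distances feed unweighted
  average-linkage agglomeration (scipy), and the tree is cut into two
  clusters. The call is the majority reference class of the test sample's
  cluster; an exact tie, or a cluster containing no reference sample, is
  marginal. The two-cluster cut plus majority vote is our assignment rule
  for a new sample; the published description asserts only that the
  reference classes separate into two main clusters.
- **PCA**: PCA is fitted on the reference profiles (genes centered), PC1
  oriented so the DDI class mean score is positive, and the sample
  projected. The boundary is the midpoint b of the class mean scores with a
  marginal half-width ε = 0.10 × |mean_DDI − mean_nonDDI|
  (`margin_frac`, configurable); marginal PCA calls exist in published
  validation tables but no numeric criterion accompanies them, so the
  fractional band is our choice.
- **Overall**: positive if any method is positive; negative only when all
  three are negative; otherwise marginal. The marginal overall state is
  reported rather than forced to a binary call — published tables happen to
  contain no marginal overall rows, and the implementation reproduces all
  48 of them from the per-method columns.

The overall rule is monotone (upgrading one input never downgrades the
output), and deliberately sensitivity-first: it exists to keep false
negatives rare in a safety-assessment setting.

## Concentration pre-screen and potency

`select_screen_dose` scans a dose-by-gene table of linear fold changes for
GADD45A, ATF3 and CDKN1A and returns the lowest dose at which any of the
three reaches the threshold (default 1.5-fold — "robust induction" is not
quantified in the source descriptions, so the default is configurable), or
an explicit no-qualifier outcome.

Dose-response series are modeled on the linear expression scale
(2^log2ratio, control ≡ 1), because a "10% increase over background" is
undefined on the log2-ratio scale where background is identically 0. The
family is a four-parameter Hill curve f(d) = a + b·dⁿ/(kⁿ + dⁿ) with the
exponent capped to [1, 18] (the cap prevents step-function degeneracy) and
a two-parameter exponential f(d) = a·exp(c·d); both are fitted by bounded
least squares with five seeded multi-starts, and the reported model
minimizes AIC = N·ln(RSS/N) + 2p. Non-convergence is flagged, not raised.
The benchmark dose solves |f(d) − f(0)| = BMR·|f(0)| (BMR default 0.10) by
bracketing on a log-spaced grid followed by Brent root refinement; curves
that never reach the benchmark response within the tested range are flagged
above-range. Panel potency is the median of converged, in-range per-gene
BMDs (midpoint convention for even counts); genes whose fitted curve moves
less than 2% of baseline across the range are flagged non-responsive and
excluded. BMDL/BMDU confidence limits and model averaging are out of scope.

## Synthetic data

`simulate_reference_set` draws a two-class log2-ratio matrix: every gene is
Normal(0, σ) noise, and a planted subset additionally shifts by ±effect in
DDI samples, half up- and half down-regulated to mirror the mixed-direction
character of real DNA-damage signatures. Gaussian noise on the log2 scale
(log-normal on the linear scale) is the standard microarray error model.
Defaults (11 DDI / 17 non-DDI samples, 500 genes, 20 informative) mirror the
size and class balance of the original 28-condition learning set. What the
generator does **not** emulate: gene-gene correlation, batch structure,
heteroscedastic intensity-dependent variance, and the identity of any real
biomarker gene — so a passing test demonstrates correctness of the
algorithms under the stated statistical model, not field performance on
real profiling data. `simulate_dose_series` produces Hill-shaped linear
responses with multiplicative log-normal noise at user-chosen parameters.

## Numerical and design choices

- Gene identifiers are canonicalized (trim, upper-case) and matched
  exactly; matrices reject duplicates after canonicalization and non-finite
  values.
- Ternary calls accept both hyphen and en-dash marginal glyphs on input and
  always emit `+/-`.
- Panel extraction tolerates missing genes down to a 90% coverage floor
  (configurable) and then fails loudly, listing the missing symbols.
- The average-linkage merge tree is computed by scipy; the test suite
  verifies it against an independent naive O(n³) agglomeration loop, and
  PCA projections against a direct eigendecomposition of the covariance.
- Scaled problem sizes in tests (e.g., 28-sample surrogates, ≤8-point
  clustering instances, 50-seed potency replicates) were chosen to make the
  suite quick to run on a laptop while keeping each statistical claim
  testable; the acceptance script regenerates its inputs at the same sizes.
- In the cross-validation surrogate of the learning set (effect 3.0 log2
  units, σ 0.3), informative genes carry standardized differences around
  |d| ≈ 8 while null genes stay below ≈ 3, so Δ = 4 retains the planted
  panel; Δ = 2 is used at the weaker effect 2.0 / σ 0.5 setting.

## Known limitations

- Strictly two-class; no multi-class or continuous genotoxicity score.
- The real 64-gene biomarker panel is not shipped (it is user-supplied
  input); `example_panel` is a synthetic placeholder.
- No platform-specific ingestion (nCounter RCC, CEL, TempO-Seq); input is
  delimited text or GCT 1.2 on the log2-ratio scale.
- BMD uncertainty (confidence limits) and in vitro–in vivo extrapolation
  are not implemented.
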