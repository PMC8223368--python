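# Methods

This note documents the statistical content of `spatepi`: the models and
procedures, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, numerical conventions, and known
limitations.

## Outcome and aggregation

The unit of analysis is the survey cluster (enumeration area). Each
respondent carries a composite binary outcome — here, a pregnancy before
age 19, defined as a past birth before 19 **or** a current pregnancy — and
a positive sampling weight. The cluster-level outcome is the weighted
proportion `p_g = Σ w_i x_i / Σ w_i`, which is invariant to rescaling all
weights by a positive constant; the package therefore imposes no weight
normalization convention and works with whatever weights the survey
provides. Community covariates (e.g. the share of respondents in the two
lowest wealth quintiles, contraceptive non-use, traditional contraceptive
use, secondary education) are aggregated the same way. Missing covariate
values are excluded pairwise with a logged count; missing outcome flags are
an error, never imputed. Display rounding in summary tables is
half-away-from-zero to two decimals; weighted counts are rounded to
integers for display only.

## Spatial weights

Clusters are points spanning many degrees of latitude, so all distances
are great-circle (haversine, Earth radius 6371.0088 km), not projected
Euclidean. Two conceptualizations are offered: k nearest neighbours
(distance ties broken by ascending id, documented and order-invariant) and
a fixed distance band. The default band is the smallest distance that
leaves no cluster isolated — the behaviour of common desktop GIS defaults —
because survey configurations with sparse desert clusters otherwise
produce islands, which are reported as an explicit error listing the
offending ids. `include_self` adds w_ii = 1 before any row-standardization;
Gi* requires it, Moran's I forbids it.

## Global Moran's I

`I = (n/S0) Σ_ij w_ij (y_i−ȳ)(y_j−ȳ) / Σ_i (y_i−ȳ)²` with expectation
−1/(n−1) under spatial randomness. Analytic inference uses the
normality-assumption variance (the convention of the GIS tools this
workflow mirrors); a value-permutation test (default one-sided toward
clustering, `p = (r+1)/(m+1)`) is available for distribution-free
inference and is exactly sized by construction. Constant inputs are a
zero-variance error, not I = 0.

## Getis-Ord Gi*

The self-inclusive local statistic
`z_i = [Σ_j w_ij x_j − X̄ Σ_j w_ij] / (S √[(n Σ_j w_ij² − (Σ_j w_ij)²)/(n−1)])`
with X̄ and S the global mean and population standard deviation. z-scores
are binned symmetrically at |z| ≥ 1.645 / 1.96 / 2.576 into 90/95/99%
hot/cold classes, with an optional Benjamini–Hochberg gate applied to the
normal p-values before binning. A window that spans the entire study area
makes the denominator vanish; that is reported as an error suggesting a
smaller neighbourhood, not a silent zero.

## Bernoulli spatial scan

Cases and controls are counted per cluster. Circular windows grow around
every cluster centre by absorbing clusters in increasing distance (tied
distances enter together), while the window population stays within a
maximum fraction of the total (default 0.5, the conventional cap). Each
window is scored by the Bernoulli log-likelihood ratio, one-sided toward
elevated risk, with `0·ln 0 := 0`; a low-rate mode mirrors it. Inference
conditions on the total case count C: replicates redistribute C cases over
the N individuals by multivariate hypergeometric sampling with cluster
populations fixed, and `p = (1 + #{replicate max ≥ LLR})/(1 + reps)`
(default 999 replications). Secondary clusters are reported greedily by
LLR among windows sharing no member with a higher-ranked reported cluster;
at most 10 clusters with p ≤ 0.05 are reported by default (the primary is
always reported). The whole window grid is evaluated as distance-ordered
prefix sums, so a scan with hundreds of clusters and 999 replicates runs
in seconds.

## OLS and the assumption battery

The global model is least squares of cluster prevalence on community
covariates with an intercept. Inference is reported classically and with
HC1 (White-type, small-sample-scaled) robust covariance — the "robust"
columns of the desktop tools this replaces state no variant, and HC1 is
their documented choice. Diagnostics: VIF_j = 1/(1−R²_j) with the gate at
7.5; Jarque–Bera `n/6 (S² + (K−3)²/4)` on the residuals (χ², 2 df);
Koenker's studentized Breusch–Pagan `n·R²` from regressing squared
residuals on the predictors (χ², k df); joint F from R²; robust joint Wald
on the slope block; residual Moran's I against the analysis weights. AICc
uses the Gaussian profile likelihood with the residual variance counted as
a parameter: `AICc = n ln(2π RSS/n) + n + 2K + 2K(K+1)/(n−K−1)`,
K = k + 2. The exploratory search fits every predictor subset (capped at
12 candidates) and keeps models whose robust coefficient p-values are all
below 0.05, VIFs below 7.5, and whose JB, BP and residual-Moran p-values
are all above 0.05, ranked by adjusted R²; the 0.05 significance gate is a
package convention, the sources of this workflow print only "< 0.01"
outcomes without stating their gate.

## Geographically weighted regression

At each cluster, `β̂(u_i,v_i) = (X'W_iX)⁻¹X'W_iy` with diagonal kernel
weights by great-circle distance. Default kernel is adaptive bisquare
(bandwidth = number of neighbours, local bandwidth the distance to the
N-th nearest neighbour of the regression point), with fixed-bandwidth
gaussian available; the adaptive bisquare default matches the desktop GWR
convention for irregularly spaced survey clusters. The effective number of
parameters is the hat-matrix trace tr(S) (the `2 tr(S) − tr(S'S)` variant
is not reported); the corrected AIC is the Fotheringham-type
`AICc = 2n ln σ̂ + n ln 2π + n(n + tr S)/(n − 2 − tr S)`, σ̂² = RSS/n.
Bandwidth is chosen by golden-section minimisation of AICc (interval ends
are probed too; adaptive bandwidths are rounded integers with
memoisation), and the full bandwidth-AICc trace is returned. Global
adjusted R² uses `1 − (1−R²)(n−1)/(n−tr S−1)`. Model preference between
OLS and GWR follows the Δ > 3 AICc rule: a smaller difference is
"indistinguishable". With tr(S) → k+1 the two AICc formulas differ only by
a constant independent of RSS, so the comparison is internally consistent.
Predictions are made at the data locations only — one equation per
surveyed cluster, no interpolation grid. A covariate that is locally
constant under a compact kernel makes the local design singular; the error
names the location and covariate and advises a wider bandwidth.

## Synthetic survey generator

The generator emulates the aspects of a DHS-style survey that the methods
are sensitive to: ~600 cluster points uniform over an Ethiopia-like
bounding box (33–48°E, 3.4–14.9°N); 2–10 teenagers per cluster; an
individual-level logistic outcome whose intercept and covariate effects
are spatial surfaces (constant, linear gradient, or gaussian bump in km);
Bernoulli community covariates with configurable (optionally spatial)
prevalence; log-normal(0, 0.25) weights rescaled to mean one, mimicking
normalized survey weights; Bernoulli(202/645) urban assignment matching
the emulated sampling frame; and the DHS confidentiality displacement
(uniform bearing, uniform distance up to 2 km urban / 5 km rural, exact
spherical destination formula). The default study-conditions configuration
(`dhs_like_config`) uses 617 clusters — the cluster count of the survey it
emulates — and plants elevated baseline risk in the south-east of the
domain so hotspot and scan stages have a known signal. All randomness
flows from one seed through named `SeedSequence` spawns; identical
(config, seed) pairs are byte-identical.

Deliberately **not** emulated: the two-stage stratified household
selection, age structure, non-response, region-boundary geography (region
labels are a coarse grid), or spatially correlated covariates. Passing
tests therefore validate the estimators' behaviour under known spatial
structure with binomial noise — they do not certify performance on real
survey data, where weights, covariate confounding and displacement
interact in ways the generator does not reproduce.

## Experiment sizes and calibration

The validation experiments (in `spatepi.experiments`, exercised by the
test suite and `scripts/acceptance.py`) use: 200 runs × 99
permutations/replications for the type-I error of the Moran permutation
test (40 clusters) and of the scan (20 clusters × 30 teenagers, rate
0.12); 100 runs at n = 617, k = 4 for OLS coverage; 400 clusters for GWR
gradient-surface recovery (slope linear in longitude, noise SD 0.03); 20
seeds × 50 clusters with a circular relative-risk-3 zone for planted scan
recovery (Jaccard > 0.5); and 20 seeds × 617 clusters with 4 true
predictors among 8 candidates for exploratory-search recovery. These sizes
give binomial confidence intervals tight enough to distinguish nominal
from broken calibration while keeping a full run in the tens of seconds.
The scan's Monte Carlo test is slightly conservative because tied maximum
LLR values inflate the replicate rank; the calibration check bounds its
size from above rather than two-sided.

## Numerical conventions and edge cases

- Constant response vectors are zero-variance errors for Moran, Gi* and
  Jarque–Bera — never silently 0.
- Rank-deficient OLS designs raise an error naming the collinear columns
  (via pivoted QR); perfectly collinear VIFs are flagged `inf`, not
  raised, so the gate can reject them.
- Scan population caps use `⌊max_fraction · N⌋`; windows whose complement
  would be empty are never scored.
- The LLR uses `xlogy` so boundary counts (c = 0, c = n) are exact.
- Quantile class breaks for coefficient surfaces collapse duplicates, so
  a constant field yields a single class rather than an error.
- R² = 1 (perfect fit) maps the joint F to +inf with p = 0.

## Known limitations

- Windows are circles on the sphere centred at observed clusters only;
  elliptic or space-time scans are out of scope.
- No spatial-lag/spatial-error econometric models; residual spatial
  autocorrelation is diagnosed, not modelled.
- Gi* and Moran p-values assume the normality approximation
  (permutation inference is provided for Moran only).
- Mixed/multiscale GWR and nonstationarity Monte Carlo tests are not
  implemented.
- The regional summary reproduces published tables only up to their own
  rounding conventions; rows whose printed counts and percentages are
  mutually inconsistent cannot (and should not) be matched exactly.
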