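# Methods

This note documents the statistical procedures, defaults and deliberate
simplifications behind `arsmicro`, and what the synthetic-cohort tests do
and do not demonstrate about real data.

## Preprocessing

Urinary arsenic values flagged below the assay limit of detection
(`lod_ugL`, default 0.05 µg/L) are substituted at LOD/2 = 0.025 µg/L, the
standard single-imputation rule for lightly censored exposure data; all
modeling then uses ln(concentration). Median and quartile groupings are
made on the concentration scale (the groupings are descriptive devices for
ordination and the distance contrast; inference always uses the continuous
log exposure). Quantile boundaries use linear interpolation of order
statistics (numpy's default, exposed as `quantile_rule`), and boundary ties
go to the lower group.

Feeding is categorized from feeding-history flags into exclusive
breastfeeding, exclusive formula and combination feeding; stratified
analyses pool the latter two as "formula-fed" and cross with sex, giving
four strata. Subjects with unreported sex stay in the unstratified
analysis only.

The OTU table is rarefied once, without replacement, to the minimum sample
depth (exact uniform subsampling via the multivariate hypergeometric
distribution; seed recorded in the run manifest). Both the distance stage
and the ZILN stage consume this same rarefied table — one table keeps the
two stages consistent, and per-stratum analyses reuse submatrices of the
single cohort-wide distance matrix rather than re-rarefying, avoiding
seed artifacts between strata.

## Generalized UniFrac

Trees are midpoint rooted (ties between equally long tip-to-tip paths
broken lexicographically, for determinism; total length is asserted
unchanged). For each edge we record the branch length and each sample's
descendant read proportion; the distance is the α-weighted normalized sum
over edges, with edges carrying no reads from either sample contributing
zero to both numerator and denominator. α defaults to 0.5, the standard
compromise of the generalized-UniFrac family; α = 1 equals normalized
weighted UniFrac (verified against scikit-bio's implementation to 1e-10)
and the implementation as a whole is verified against a brute-force
edge-summation oracle on small trees. The distance is scale-invariant in
the branch lengths and need not satisfy the triangle inequality, so no
metric property is assumed downstream.

## Covariate-adjusted PERMANOVA

With G = −½·J(D∘D)J the Gower-centered inner-product matrix, sums of
squares are projection traces tr(H·G) under a sequential decomposition
with covariates entered before the exposure; the exposure pseudo-F is
(SS_exp/df_exp)/(SS_res/df_res). Significance comes from permuting the
exposure column while holding covariates fixed (default), or from
Freedman–Lane permutation of the reduced-model exposure residuals
(`scheme="fl"`); both are valid nulls for the exposure term conditional on
covariates. The p-value counts the observed statistic, p = (1+b)/(1+B),
so p ≥ 1/(B+1) and p > 0 always. Default B = 10,000. Calibration is
checked by simulation: under exchangeable Gaussian data the empirical
type-I error at nominal 0.05 sits inside the binomial 95% band.

PCoA is the eigendecomposition of G; coordinates are eigenvectors scaled
by the square root of positive eigenvalues, negative eigenvalues are
reported unmodified, and proportions explained are normalized by the
positive inertia (so positive proportions sum to one).

## Extreme-quartile contrast with BCa bootstrap

The statistic is the mean distance over all (Q1 sample, Q4 sample) pairs.
The bootstrap resamples **subjects** within each extreme quartile with
replacement (resampling pairs would ignore that pairs sharing a subject
are dependent) and recomputes the statistic, default B = 2,000. The BCa
interval uses bias correction z₀ = Φ⁻¹(fraction of bootstrap statistics
below the observed value) and acceleration from the jackknife-skewness
formula over leave-one-subject-out statistics. A degenerate bootstrap
distribution collapses the interval to the point estimate with a warning.
Coverage of the 95% interval, measured against an analytically known
population mean distance (E|z−z′| = 2/√π for standard normal positions),
lands near 0.93–0.95 in the simulation suite.

## Zero-inflated logistic-normal model with MCP selection

Per OTU: a logistic regression of presence on the design (intercept,
ln-arsenic, specific gravity, feeding indicators) and, conditional on
presence, least squares on logit(relative abundance) — the additive
log-ratio of the OTU against the rest of the composition, which keeps each
OTU's model univariate. Robust HC0 sandwich variances are reported for
the positive part. Taxa are treated as working-independent; a
tree-structured working correlation would be the natural refinement, and
its omission is a deliberate simplification documented here rather than a
claim of independence.

Selection refits the exposure coefficients jointly under the minimax
concave penalty (γ = 3). Under working independence, the joint coordinate
descent decomposes per OTU into the closed-form univariate MCP threshold
applied to the covariate-partialled, standardized exposure (the penalty is
applied on the standardized-coefficient scale, the usual convention). The
penalty level is tuned by an extended BIC whose per-variable cost is
log N + 2ζ·log m (ζ = 1 by default, m = number of candidate OTUs); the
extra log m term controls family-wise false selection across the many
candidate OTUs, and ζ = 0 recovers the classical BIC. λ = 0 reproduces
the unpenalized fit; the grid is 50 log-spaced points from the smallest
all-zeroing λ down to λ/100. OTUs below 10% prevalence, or with too few
positive observations to fit, are excluded with a warning. Selected OTUs
are classified by coefficient sign and aggregated (mean of member
coefficients) to the lowest assigned rank of their Greengenes-style
lineages, with a "mixed" flag when member signs disagree.

## Synthetic cohort generator

The generator mirrors the analysis model so recovery is well-posed:
presence is Bernoulli with per-OTU baseline log-odds ~ N(0, 1.5²) (heavy,
OTU-specific zero inflation), positive logit-abundance is Gaussian
(baseline mean ~ N(−4, 1), residual SD 1.0), compositions are closed and
scaled to log-normal read depths (median 30,000, σ_log 0.3, so the minimum
depth across ~200 samples lands near 10–12 thousand reads), with
largest-remainder rounding preserving row sums exactly. Cohort margins
default to 204 subjects with sex 118:81 (+5 unreported) and feeding
146:49:9, drawn independently. Exposure is log-normal with common
σ_log = 0.9 and feeding-group arithmetic means 0.5/0.9/1.2 µg/L, which
puts the overall median near 0.36–0.4 µg/L and yields roughly 1–3
below-LOD subjects per cohort; specific gravity is truncated normal
(1.015, 0.005) on (0.99, 1.05). Planted effects act on both model parts
for a configurable OTU subset (half positive, half negative signs),
per unit of centered ln-arsenic, optionally confined to one sex×feeding
stratum; the default stratified-effect setting used in the power study is
size 2.0 on 10 of 100 OTUs in formula-fed males, chosen so the per-stratum
permutation test at n ≈ 33 has high power and the joint event "flagged in
the target stratum and in none of the other three" clears 80%.

What the generator does **not** emulate: sequencing error and chimeras,
taxon-taxon ecological interactions beyond compositional closure,
overdispersion of counts given the composition, longitudinal structure,
or confounding of exposure with unmeasured covariates. Passing recovery
and power tests therefore demonstrate internal correctness and operating
characteristics under the stated model, not performance guarantees on
real cohorts. Exposure is correlated with feeding by construction (as in
real data), which is why covariate adjustment is exercised rather than
marginal testing.

## Numerical and degenerate-input choices

- Design-matrix rank is checked up front; collinear columns are named.
- Constant exposure, all-identical concentrations (degenerate median or
  quartile split), zero-length trees, empty sample/OTU intersections and
  all-zero distance matrices raise typed validation errors.
- Permutation F comparisons use a 1e-12 slack so exact ties count as
  "greater or equal", keeping p-values conservative.
- Strata with fewer than `min_stratum_n` (default 10) samples skip the
  distance-based tests; quartile contrasts need at least 8 samples; both
  skips are logged in the manifest rather than failing the run.
- Problem sizes in the simulation studies (500 datasets for calibration
  and coverage, 5 replicates for recovery, 25 for power, 99–199
  permutations inside simulations) were chosen to keep Monte Carlo error
  comfortably inside the asserted bands while the full suite runs in well
  under a minute for the statistical checks.

## Known limitations

- The ZILN estimating equations use working independence across taxa; the
  sandwich variances are robust to the resulting misspecification, but
  efficiency is not optimal under strong phylogenetic correlation.
- MCP selection penalizes only the exposure coefficients; nuisance
  coefficients are never shrunk.
- Rarefaction is a single draw by design (seeded and recorded); averaging
  over rarefactions is out of scope.
- Generalized UniFrac is computed densely over all edges; no sparse/fast
  UniFrac optimizations are attempted.
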