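# Methods

## Problem setting

The package targets ecological (area-level) association studies of an
environmental exposure and stratified health-outcome counts across a
moderate number of contiguous regions — the motivating setting is a
city of ~140 neighborhoods with mental-health disorder counts split by
sex and four age groups (0–19, 20–44, 45–64, ≥65), a vegetation
covariate from satellite imagery, and four marginalization covariates.
Counts at this scale are overdispersed relative to Poisson and spatially
autocorrelated, so inference proceeds through a hierarchical Bayesian
convolution model rather than ordinary Poisson regression.

## Expected counts

Indirect (internal) standardization: for stratum *g* = (sex, age group),
the study-wide rate is ρ_g = Σ_i O_{ig} / Σ_i P_{ig} and the expected
count is E_{ig} = ρ_g · P_{ig}. Two consequences are used as exact
invariants in the tests: Σ_i E_{ig} = Σ_i O_{ig} per stratum, and the
expected-count-weighted mean of the standardized incidence ratios
SIR_i = O_i/E_i is exactly 1. An external rate table can replace the
internal rates when population reference rates exist. Regions with zero
stratum population receive E = 0 and are excluded from that stratum's
model with a logged exclusion list.

## Spatial autocorrelation screening

Global Moran's I with binary or row-standardized contiguity weights
(row-standardized by default for testing, binary internally for the ICAR
kernel). Inference is by random permutation of the values over regions
with the plus-one pseudo p-value, p = (1 + #extreme)/(1 + n_perm),
n_perm = 999 by default, so the smallest attainable p is 0.001. The
default alternative is one-sided "greater" (positive autocorrelation);
two-sided uses extremity of |I|. Screening in the pipeline runs on
log((O + 0.5)/E) — the modeled quantity — with the raw-count statistic
reported alongside. The 0.5 offset keeps zero-count regions finite.

## The BYM Poisson-lognormal model

Per stratum, O_i ~ Poisson(E_i r_i) with
log r_i = β₀ + Σ_k β_k X_ki + u_i + s_i. The unstructured effect is
u_i ~ N(0, 1/τ_u); the spatial effect s carries the intrinsic CAR prior
with density kernel exp(−(τ_s/2) Σ_{i~j} (s_i − s_j)²) over contiguity
pairs, rank n − c for c graph components, identified by recentering s to
mean zero (per component) each sweep, with the removed level folded into
β₀ so the likelihood is untouched.

Priors (all configurable): β_k ~ N(0, 100²), τ_u, τ_s ~ Gamma(0.5,
0.0005). These are the long-standing diffuse defaults for convolution
disease-mapping models; with region counts near 140 and expected counts
in the tens to hundreds, the data dominate them. Covariates enter on
their natural scale by default (EVI lives in [0, 1], so a coefficient is
the log-risk change over the full vegetation range); a `standardize`
flag z-scores them and records the choice in the output metadata.

### Sampler

Metropolis-within-Gibbs, fully vectorized:

- β: per-coordinate Gaussian random walks. Internally the covariates
  are mean-centered for sampling (stored draws are transformed back),
  which removes the intercept–slope posterior correlation.
- u: simultaneous single-site random-walk updates (valid because the
  u_i are conditionally independent given the rest).
- s: the adjacency graph is greedily colored; sites within a color
  class are conditionally independent under the pairwise ICAR kernel
  and are updated simultaneously, one color at a time.
- τ_u, τ_s: conjugate Gamma draws with shapes a + n/2 and
  a + (n − c)/2 and rates b + Σu²/2 and b + Σ_{i~j}(s_i−s_j)²/2.
- Ridge moves: one extra Metropolis step per iteration translates the
  state along each likelihood-invariant direction (β₀ + δ, u − δ) and
  (β_k + δ, s − δ·x_k) with only the priors entering the acceptance
  ratio. These directions are exactly the weakly identified ridges
  created by spatial confounding — a smooth covariate is nearly
  collinear with the ICAR field — and without them the slope chains mix
  an order of magnitude more slowly and interval coverage degrades.

Step sizes adapt every 50 iterations during burn-in only (multiplicative
update toward 0.44 acceptance, clipped to [1e−4, 20]) and are frozen
afterwards, so the retained chain is a valid fixed-kernel Markov chain.
Defaults: 15,000 iterations, 5,000 burn-in, thin 1. Geweke z-scores for
the β chains are computed (with ESS-adjusted standard errors) and
reported on the fitted estimator, not enforced. All randomness flows
from a single `random_state`; identical seeds give bit-identical chains.
A non-finite posterior state aborts with the offending state in the
error message.

### Posterior functionals

- ψ = SD(s)/(SD(s) + SD(u)) computed per retained draw from the
  empirical (ddof = 1) standard deviations of that draw's s and u
  vectors, then summarized by the mean and equal-tailed 95% interval.
  Draws where both SDs are zero have no defined ψ and are dropped with a
  log message. Convergence note: the ψ posterior depends on the
  τ_u/τ_s split, which mixes more slowly than the coefficients — short
  chains (≲6k iterations) visibly blur the spatial/nonspatial contrast,
  which is why the defaults are 15k.
- Relative risk r_i = exp(β₀ + x_i′β + u_i + s_i) per draw, summarized
  by mean and equal-tailed 95% bounds; the map export adds an
  exceedance flag for mean r_i > 1.
- A coefficient is flagged significant when its equal-tailed 95%
  interval strictly excludes zero; an endpoint exactly at zero is not
  flagged.

## Synthetic data generator

The generator emulates the study conditions so that every downstream
stage can be validated against known truth:

- Geography: rook-contiguity lattices (queen optional); the default
  study size is 10 × 14 = 140 regions, matching the motivating study's
  neighborhood count.
- Covariates: X1 is a smooth diagonal gradient plus N(0, 0.05) noise
  clipped to [0, 1] (EVI-like, strongly spatially autocorrelated);
  X2…X5 are iid standard normal (deprivation-score-like).
- Populations: per (region, stratum), uniform integers in [800, 4000] —
  neighborhood-stratum sizes of a large city.
- Baseline rates: per-stratum values evenly spaced over 0.05–0.25
  cases/person, giving each stratum a distinct crude level of plausible
  magnitude; these are deliberate placeholders, not calibrated to any
  real population, and are configurable.
- Counts: E = rate × population; u ~ N(0, σ_u²); s is an exact ICAR
  draw realized by eigendecomposition of the graph Laplacian (variance
  1/λ along each non-null eigenvector, null space excluded), recentered
  and rescaled so its empirical SD equals σ_s; O ~ Poisson(E·exp(Xβ + u
  + s)). Each stratum gets independent effect realizations (a flag
  shares one realization). Counts exceeding the population are
  truncated with a logged warning so the StratumTable invariant O ≤ P
  always holds; in the default regimes truncation touches at most a few
  regions in the highest-rate strata.
- Band rasters: pixels mix a vegetated endmember (high NIR, low red)
  and a bare endmember according to the region's vegetation fraction,
  plus N(0, 0.01) noise, clamped to [0, 1] — enough structure for the
  EVI stage to recover the regional vegetation ranking (Spearman > 0.9)
  without pretending to be real imagery.

What the generator does **not** emulate: real geographic boundary
irregularity, spatially correlated deprivation covariates, covariate
measurement error, cloud/shadow artifacts in imagery, or
population-structure correlations between strata. Passing tests
demonstrate internal statistical correctness (recovery, calibration,
discrimination) under the stated generative model, not robustness to
those real-data complications.

## EVI

EVI = G·(NIR − Red)/(NIR + C1·Red − C2·Blue + L) with the standard
coefficients G = 2.5, C1 = 6, C2 = 7.5, L = 1, exposed as parameters.
Pixels with any nodata input or denominator magnitude below 1e−9 are
masked rather than raising; output is not clipped to [−1, 1] (values
outside are counted in a log message — sensor artifacts are out of
scope). The zonal statistic is the unweighted mean over valid pixels;
regions with no valid pixel are reported missing. Rasters are plain
whitespace text grids (NaN = nodata) or single-band TIFFs.

## Pipeline determinism

A study run derives one seed per stratum as master_seed + 100 + stratum
index, so strata are reproducible individually and independent of which
subset is requested. Two runs with the same master seed produce
byte-identical report CSVs; this is asserted in the test suite.

## Problem sizes used in the automated checks

Oracle comparisons run on ≤10-region toys and 10×10 pixel grids.
Coefficient recovery uses 20 replicates of the 140-region lattice at
15,000 iterations per fit; ψ discrimination uses 10 replicates per
regime at the same chain length; Moran calibration uses 200 null and 50
ICAR-field replicates at 999 permutations. The full suite and the
acceptance script each complete in a few minutes on one CPU.

## Design choices where the design was open

- The ψ functional is taken as SD_s/(SD_s + SD_u) on the per-draw
  empirical SDs — the variance-partition form whose limits match the
  interpretation "ψ → 1 ⇒ variation mainly spatial".
- Independent hyperparameters per stratum (eight separate models), not
  a shared hierarchy: the stratified reporting structure implies
  separate fits, and it isolates failures per stratum.
- Moran screening defaults to the transformed log-SIR rather than raw
  counts, because the transformed quantity is what the model sees; both
  are reported.
- Sampling-based inference (MCMC) rather than INLA-style approximation:
  exact reproducibility and no extra dependencies, at problem sizes
  where a few seconds per fit is acceptable.

## Known limitations

- The ICAR recentering step makes the spatial effect's level
  non-identifiable by construction; only contrasts of s are meaningful.
- Ecological design: coefficients describe area-level associations and
  support no individual-level or causal claims.
- Single-chain inference; the Geweke diagnostic is reported but
  convergence is ultimately the user's responsibility for unusual data.
- The permutation test assumes exchangeability under the null; it is
  not exact in the presence of strong covariate-driven mean structure
  (screen residuals or SIRs, not raw rates, in that case).
- No support for disconnected geographies in the synthetic ICAR draw
  beyond per-component centering; islands get zero spatial effect
  information.
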