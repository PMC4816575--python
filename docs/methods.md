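# Methods

This note documents the models implemented in `cloudclim`, the choices
made where the design was genuinely open, and what the synthetic-data
experiments do and do not demonstrate.

## Cloud-frequency climatology

A daily observation at a pixel is a binary cloud flag plus a validity
bit.  The monthly cloud frequency for sensor s, month m, year y is
CF = 100 · (positive flags / valid observations); pixels with no valid
observation in the month are masked.  Climatological summaries are
μₘ = mean over years of CF and σₘ = SD over years (sample, n−1; σₘ
masked with fewer than two years).  Sensors are merged by equal-weight
averaging of their μₘ, falling back to the available sensor where only
one has data.

Derived metrics, all in percent cloud frequency:

* mean annual = mean of available μₘ;
* intra-annual variability (seasonality) = sample SD of the available
  μₘ (masked with < 2 months);
* inter-annual variability (stability) = mean of available σₘ;
* spatial variability = focal SD of mean annual CF within a circular
  window (radius in cells; the window is not great-circle corrected —
  synthetic grids are abstract, and the approximation is documented
  rather than hidden);
* seasonal concentration: the 12 monthly means are polar vectors with
  angle φₘ = 2π(m−1)/12; with resultant S = Σ μₘ e^{iφₘ}, the index is
  100·|S|/Σμₘ and the peak month is the month angularly nearest arg(S),
  ties resolved to the earlier calendar month.  Normalizing by the
  *sum* (not the mean) of the monthly values is what makes the index
  span exactly 0 (uniform) to 100 (single month); normalizing by the
  mean annual value would span 0–12.  Pixels with a zero annual total
  or fewer than two available months are masked; when the resultant is
  numerically zero the peak month is undefined and masked.

Missing months (polar winter darkness) are handled by summarizing over
available months and publishing the month count.  Sample SDs (n−1) are
used throughout the climatology module; the focal-window SD exposes a
population/sample flag (sample by default) because the window statistic
is sometimes wanted as a descriptive population SD of the kernel.

Stability hotspots: cells in the top decile of mean annual CF are
labelled by whether they also sit in the bottom decile of intra-annual
variability, of inter-annual variability, of both, or of neither.
Quantiles are computed globally over unmasked cells and require strictly
varying inputs (a constant variability field has no decile structure and
raises).

## Stripe-artifact removal

Orbital geometry makes observation frequency — and therefore long-term
cloud frequency — banded along near-longitudinal stripes (≈ ±15° from
the meridian for a morning/afternoon sensor pair).  The noise is
stationary and oriented, so it is treated in the frequency domain.  An
oriented pattern (anisotropic Gaussian envelope at angle θ, scales
σx across and σy along the stripe, zero mean, unit L2 norm) defines a
spectral ridge; each frequency f is scored by

    q(f) = |P(f)|² · |D(f)|⁴,

with P the pattern transfer function and |D|² the transfer function of
the finite-difference gradient.  The |D|⁴ factor is a second-difference
(thin-plate) smoothness prior on the clean image: it drives q → 0 at the
low frequencies where the climate signal lives, while stripe harmonics —
higher across-stripe frequencies inside the pattern's ridge — score
highly.  The default estimator zeroes all frequencies with q > λ.  This
is an orthogonal projection, hence exactly idempotent, exactly
mean-preserving (the zero frequency is never gated), and the identity
for large λ; a Wiener-style shrinkage gain q/(q+λ) is available as
`mode="wiener"` for users who prefer soft attenuation.  Masked cells are
inpainted by nearest neighbor before the FFT and re-masked after.

Defaults mirror the stripe geometry of the twice-daily sensor pair
(θ = ±15°, σx = 5, σy = 200, in pixels of the target grid; λ = 1).  The
scale parameters are grid-relative and deliberately exposed: the
spectral ridge must cover the stripe fundamental, so σx should be of
the order of the stripe width.

The synthetic destriping experiments use a 120×120 grid, truth smoothed
over ~40 cells, and Gaussian-profile stripes of spacing 10 and width 2
cells with ~12% cloud-frequency amplitude.  This scale separation —
climate structure an order of magnitude broader than the stripes —
mirrors the real situation and is what makes destriping well-posed; when
signal and stripes share a spatial scale no linear filter can separate
them.  Note that a one-signed stripe bias moves the domain mean, and a
mean-preserving filter cannot restore it; the residual error after
correction is dominated by that offset.

Albedo artifacts (bright, seasonally varying surfaces such as salt flats
misread as cloud) are flagged where max monthly albedo > 0.5 AND
intra-annual albedo SD > 0.15 (both configurable; no canonical values
exist) and replaced by inverse-distance-weighted (power 2) means of
unflagged neighbors within 10 cells; cells without donors stay masked.

## Station validation

Ground observers report the fraction of visible sky covered, which
samples a far larger area than one grid cell; gridded CF is therefore
averaged over a 16-km-radius great-circle footprint (spherical Earth,
R = 6371 km) before comparison, and cloud *amount* is compared to cloud
*frequency* directly, without a calibration transfer.  Archive filters:
`modis_era` keeps stations with ≥ 20 observations in every month of
every window year; `full_record` keeps stations with ≥ 20 qualifying
years (all 12 months ≥ 20 observations).  Validation regressions are
unweighted OLS of station amount on footprint CF per month and per
season (DJF/MAM/JJA/SON, December belonging to the following winter),
reporting n, R², RMSE, slope, intercept.  Residuals are summarized by
latitude band and by the modal land-cover class within the footprint
(ties to the lower class id).

## Presence-only model (IWLR)

The presence-only model is a logistic regression with weight 1 on the
presence records and weight W (default 10³) on a uniform background
sample (default 10 000 points).  As W → ∞ the slope estimates converge
to the MLE of an inhomogeneous Poisson point process with
log λ(s) = x(s)'β, which is also the MaxEnt estimand; the tests verify
< 1% slope movement between W = 10³ and 10⁵ and 3-decimal agreement with
a directly maximized discretized point-process likelihood.  Fitting is
Newton/IRLS to gradient max-norm 10⁻⁸ with a separation guard (|coef|
> 50 aborts).  The formula grammar covers the model families used for
habitat delineation: linear terms, `I(x^2)` squares, categorical factors
(reference level = first alphabetically), and factor-by-continuous
interactions.  Model comparison uses the weighted log-likelihood with
k = number of coefficients; BIC's effective n is the number of presences
(the information-bearing unit in a point process — a documented
convention, since no universal choice exists).  AUC treats the
background as pseudo-absences and is computed by the rank statistic; COR
is the point-biserial correlation between the presence indicator and the
fitted value.  Prediction maps are relative occurrence rates:
exp(x'β) without the intercept, rescaled to a maximum of 1.

Wald-interval calibration is demonstrated at ~1000 presences over 2500
background cells, where coverage of the 95% interval is ≈ 0.95 across
seeds.  At a few hundred presences the model-based SEs of a strongly
skewed intensity (slope 1.5 on a standard-normal covariate) are visibly
anti-conservative; this is a small-sample property of the estimand, not
of the implementation (the SEs agree with an independent Poisson GLM to
six figures), and is the reason the calibration experiment is sized as
it is.

## Occupancy model (ZIB)

Latent suitability zᵢ ~ Bernoulli(θᵢ), logit θᵢ = xᵢ'β; detections
yᵢ ~ Binomial(nᵢ, zᵢ·δ) with a constant per-survey detection
probability δ (logit δ = γ, intercept-only — detection covariates are
out of scope).  Priors are independent Normal(0, 10⁶) on β and γ.
Checklist records enter as cell-level counts after effort filtering:
complete checklists with duration < 4 h (strict) and distance ≤ 5 km or
area ≤ 500 ha (a missing field passes if the other bound holds).

The sampler is Metropolis-within-Gibbs: z from its exact full
conditional (z = 1 when y > 0, else Bernoulli with odds
θ(1−δ)ⁿ : (1−θ)); β jointly and γ by random-walk Metropolis with
proposal scales adapted toward 20–50% acceptance during burn-in only
(diminishing adaptation, frozen afterwards so the kept chain is
Markov).  Covariates are standardized internally; draws can be mapped
back to the raw scale.  Defaults are 3 chains × 10 000 burn-in +
50 000 iterations thinned by 50; the test suite runs scaled-down chains
(3 × 2 000 + 8 000, thin 10) at ~2 000 cells, which the coverage
experiments show is already well-calibrated.  Cells with nᵢ = 0 are
excluded from the likelihood but included in prediction and range size.

Per-draw deviance uses the z-marginalized likelihood
Lᵢ = θᵢ·Binom(yᵢ|nᵢ,δ) + (1−θᵢ)·1[yᵢ=0]; DIC = D̄ + p_D with
p_D = D̄ − D(posterior mean).  A negative p_D — a known DIC pathology
for mixture likelihoods — is logged, not raised.  Convergence is the
Brooks–Gelman multivariate PSRF, (n−1)/n + ((m+1)/m)·λ₁(W⁻¹B/n).
Range size is the sum of posterior-mean cell probabilities (no
threshold): two cells at 50% count as one expected cell.

## Spatial statistics

Moran's I and Geary's C with explicit sparse symmetric weights: binary
rook/queen grid contiguity or great-circle distance bands.  The weight
choice is reported in the output because the statistics are
weight-relative; queen contiguity on the prediction grid is the default
for table-style reporting.  Correlograms evaluate Moran's I per distance
bin with binary membership weights; default bins are 10 equal-width bins
to half the domain diameter.  Null expectations used in tests:
E[I] = −1/(N−1) and E[C] = 1 under random permutation.

## What the synthetic experiments show — and what they do not

The generators draw daily flags as independent Bernoulli fields from
smooth monthly probability surfaces, stations as noisy footprint means,
presences as a thinned Poisson process, and checklists from the ZIB law
itself, all from named substreams of one root seed (byte-identical
reruns).  Passing tests therefore demonstrate *correct recovery under
the stated laws*: estimator code, normalizations, masks, and tie-breaks.
They do not demonstrate robustness to what real data add — temporally
autocorrelated cloudiness, observer-dependent station bias, spatially
biased presence sampling, overdispersed detection — and the
accept/reject behavior of the archive filters is only as good as the
filter thresholds themselves.

Numerical conventions collected in one place: sample SDs everywhere;
frequencies in percent in all public outputs; any derived cell is
masked when any required input at that cell is masked; the
concentration tie-break favors the earlier month; the hotspot quantiles
are global; OLS validation is unweighted; the 3·SE Monte-Carlo bands in
tests are applied per test statistic, with fraction-within-band checks
(not per-cell maxima) when tens of thousands of cells are tested at
once, since the maximum of that many draws predictably exceeds 3·SE.
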