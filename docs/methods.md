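# Methods

## Data model

The pipeline operates on a sites × samples pair of integer matrices
(methylated reads M, total reads T) with 0-based half-open genomic
coordinates. Bismark-style coverage files (1-based inclusive) are converted
at a single point in `methaging.io`; the conversion is an involution, tested
as such. A total of zero marks an unobserved entry. The methylation fraction
(OMF) is M/T.

## Site selection

Filters run in the order: common-site intersection → per-age-group coverage
rule → outlier masking and SNP exclusion → strand aggregation → shorth
variance filter. The shorth filter runs last so that variance is measured on
the final CpG-level fractions. The coverage rule excludes a site if, within
any age group **or within the pooled treated set**, the proportion of
samples with coverage < 10 strictly exceeds 50%; both thresholds are
arguments. Outlier masking removes entries above the per-sample 0.999
coverage quantile (linear-interpolation quantile); because masking can break
the common-site property, the intersection is re-applied afterwards. The
shorth threshold is the mean of the shortest window of ⌈n/2⌉ consecutive
sorted site SDs, ties resolved to the lower-mean window, making the
estimator deterministic; sites with SD ≥ threshold are kept.

## Per-site age regression and model selection

Significance is decided on the untransformed linear model
fraction ~ age (+ confounders) with a two-sided t-test on the age
coefficient and Benjamini–Hochberg adjustment across sites (α = 0.05
default). The transformation grid is evaluated only for significant sites
and only characterizes their dynamics; deciding significance per best-AIC
model would add a selection bias.

The grid fits g(age) ~ mᵖ for g ∈ {identity, ln} and
p ∈ {−13, −5, −1, 1, 5, 13} (fractions clipped to [1e−4, 1−1e−4] before
negative powers). AIC = n·ln(RSS/n) + 2k, plus 2·Σⱼ ln(ageⱼ) for the ln-age
response — the Jacobian term that makes likelihoods of differently
transformed responses comparable (`naive_aic=True` disables it). Any model
within ΔAIC < 2 of the plain line (age, 1) resolves to the line. Best models
map to dynamics classes: age response with p ≤ −5 → late-accelerating;
ln-age response → early-adulthood change; everything else (including the
mild powers −1, 5, 13) → linear.

**Identifiability boundary.** The grid regresses (a transform of) age on a
noisy predictor mᵖ. Noise on m is amplified by |p|·m^(p−1), so for strongly
negative powers the predictor's noise overwhelms its signal once the
fraction-scale noise SD exceeds a few ×10⁻³: in simulations the generating
(age, −13) family is recovered for ≥ 94% of late-acceleration trajectories
at noise SD 0.002 but essentially never at SD 0.02, where the milder
(age, −1) model wins on predictive RSS (classical errors-in-variables
attenuation). At realistic RRBS coverage (~30×, binomial noise SD ≈ 0.05–0.09)
per-site dynamics labels therefore default to "linear" even for truly
accelerating sites; the late-acceleration label is reliable only for
low-noise inputs such as group-mean trajectories or very deep coverage.

## Shannon entropy

H = (1/(N·ln ½)) · Σᵢ [mᵢ ln mᵢ + (1−mᵢ) ln(1−mᵢ)] per sample over a site
set, computed with x·log(x) carried to its continuity limit of 0 at the
boundaries (scipy's `xlogy`), which preserves the exact symmetry
H(m) = H(1−m) for any fraction vector including exact 0/1 entries. The
natural log is used; the base cancels under the normalization. The
entropy–age trajectory reuses the site-level linear fit and transformation
grid. Permutation comparisons between site sets relabel **sites** across the
union (the compared unit is the site set); the statistic is the mean over
samples of H(A) − H(B), and p = (1 + #{|null| ≥ |obs|})/(1 + n_perm).

## Entropy normalization

A one-dimensional penalized B-spline GAM (statsmodels GLMGam, basis
dimension 20, cubic) of slope against intercept is fitted on the significant
sites. The smoothing penalty is selected by generalized cross-validation
over a fixed log-spaced grid 10⁻⁴…10⁶ — deterministic and cheap; inputs
beyond 50,000 points are thinned by order statistics before fitting. The
fitted smooth is evaluated on a 256-point grid and extended by linear
extrapolation, giving a deterministic expected-slope function of the
intercept, evaluated for **all** sites. RMF = OMF − age·(expected slope),
not clipped; the RMF is refit with the full age-regression machinery and
each site is classified from the (OMF significant, RMF significant) pattern,
with both-significant sites split by sign and magnitude of the observed
versus expected slope.

**Calibration.** On null cohorts whose sites follow their expected slope
exactly plus noise, the RMF raw p < α rate equals α (the BH-adjusted rate is
necessarily below α under a global null, so the raw rate is the calibration
readout). When the slope-vs-intercept law is steep, the expected slope is
evaluated at the *estimated* intercept, whose error anticorrelates with the
site's slope error; this partially cancels the slope noise and deflates the
null rate (measured ~0.02 at α = 0.05 for d slope/d intercept = −0.008).
The procedure is conservative, never anti-conservative.

## Region analysis

Sites are points assigned to interval sets by half-open containment
(intervaltree). Region trends are the mean across member sites of the age
slope of the **z-scored** fraction series, so the statistic counts how many
sites change and in which direction, independent of per-site effect size;
constant sites are excluded, regions with fewer than two usable sites are
skipped with a warning, and the CI is a site-level percentile bootstrap
(1,000 resamples, seeded). Enrichment uses the two-sided Fisher exact test
(2×2 of region membership × direction over all tested sites; the background
is all tested sites), computed by vectorized hypergeometric summation with
the customary 1+1e−7 relative slack on the observed table probability, and
BH-adjusted across regions within each direction. CGI sensitivity recomputes
region slopes after cumulative removal of CGI / +shore / +shelf member
sites. Metagene profiles map each site in a gene's ±1-gene-length window to
r ∈ [−1, 2] (0 = TSS, 1 = gene end, strand-mirrored) and smooth the per-age
group mean methylation along r with the same penalized-spline machinery.

## Calorie-restriction decomposition

m = β₀ + β_age·age + β_IS·CR + β_TAT·(age − t₀)·CR (+ confounders), fitted
by OLS per site with a shared design; t₀ is subtracted only inside the
interaction, so β_IS is exactly the model's predicted CR−control difference
at age t₀. The joint CR effect is the 2-df nested F-test against the
age-only model; per-term IS/TAT calls use coefficient t-tests; all three
p-value families are BH-adjusted. Coefficient correlations (Pearson) are
computed on the site selections of interest — aging∩IS, aging∩TAT, IS∩TAT —
with the aging coefficient taken from the control-only regression (the
joint-model β_age is available as an alternative). The endpoint comparison
takes the per-site CR−control mean difference at the oldest shared age and
correlates it with the control-cohort and CR-cohort slopes.

## Synthetic cohorts

The generator emulates an aging RRBS blood cohort: 16 age groups spanning
3–35 months with 9 animals each (~144 control samples), a CR arm of four
groups at 10/16/21/27 months treated from t₀ = 4 months (8 animals each),
10,000 CpGs, coverage ~ NegativeBinomial(mean 30, size 5) floored at one
read, Gaussian latent-fraction jitter of SD 0.02, and a bimodal baseline
(Beta(1,8) / Beta(8,1) modes, 52/48 mix) whose mean sits slightly below 0.5.
Site trajectories come from five families — stable, linear (|slope|
0.005–0.010/month), late-accelerating (the inverse of age = a + b·m⁻¹³
through drawn endpoints, so the generating model is literally the selected
family), early-change (m₀ + d·ln age), and exponential drift toward 0.5 —
mixed 79/4/12/2/3% by deterministic largest-remainder allocation. Gaining
sites start low and losing sites start high, reproducing the observed
coupling between baseline and direction. CR effects are coupled to each
site's lifespan-average slope: IS = +5 month-equivalents (an instantaneous
shift in the direction of aging), TAT = −0.3× the slope (a cumulative
brake); both couplings are choices the source data do not pin down, made
once. All randomness descends from one seed; each site has its own spawned
substream, so a site's counts are independent of which other sites are
generated.

**What the generator does not emulate:** read-level data (no bisulfite
conversion errors, no epipolymorphism), genomic realism beyond evenly spaced
positions on one chromosome, cell-type composition shifts, batch effects,
and spatial correlation between neighboring CpGs. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated noise
model, not robustness to those real-data complications.

## Numerical choices and degenerate inputs

Exact fits (zero residual variance) yield p = 0 for nonzero effects and
p = 1 otherwise rather than NaN. Rank-deficient designs raise an error
naming the collinear columns. Fisher tables with an empty margin report an
undefined odds ratio and p = 1. Correlations on fewer than three sites or on
constant vectors are reported as undefined (NaN) where the operation
tolerates it and raise otherwise. The expected-slope smooth falls back to an
exact least-squares spline when the penalized fit detects perfect
separation, and to a straight line when fewer than five distinct intercepts
exist.

## Problem sizes

Default test and acceptance runs use 10,000 sites × 176 samples for the
study-scale checks, 2,000 sites for calibration nulls, and 200 trajectories
for model-selection checks; the full suite runs in about a minute on one
CPU.

## Known limitations

- Dynamics classification at realistic per-site RRBS noise collapses to
  "linear" (see the identifiability boundary above); group-level or
  deep-coverage data are needed for reliable late/early labels.
- The CR F-test at coverage 30 with 32 treated samples has low per-site
  power for fraction shifts below ~0.05; cohort-level coefficient
  correlations remain informative much earlier than per-site calls.
- The expected-slope normalization is slightly conservative under steep
  slope-vs-intercept laws (see Calibration).
- Confounders are accepted as numeric columns and entered linearly; no
  cell-type deconvolution is performed.
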