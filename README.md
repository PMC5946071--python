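# methaging

Analysis of age-related remodeling of the blood DNA methylome from RRBS
(reduced representation bisulfite sequencing) count data, with a built-in
synthetic-cohort generator so every stage can be validated against known
ground truth.

The package is aimed at epigenomics researchers analyzing per-CpG
methylated/unmethylated read counts across an aging cohort, optionally with a
calorie-restricted (CR) treatment arm. It implements:

- **Site selection** — common-site intersection, a soft per-age-group
  coverage cutoff (exclude a site if more than 50% of samples in any age
  group, or in the CR set, have <10× coverage), high-coverage outlier
  masking, SNP exclusion, CpG strand aggregation, and a *shorth* variance
  filter (drop sites whose fraction SD falls below the mean of the shortest
  interval covering half of all site SDs).
- **Per-site age regression** — OLS of the methylation fraction *m* on age
  (plus optional confounders), Benjamini–Hochberg FDR across sites, and AIC
  selection over a grid of transformed models *g*(age) ~ *m*ᵖ with
  *g* ∈ {identity, ln} and *p* ∈ {−13, −5, −1, 1, 5, 13}, classifying
  significant sites as late-life-accelerating (*p* ≤ −5, the
  age ~ *m*⁻¹³ family), early-adulthood change (ln-age response) or linear.
- **Shannon entropy** — per sample over N sites,
  H = (1/(N·ln ½)) Σᵢ [mᵢ ln mᵢ + (1−mᵢ) ln(1−mᵢ)],
  so H = 1 when all sites are half-methylated and 0 when all are fully
  (un)methylated; entropy–age trajectory fitting reuses the transformation
  grid.
- **Entropy normalization** — a penalized-spline GAM of slope against
  intercept over the significant sites gives each site an *expected slope*;
  the residual methylation fraction RMF = OMF − age·(expected slope) is
  refit, and sites are classified as resisting, following, exceeding,
  lagging, or countering the average entropy trajectory.
- **Region analysis** — assignment of sites to labeled BED intervals (CpG
  islands, shores, shelves, promoters, ...), region trends as the mean
  z-score-scale slope of member sites, Fisher exact enrichment of gain/loss
  sites per region, CGI/shore/shelf removal tiers, and metagene profiles
  along the normalized gene coordinate (0 = TSS, 1 = gene end, extended one
  gene length both ways).
- **CR decomposition** — per site,
  m = β₀ + β_age·age + β_IS·CR + β_TAT·(age−t₀)·CR, where β_IS is the
  instantaneous shift at treatment start t₀ and β_TAT the additional
  per-month rate under treatment (cumulative effect); joint significance by
  a 2-df nested F-test, per-term t-tests, and coefficient-correlation
  analyses between aging, IS and TAT.

## Worked example

Generate a cohort at the default study conditions (16 age groups from 3 to
35 months, 9 animals each; CR arm at 10/16/21/27 months treated from 4
months; 10,000 CpGs at ~30× coverage) and run the chain:

```
methaging simulate --out raw --seed 42
methaging preprocess --coverage-dir raw --samples raw/samples.tsv --out pre
methaging fit-age --matrix pre/matrix.tsv --samples raw/samples.tsv --out fits
methaging entropy --matrix pre/matrix.tsv --samples raw/samples.tsv \
    --site-fits fits/site_fits.tsv --out ent
methaging normalize-entropy --matrix pre/matrix.tsv --samples raw/samples.tsv \
    --site-fits fits/site_fits.tsv --out norm
methaging cr-model --matrix pre/matrix.tsv --samples raw/samples.tsv \
    --site-fits fits/site_fits.tsv --out cr
```

Or from Python:

```python
from methaging import synthio, agefit, crmodel

design = synthio.CohortDesign(seed=1, cr=synthio.CRDesign())
matrix, sheet, truth = synthio.generate_cohort(design)
ctrl = sheet[sheet.group == "control"]
cmat = matrix.subset_samples(ctrl.sample_id.tolist())
fits = agefit.fit_all_sites(cmat, ctrl.age.to_numpy())
print(f"{(fits.q < 0.05).mean():.1%} of sites age-significant")

cr_fit = crmodel.fit_all_cr(matrix.fractions(), sheet.age.to_numpy(),
                            (sheet.group == "CR").to_numpy(), t0=4.0,
                            site_ids=matrix.site_ids())
summary = crmodel.cr_summary(cr_fit, fits)
```

With seed 1 this prints `21.0% of sites age-significant`, close to the ~21%
of truly changing sites the generator plants. On the same cohort the
coefficient correlations over aging-significant sites come out
r(aging, IS) = +0.73 and r(aging, TAT) = −0.71: the initial CR shift points
in the direction of aging while the cumulative effect opposes it — the
structure the generator's coupling encodes (IS = +5 month-equivalents of the
site's aging slope, TAT = −0.3× the slope). The oldest-age CR−control
difference correlates negatively (r = −0.21) with the control aging slope,
the signature of slowed methylome aging under long-term CR.

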