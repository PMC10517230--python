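# Methods

This note documents the statistical procedures implemented in `mnsurvey`,
the choices made where more than one defensible definition exists, and what
the synthetic-fixture experiments do and do not demonstrate.

## Pipeline contract

A run is driven by two tables. The *dataset template* (CSV or Excel; rows =
fields, one column per dataset) names each file, its format, the survey
design variables (strata, cluster, weight), the age variable and unit, the
sex variable and its coding, the population group (PSC, WRA, other), and one
variable/unit row pair per biomarker (`<name>_var`, `<name>_unit`). The
*cutoff template* (one row per rule) carries biomarker, condition label,
group, sex, age range with unit, direction, threshold in the biomarker's SI
unit, an `use_adjusted` flag, and a free-text provenance note. Row labels
and enumerated values are matched case-insensitively with whitespace
stripped; age intervals are closed on both ends; PSC ages are handled in
months, WRA ages in years (each rule carries its unit explicitly, so mixed
tables are unambiguous).

Each dataset is loaded verbatim (CSV, Excel, Stata `.dta`, SAS
`.xpt`/`.sas7bdat`, SPSS `.sav`), checked for every detectable problem
before analysis (missing mapped variables, non-numeric values, non-positive
weights, sex values outside the declared coding, implausible ages —
warnings at 0–59 months for PSC and 10–60 years for WRA, duplicate column
mappings), then standardized to canonical names, converted to SI units, and
zero-recoded. A dataset with fatal errors is skipped with guidance; the run
continues with the remaining datasets and exits nonzero.

### Missing values and zeros

Empty cells, pandas' NA markers, and values failing numeric coercion (after
a reported warning) become missing; all estimation is complete-case per
biomarker, and every reported estimate carries its `n` so denominators are
auditable. Exact zeros in biomarker columns are recoded to 0.0001 so ln is
defined, with a per-row `zero_recoded_<biomarker>` flag. The recode is
applied in *source* units, before SI conversion, so the substituted constant
is exactly 0.0001 regardless of the unit scale; the operation is idempotent
and never touches negative values (those are rejected during checking). No
outlier handling, limit-of-detection imputation, or duplicate-record
detection is performed — data are analyzed as supplied.

### Units

Each biomarker has one canonical SI unit (ferritin µg/L; sTfR mg/L; RBP and
retinol and zinc µmol/L; folate nmol/L; B-12 pmol/L; AGP g/L; CRP mg/L).
Conversions are multiplicative factors derived from molar masses (retinol
286.45, zinc 65.38, B-12 1355.37, folate 441.40 g/mol) and metric prefixes,
e.g. µg/dL → µmol/L is ×10/M. Every shipped factor satisfies
factor × M × prefix-ratio = 1 exactly by construction, and a unit test
asserts this identity entry by entry. Unknown (biomarker, unit) pairs fail
validation before any value is converted — silent unit errors are the
costliest failure mode in this domain. No molar conversion is shipped for
sTfR because sTfR assays are not mutually calibrated; users must register an
assay-specific factor. User biomarkers register their own conversions
(CSV: biomarker, from_unit, to_unit, factor).

## Inflammation adjustment

Acute-phase inflammation raises ferritin and sTfR and depresses retinol,
RBP and zinc, biasing naïve prevalence estimates. The regression-correction
approach models ln X as linear in ln AGP and/or ln CRP and subtracts the
fitted contribution *above a reference level*:

    ln x̃_i = ln x_i − β₁·max(ln AGP_i − ref_AGP, 0) − β₂·max(ln CRP_i − ref_CRP, 0)

* **Slopes** come from unweighted OLS of ln X on the available ln markers
  over complete cases (≥ 10 required, else the biomarker is bypassed with a
  warning). The regression targets the biological ln–ln relationship, not a
  population parameter, so survey weights are deliberately not used; this is
  a documented limitation, not an oversight.
* **References** default to the dataset's own lowest decile of each
  ln marker (numpy's linear-interpolation quantile), the documented fallback
  of the regression-correction literature; external reference values can be
  supplied instead. A marker with fewer than 10 usable values contributes no
  reference.
* **Truncation at the reference** prevents "negative inflammation" from
  inflating values of low-inflammation participants; rows at or below both
  references are numerically unchanged.
* **Scope.** Adjustment runs only for PSC and WRA datasets (the groups for
  which the method is established) and only for {ferritin, sTfR, RBP,
  retinol, zinc} by default; sTfR uses AGP only. Both sets are configurable
  — folate and B-12 can be added where an analyst has established a
  relationship — but widening the default silently would apply a correction
  of unverified validity. Slopes are applied regardless of statistical
  significance (deterministic behavior); an optional significance gate
  (p ≤ 0.05) can zero out non-significant slopes.
* **Degradation.** No AGP and no CRP, a group other than PSC/WRA, too few
  complete cases, or a singular design all degrade to flagged bypasses: the
  pipeline proceeds with unadjusted values and records the reason. Rows
  missing a required inflammation marker keep their unadjusted value and are
  flagged per row.

## Design-based estimation

* **Point estimators.** Hájek ratio mean ŷ = Σwᵢyᵢ/Σwᵢ; geometric mean
  exp(weighted mean of ln y); prevalence 100·(weighted mean of the 0/1
  indicator).
* **Variance.** First-order Taylor linearization with the single-stage
  with-replacement approximation: residuals zᵢ = wᵢ(yᵢ − ŷ) are summed to
  PSU totals; the variance is Σ_h n_h/(n_h−1) Σ_a (z_ha − z̄_h)² over strata
  h, divided by (Σwᵢ)². This is the standard production-survey default and
  reduces exactly to sd/√n under unit weights, one stratum, and row-level
  PSUs.
* **Confidence intervals.** Student t with design degrees of freedom
  #PSUs − #strata (SRS fallback n − 1). Prevalence CIs are Wald on the
  linearized SE, truncated to [0, 100]; the geometric-mean CI is the
  exponentiated ln-scale CI, with the natural-scale SE by the delta method
  (estimate × ln-scale SE).
* **Quantiles.** The estimate inverts the weighted empirical CDF: the first
  distinct value whose cumulative weight share strictly exceeds p; when p
  falls exactly on a step boundary the midpoint of the two adjacent distinct
  values is returned (the average of the left- and right-continuous
  inverses). Under equal weights this is the Hyndman–Fan type 2 sample
  quantile, so the median of {1,2,3,4} is 2.5 while a weighted mass crossing
  returns the carrying value. Quantile SEs are not reported.
* **Lonely PSUs.** A stratum with a single PSU makes its variance
  contribution undefined; the default is a hard error with guidance, with an
  opt-in `center` mode that scores the lonely PSU total against the grand
  mean. When *every* stratum is lonely (df ≤ 0) the SE is omitted with a
  warning rather than fabricated. Weight-scale invariance holds throughout:
  multiplying all weights by a constant changes no estimate and no SE.

## Classification and reporting

Rules match on population group (PSC/WRA rules match the dataset's declared
group; male/female rules match participant sex; `any` matches all), sex, and
age within the closed interval, after unit conversion. Comparisons are
strict (`<` / `>`): a participant exactly at the threshold is not deficient.
The value compared is the adjusted one when the rule requests it and
adjustment ran, otherwise the unadjusted one. Participants with missing
values or no matching rule receive missing calls and drop out of the
prevalence denominator.

When adjustment ran, every distribution statistic is reported twice
(`adjusted` flag false/true) so the inflammation impact is visible in a
single run. Outputs are deterministic CSVs (no timestamps, fixed column
order, full-precision floats plus a 2-decimal display column); repeated runs
on identical inputs are byte-identical.

## Synthetic fixtures and what they show

The generator emulates a stratified one-stage cluster survey:

    ln X_i = µ + b_AGP·ln AGP_i + b_CRP·ln CRP_i + u_c(i) + ε_i

with ln AGP ~ N(−0.1, 0.35²) (geometric mean 0.9 g/L, ≈ 39% above 1 g/L),
ln CRP ~ N(0, 1.2²) (geometric mean 1 mg/L), a cluster effect
u_c ~ N(0, 0.15²), ε ~ N(0, σ²), and defaults of µ = ln 30, σ = 0.7,
b_AGP = 0.8, b_CRP = 0.2 for ferritin (cutoff 12 µg/L) and µ = 0, σ = 0.35,
b_AGP = −0.25, b_CRP = −0.10 for retinol (written in µg/dL so the SI
conversion path is exercised; cutoff 0.7 µmol/L). Weights depend on the
stratum only, and the biomarker distribution does not vary by stratum, so
design-based estimators remain unbiased and hand-checkable. All randomness
flows from one seeded PCG64 generator; identical spec + seed give identical
files on any platform. Generated values are quantized to 15 significant
decimal digits — the most xlsx can carry — so one fixture serialized to all
five formats loads back bit-identically.

Under this generating model the estimand of the regression correction is the
concentration at the *reference* inflammation level, not at zero
ln-inflammation. The truth sidecar therefore records both: `*_free`
(b-terms removed entirely) and `*_ref` (standardized to the analytic
population 10th percentile of each ln marker, µ_marker − 1.2816·σ_marker),
and true deficiency status is defined on `*_ref`, whose analytic probability
is the lognormal CDF at the cutoff. The prevalence-recovery experiment —
adjusted prevalence closer to the sidecar truth than unadjusted in ≥ 95% of
200 replicates of n = 2000 — is thus a check of the method, not of a lucky
parameter choice.

What the fixtures do **not** emulate: real LoD censoring, outliers,
assay drift, inflammation markers with cluster-level correlation,
non-lognormal biomarker shapes, or informative weights within strata.
Passing tests demonstrate the pipeline's internal correctness and the
adjustment's behavior under its own model assumptions, not field validity
for any particular survey.

## Numerical and experimental choices

* Reference deciles use numpy's default (linear interpolation) quantile;
  the choice is visible in tests and matters only at small n.
* The CI-coverage experiment uses 4 strata × 24 PSUs × 15 rows
  (ICC ≈ 0.155). With ~32 PSUs the t interval for the *mean* of a
  lognormal outcome covers only ≈ 93% — the familiar skewness effect of
  Wald/t intervals at small PSU counts, not a variance-estimator defect
  (the ln-scale mean covers ≈ 95.6% under the identical design). Users
  analyzing strongly skewed biomarkers with few PSUs should prefer the
  geometric mean's ln-scale interval.
* SAS XPORT files are written with exact IEEE→IBM hexadecimal float
  conversion (56-bit fractions hold any double); magnitudes below the
  smallest IBM normal (16⁻⁶⁵) flush to zero. pandas' XPORT decoder renders
  the IBM zero word as ≈ 5·10⁻⁷⁹, so the SAS loading path restores exact
  zeros below 10⁻⁷⁵ — far beneath any physical concentration.
* SPSS support covers uncompressed `.sav` files with numeric and short
  (≤ 8 byte) string variables, written and read by the package itself; it
  is validated by byte-level header checks and round-trips, not against
  SPSS binaries.

## Known limitations

* The adjustment regression ignores survey design (documented above) and
  fits slopes per dataset; very small surveys yield noisy corrections.
* Internal reference deciles make adjusted values across surveys not
  strictly comparable unless external references are supplied.
* Replicate-weight variance methods (BRR, jackknife), finite-population
  corrections, multi-stage designs beyond one stage, post-stratification
  and Woodruff quantile CIs are out of scope.
* Cutoffs that depend on fasting status or time of day (serum zinc) must be
  handled by subsetting and supplying separate cutoff files.
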