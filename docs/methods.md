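# Methods

## Data model

A cohort is a table of subjects with disease status (case/control), sex
coded `gen` ∈ {1=male, 2=female}, age in years, height/weight/BMI, and
a risk-allele dosage ∈ {0, 1, 2} at each of three loci (the *ASPN*
D-repeat risk allele, *GDF5* rs143383, *DVWA* rs7639618). The
multiallelic *ASPN* microsatellite is collapsed to the dosage of its
named risk allele so all three loci share the homozygote / heterozygote
/ other layout. The genetic score is the dosage sum *n* ∈ [0, 6].
Readers accept comma- or tab-delimited text, map `M`/`F` onto the
numeric sex code, and reject rows violating the invariants (dosage
outside {0,1,2}, BMI inconsistent with height/weight beyond 0.5 kg/m²,
duplicated ids) with row-level diagnostics. Missing height/weight are
tolerated when BMI is present; all model fits are complete-case.

## Association statistics

**Allelic odds ratios.** Each group's genotypes expand to 2N alleles
(risk count 2·homo + hetero); the OR is the 2×2 cross-product and the
95% CI is Woolf's log-normal interval, log OR ± 1.96·√(Σ 1/cell).
Treating the 2N alleles as independent is the standard allelic
approximation for unrelated subjects. When a cell is zero, 0.5 is added
to all four cells (Haldane-Anscombe) and the result's method label says
so. P-values are the allelic 2×2 Pearson χ² (two-sided).

**Trend test.** The Cochran-Armitage statistic with scores 0..6,
χ² = N·(N·Σsᵢrᵢ − R·Σsᵢnᵢ)² / [R(N−R)(N·Σsᵢ²nᵢ − (Σsᵢnᵢ)²)], referred
to χ²(1). It is invariant under affine score changes. A fixed-margin
permutation reference (multivariate hypergeometric redistribution of
case status) is provided as an independent check of the asymptotic
p-value.

**Grouped fits.** The genetic-only logistic model depends on the data
only through the per-count case/control totals, so it is fitted on the
grouped binomial counts (identical MLE to the subject-level fit; a
property test asserts this sufficiency). On the published histogram the
fit gives slope 0.205 (per-allele OR 1.23) and intercept −0.856. The
intercept's sign is reported as fitted: the positive sign that
circulates with this formula cannot reproduce the histogram it
summarizes (it would imply ~70% case probability for zero-allele
subjects against the observed ~40%), so we treat it as a typographical
slip and do not force a match. Quasi-separated grouped fits are
returned with a `separation-flagged` method label rather than silently.

## Prediction models and evaluation

`MODEL_I` (*n*), `MODEL_II` (*n*, *gen*, age, BMI) and `MODEL_III`
(*gen*, age, BMI) are plain maximum-likelihood logistic regressions
(statsmodels). Intercepts absorb the case-control sampling fractions
and are never interpreted as prevalence. Stepwise selection enters
terms on likelihood-ratio p < 0.05 and removes on Wald p > 0.10
(conventional defaults; ties broken by candidate order, so selection is
deterministic). Nested models are compared by 2·Δlog-likelihood against
χ² with df = added terms.

AUC uses the Mann-Whitney estimator via midranks — exactly
P(case > control) + ½·P(tie) — which equals the trapezoidal area of the
threshold-sweep ROC. With only seven score levels roughly 28% of
case-control pairs are tied, so the half-credit convention is load-
bearing: the grouped-count AUC is computed in exact integer arithmetic
(on the published histogram, 632790/1142925 ≈ 0.554). Cross-validation
uses stratified k-fold (default k = 10; the source analysis does not
state its fold count) with seeded shuffling.

## Attributable risk

For multi-level exposures the case-control PAR is Bruzzi's estimator
PAR = 1 − Σⱼ ρⱼ/ORⱼ, with ρⱼ the case fraction in stratum j and ORⱼ
from a single logistic fit on stratum indicators plus any adjustment
covariates (reference stratum OR ≡ 1). Risk-allele strata default to
{0-1, 2, 3, 4, 5-6} with 0-1 as reference, following the histogram's
low zero-count occupancy. BMI bands are <25 normal/underweight,
[25, 30) overweight, ≥30 obese; the source banding leaves 25-26
unassigned, and we close the gap with the half-open [25, 30) interval.
Confidence intervals come from a subject-level bootstrap stratified by
group (seeded; default 1,000 replicates), since no analytic CI is
published for this design.

## Demographic standardization

Clinic-recruited controls need not match the age-sex structure of the
screening population. The standardization simulation restricts to
subjects at or above a minimum age (default 60), draws per replicate a
control subgroup matched to a reference population — either per-sex
counts only, or full sex×age-stratum composition against a user-
supplied demographic table, with stratum quotas by largest-remainder
rounding and sampling without replacement — plus a random case
subgroup, refits the model, and records the in-replicate AUC and
variance shares. Replicate RNG streams are spawned from the master seed
by counter, so results are reproducible and a failed replicate does not
shift later ones; more than 5% failures aborts the run. The packaged
demographic table is a clearly-labelled synthetic approximation of a
mid-2000s elderly Japanese age structure for demos and tests; real
analyses should supply an actual reference table. Default age strata
are 5-year bins from 60 (no binning is prescribed by the source
analysis).

**Variance decomposition.** Writing the fitted linear predictor as
η = G + E with G = β_n·n and E the clinical terms, the package reports
Var(G), Var(E), Cov(G, E) and both shares Var(G)/Var(η) and
Var(E)/Var(η) over the analysis subjects, labelled explicitly; the
"genetic share" is Var(G)/Var(η). η is the liability-scale proxy. Under
independent generation of genotypes and clinical covariates Cov(G, E)
is expected to vanish, and the decomposition check enforces
Var(η) = Var(G) + Var(E) + 2·Cov(G, E) to 1e-9.

## Synthetic cohort generator

The generator emulates the study design, not any richer biology. A
source population is simulated — sex ~ Bernoulli (female fraction
0.754, the control group's), age truncated-normal (mean 70, sd 9,
bounded [40, 95]; the study's patients were all over 40, and 70/9 is a
between-group compromise since only per-group means are published),
per-sex height and weight normals from the control-group summary with
weight sharing a latent factor with height (correlation 0.4, a
generator choice so BMI has realistic spread), BMI computed from
height/weight, and per-locus dosages Binomial(2, q) at the control
allele frequencies (0.062, 0.747, 0.569) independently across loci
(the pairwise independence tests found no dependence). Disease
probability is logistic(−8.395 + 0.200·n + 0.302·gen + 0.045·age +
0.162·BMI), the published combined-model coefficients; an
`extra_linear_term` hook accepts additional terms (e.g. a gene-gene
product) for power studies. Exactly n_case cases and n_control
controls (defaults 933/1,225) are then sampled without replacement
from the realized population, whose size is chosen by a pilot-estimated
prevalence so both groups have a 1.5× expected margin; an unattainable
request raises a generation error rather than silently re-weighting.

Because sampling is retrospective, fitted intercepts are offset by the
log ratio of case/control sampling fractions; slope coefficients are
the recoverable quantities, and the parameter-recovery test therefore
checks Wald-CI coverage of the four slope coefficients (observed ~94%
over 200 study-size replicates). What the generator does **not**
emulate: linkage disequilibrium, population stratification,
gene-environment interaction, age-by-sex structure within groups
(unless a demographic table is supplied), misdiagnosis, or any
covariate measurement error. Passing tests therefore certify the
statistical machinery under the stated design, not robustness of the
published conclusions to those real-data complications.

## Numerical choices and edge cases

- Logistic fits: statsmodels Newton MLE, max 200 iterations;
  non-convergence raises a typed error carrying the iteration trace.
- Zero cells in 2×2 tables: Haldane-Anscombe 0.5 on all cells, flagged.
- Empty rows/columns in 3×3 dosage tables: collapsed with a warning and
  reduced df; expected counts below 5 warn.
- Interaction coding: product of dosages (1 df) by default — the
  simplest multiplicative-interaction term — with a categorical 4-df
  indicator coding behind a flag; Bonferroni family sizes are always
  explicit arguments (3 for the gene pairs).
- AUC never returns NaN on valid input; single-class inputs raise a
  degenerate-input error.
- Exact AUC underflow/overflow cannot occur (integer arithmetic);
  Wald CI exponentials are clamped at 1e-300 under extreme separation.
- Seeds: every stochastic routine takes an explicit integer seed;
  derived streams use `SeedSequence.spawn`, so identical seeds give
  byte-identical outputs.

## Problem sizes in the shipped runs

The analysis drivers and test suite run at the study's group sizes
(933/1,225) for deterministic statistics and parameter recovery. The
replicate-heavy simulations use: 200 study-size replicates for
coverage; 1,000 null replicates at 300 cases / 300 controls for the
interaction-LRT type-I error (at a few hundred subjects per group the
asymptotic LRT is already calibrated, while n ≈ 150 per group shows
mild inflation); 100-300 replicates for the standardization arms; and
reduced bootstrap depths (120-300) in tests and drivers versus the
1,000-replicate default in the library.

## Known limitations

- The published covariate-adjusted PARs, combined-model AUCs, and
  interaction p-values depend on the unpublished individual-level data;
  this package reproduces the aggregate-table statistics exactly and
  covers the rest with property-based checks on synthetic cohorts.
- The allelic OR treats alleles as independent within subjects; a
  genotype-level (e.g. trend-based) OR would differ slightly under
  Hardy-Weinberg departures.
- Bruzzi PAR assumes the stratum ORs approximate relative risks
  (rare-ish disease) and unconfounded stratum membership given the
  adjustment covariates.
- The liability-scale shares use the logistic linear predictor as the
  liability proxy; they are not twin-study heritabilities.
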