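# Methods

## Model and procedure

`repaudit` treats each demographic category as a categorical probability
mass function and measures the similarity of two populations with the
Jensen–Shannon distance (JSD), the square root of the Jensen–Shannon
divergence built from Kullback–Leibler divergences against the equal
mixture M = (S+T)/2. The pipeline is:

1. **Read** patient-level rows (one per patient-event) and reference
   count tables from UTF-8 CSV with a mandatory header; dates are
   ISO-8601 only, so day/month ambiguity cannot arise. Raw demographic
   strings are preserved verbatim at read time.
2. **Deduplicate** to unique patients at the *index event*: the record
   with the earliest ingestion date wins, ties broken by input order
   (deterministic, and the collision count is logged).
3. **Harmonize** raw values into canonical bins: case-insensitive
   vocabulary maps for sex/race/ethnicity, half-open age bins, and the
   OMB combination (Hispanic as one group, non-Hispanic by race).
4. **Accumulate** cohorts at each ingestion date (all patients with
   batch date ≤ d) and tabulate each category.
5. **Compare** with the JSD: all-patients vs. census snapshot,
   positives vs. cumulative surveillance counts, surveillance vs.
   census, and the signed per-date difference of the first two.

### Assumptions

- The census snapshot is time-invariant across the study window.
- Both the cohort and the surveillance series are cumulative, so the
  correct surveillance comparator for an ingestion date is the nearest
  surveillance entry at or before it (gaps are logged). Incident
  (per-month) comparisons are deliberately out of scope.
- Patients with unknown disease status count in all-patients
  tabulations but never in positive-only ones.
- Surveillance counts are taken as given; they are not deduplicated
  (case counts need not be unique patients), a documented limitation of
  that source rather than something the audit corrects.

## Divergence conventions

- **Log base**: 2 by default, because the [0, 1] bounds of DJS/JSD hold
  in base 2 and make the scale interpretable; natural log is available
  and every result records the base used.
- **Support policy**: `union` by default — bins with zero mass in *both*
  distributions are dropped and 0·log 0 = 0 elsewhere. This is the
  convention under which two disjoint distributions attain JSD exactly
  1. The alternative `shared` policy keeps only bins non-zero in both
  groups (an occasionally used stricter reading), with
  `renormalize_after_exclusion` off by default since renormalization is
  a separate modelling choice; disjoint supports under `shared` raise
  rather than silently returning something. Results carry
  `bins_used`/`bins_excluded` so the convention is always visible.
- Inside `js_divergence` the mixture M is formed after alignment, so
  M(x) > 0 wherever S(x) > 0 or T(x) > 0 and the KL terms are finite by
  construction; the standalone `kl_divergence` raises an explicit
  infinite-divergence error when T(x) = 0 under S(x) > 0.
- **Numerics**: masses are counts divided by totals in double precision;
  KL terms use `scipy.special.rel_entr`; a max(·, 0) guard absorbs
  rounding at the 1e-16 level before the square root. Identity checks in
  tests use 1e-12, comfortable for sums over at most dozens of bins.

## Harmonization parameters

- **Age bins**: 10-year half-open bins 0–9 … 70–79 plus 80+ (the common
  case-surveillance convention), configurable via `age_bin_edges`;
  comparability requires cohort and references to share bins, so the
  resolved edges are echoed in every run's metadata.
- **Missing values** (`missing_policy`): `retain_as_bin` (default) keeps
  "Not Reported" as a first-class bin so missingness differences between
  sources show up in the JSD, which is exactly what an audit should
  surface; `drop` excludes the record from that category's tabulation;
  `impute_non_hispanic` (ethnicity and the combined category only)
  implements the deterministic assumption sometimes applied to
  surveillance data that unreported ethnicity is non-Hispanic. No
  probabilistic race imputation is offered.
- **Vocabularies**: minimal OMB-consistent defaults — sex {Male, Female,
  Other}, ethnicity {Hispanic, Non-Hispanic}, race {White, Black, Asian,
  American Indian or Alaska Native, Native Hawaiian or Other Pacific
  Islander, Other} — plus "Not Reported"; all remappable through the
  policy YAML, and unmapped non-empty values fall into "Not Reported"
  with a warning tally rather than failing a run.

## Synthetic data generator

The generator emulates the *shapes* of a real audit's inputs with known
ground truth:

- patient records whose demographics are drawn independently per
  category from configurable marginals (defaults are
  2020-decennial-style: e.g. sex 49.3/50.7, race 61.6 % White / 12.4 %
  Black / 6.0 % Asian / 18.7 % Other, ethnicity 18.7 % Hispanic, a
  realistic age pyramid), masked to "Not Reported" at per-category
  rates *after* drawing, so the truth stays known for recovery tests;
- cohort-style missingness of 10 % for race and ethnicity, and
  surveillance-style missingness of 35 % (race) / 45 % (ethnicity),
  reflecting the order of missingness seen in public case-surveillance
  data versus curated research cohorts;
- a COVID-positive rate of 0.55 (a cohort assembled around a pandemic
  response skews positive), with optional separate marginals for the
  positive subpopulation;
- accrual over 8 quarterly ingestion dates with equal weights, a
  modelling convenience rather than a claim about any real commons;
- a census snapshot via largest-remainder rounding (counts sum exactly
  to the requested total) and a surveillance series whose per-date
  increments are multinomial draws from the masked truth, making
  cumulative monotonicity hold by construction.

What the generator does **not** model: correlation between demographic
categories (the audit analyzes marginals; the one combination that
matters, race×ethnicity, is produced by the harmonization rule, not a
joint sampler), per-site arrival processes, reporting lags, or
duplicated surveillance cases. Passing tests therefore demonstrate that
the pipeline measures what it claims on data of the right shape and
missingness level — not that any real commons is representative.

The sequestration splitter is a transparent simplification of
production multidimensional stratified sampling: strata are the
cross-product of the chosen categories' harmonized bins, the per-stratum
open quota is round-half-away-from-zero of `open_fraction × size`
(deterministic and symmetric), and membership within a stratum is drawn
by seed. Realized open fractions match the target to within 1/size per
stratum, hence within ± (number of strata) patients overall.

## Problem sizes

Default validation scales, chosen to exercise the statistics at
desk scale: divergence identities on ≤ 1,000 random Dirichlet pairs;
the sequestration contract on 10,000 synthetic patients over sex×race
strata; sampling-convergence (median JSD to truth decreasing over
n ∈ {100, 1,000, 10,000}) across 20 seed replicates; end-to-end audits
on cohorts of a few hundred to a few thousand patients over 8 ingestion
dates.

## Known limitations

- The JSD summarizes a whole category; it does not localize *which*
  subgroup drives dissimilarity (use `ppr` per subgroup alongside).
- No confidence intervals or significance tests are attached to JSD
  series; the audit is descriptive.
- With `retain_as_bin`, differing missingness alone can dominate the
  JSD between otherwise similar populations; that is intentional but
  must be kept in mind when reading the series (the per-category
  Not-Reported fractions are logged and written to the run metadata).
- Alternative distribution distances (Hellinger, matching-based
  measures) are out of scope.
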