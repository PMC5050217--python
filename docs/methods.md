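# Methods

## Cohort definition and eligibility

The analysis population is adults (age ≥ 16 years) with severe burns
(the generator's TBSA support starts at 20%), a non-electrical etiology,
an early plasma draw (≤ 48 h after injury, injury-relative — not
admission-relative), at least one ICU day, and a first recorded
infection no sooner than 24 h after the blood draw. The last condition
keeps the cytokine measurement predictive of, rather than consequent to,
infection. Both timing comparisons are inclusive at the boundary: a draw
at exactly 48 h and an infection exactly 24 h after the draw are
eligible. Exclusion reasons are enumerated per patient and may overlap,
so exclusion counts do not sum to the number excluded.

The age rule deserves a note: "adult" inclusion (≥ 16) and "pediatric"
exclusion (≤ 16) overlap at exactly 16 years; the package treats age 16
as eligible (inclusion wording wins) and documents the choice here.

All clinical times are relative to injury: hours for admission delay and
blood draw, fractional days for infection onsets (day 0 = injury). The
single conversion constant lives in `_units.py`.

## Episode tabulation

Consecutive infection records often document one ongoing infection. The
waiting-list rule merges them: every placed record waits
`similar_window` days (default 6) for a *similar* later record — equal
infection type, mode, and pathogen — or `dissimilar_window` days
(default 2) otherwise. A candidate record joins the episode of the most
recent record still waiting for it (day ties break to the lowest episode
index); with none waiting it opens a new episode. Design choices the
source description leaves open, all configurable:

- **Anchor renewal.** Every joining record re-arms its episode's window
  from its own day ("each record … on a waiting list" implies all
  records wait, not only episode openers).
- **Inclusive boundary.** A gap exactly equal to the window extends
  ("for 6 days" read as through day +6).
- **Unknown never matches.** An "unknown" pathogen (or type/mode) never
  counts as similar, even to another "unknown" — conservatively forcing
  the 2-day window, since there is no evidence of a shared cause.
- **Similarity as conjunction** over all three fields; the field subset
  is configurable for sensitivity analysis.

Patients with ≥ 3 cumulative episodes are hypersusceptible cases.
An exhaustive pairwise brute-force oracle reproduces the tabulation
exactly on all tested histories of up to 8 records.

## Severity scores

Ryan = (TBSA > 40) + (age > 60) + inhalation, strict inequalities.
ABSI = male(1) + inhalation(1) + full-thickness(1) + age points
(interval (0, 20] → 1, (20, 40] → 2, … unbounded) + TBSA points
([1, 10] → 1, (10, 20] → 2, …; TBSA < 1% → 0, an extension never
exercised by cohorts with ≥ 20% burns). Fractional inputs bucket by
these half-open value intervals, so age 20.5 scores as the 21–40 label.
Baux = TBSA + age; R-Baux adds exactly 17 points for inhalation injury.
ABSI reporting bands: 6–7 moderately severe, 8–9 serious, 10–11 severe,
≥ 12 maximum (below 6 grouped as "low"). APACHEII is always a recorded
input, never computed.

## Biomarker and stratification

The ratio TNF-α/IL-10 (pg/mL over pg/mL) requires positive
concentrations; an IL-10 at or below zero raises an error unless the
caller supplies an assay limit of detection, in which case LOD/2 is
substituted. Z-scores use the sample mean and SD (ddof 1). Mean-split
stratification cuts at ⌊mean⌋ so the strata reproduce printed integer
cutpoints (e.g. TBSA ≤ 41 vs ≥ 42 around a mean of 41.6); quartile
stratification uses linear-interpolation quartiles with ties to the
lower bin. Both SD and SE (= SD/√n) are emitted; plots conventionally
use SE.

## Statistics

Two-group means: pooled-variance t-test, df = n₁ + n₂ − 2, two-tailed,
in raw-sample and summary (mean/SD/n) forms that agree exactly when the
summaries come from the raw data. Medians: Mann–Whitney — exact
enumeration when both groups have ≤ 8 observations and no ties, else
the tie-corrected normal approximation with continuity correction (the
crossover is a package convention; both variants are callable).
Proportions: Fisher's exact test; a zero margin returns p = 1.
Multi-category panels: one-way ANOVA with Dunnett's two-sided
comparisons against the first (least severe) category, evaluated via
the equicorrelated multivariate-t distribution (scipy's randomized-QMC
integrator, seeded for reproducibility; an independent Monte-Carlo
oracle in the test suite agrees to ±0.02). Binomial intervals: Wilson
score with continuity correction, clamped to [0, 1]; the corrected
interval always contains the point estimate and strictly widens the
uncorrected Wilson interval away from the boundary.

## Predictive models

Nine models: each of {ratio, TBSA, APACHEII, Baux, R-Baux} alone, plus
the ratio combined with each clinical score. Fits use Firth's penalized
likelihood ℓ(β) + ½ log det I(β): Newton iteration on the
hat-value-modified score Σᵢ(yᵢ − πᵢ + hᵢ(½ − πᵢ))xᵢ with step-halving,
stopping when max |score| < 1e-6 (default) or 50 iterations; SEs from
the inverse penalized information. The penalty keeps estimates finite
under complete separation and equals adding ½ to each cell in the
intercept-only case (β₀ = logit((k+½)/(n+1)), used as a closed-form
test). Near-flat likelihoods from very small datasets may need more
iterations; both knobs are exposed.

Subjects are scored by fitted case probability, so protective
predictors (the ratio: lower = higher risk) need no manual sign flip;
for a single predictor the fitted monotone transform leaves the AUROC
of the raw variable unchanged (exact, tested). AUROC is the
Mann–Whitney pairwise estimator with ties counted ½. Its 95% CI is a
stratified percentile bootstrap — cases and non-cases resampled
independently, 10,000 replicates by default, seeded. Reported AUROCs
are **apparent (in-sample)** performance: no cross-validation, matching
the analysis this package reproduces. The operating point maximizes
the Youden index (ties to higher sensitivity; closest-to-top-left is
available), with Wilson-CC intervals on sensitivity and specificity.
Because the fit maximizes penalized likelihood rather than AUROC, a
two-predictor model's in-sample AUROC can fall slightly (observed up to
~0.05) below a nested single predictor's.

## Synthetic cohort generator

The generator emulates the published cohort structure: two groups
(default 17 + 17) defined by episode count.

- **Ratios**: per-group log-normal, moment-matched via
  μ = ln m − σ²/2, σ² = ln(1 + (s/m)²) to non-case 0.200 ± 0.154 and
  case 0.067 ± 0.072. Log-normality is a modelling choice (positive,
  right-skewed) — only mean ± SD are published.
- **Concentrations**: IL-10 log-normal (mean 40, SD 40 pg/mL — a
  realism choice; absolute levels are not published), TNF-α emitted as
  ratio × IL-10, so downstream code computes the ratio itself.
- **Severity coupling**: a Gaussian copula ties the ratio's normal
  score to TBSA and APACHEII within each group (loading −0.5 by
  default), planting the inverse ratio–severity correlation that the
  stratified comparisons exhibit while leaving every marginal exactly
  as configured (log-normal ratio; truncated normals via the copula's
  probability transform).
- **Truncated normals**: TBSA per group (31.9 ± 11.2 / 51.2 ± 20.0 on
  [20, 100]), age 40.6 ± 17.2 on [16, 90], blood draw 19.9 ± 12.0 h on
  (0, 48], admission delay, BMI, APACHEII per group. Truncation shifts
  sample moments from the nominal mean/SD; tests compare against the
  truncated distribution's theoretical moments.
- **Episode counts**: non-case pmf (0.3, 0.4, 0.3) on {0, 1, 2}
  (median 1 [0–2]); case 3 + negative binomial (r = 1.7, mean 4.5),
  giving quartiles 5/6/9 — bracketing the published 6 [5–10].
- **Infection histories** plant exactly the drawn episode count:
  within-cluster records share type/mode/pathogen with gaps inside the
  dissimilar window (they merge under any similarity verdict), clusters
  separated by more than the similar window. Tabulation therefore
  recovers the planted count exactly — a round-trip contract the tests
  exercise. First infection day ~ 5.4 ± 3.0 truncated so every patient
  stays eligible by construction. Pathogens are sampled per episode
  from the published prevalence list, independently — a simplification:
  real within-patient pathogen sets are correlated, so the generator
  understates polymicrobial clustering.

What passing tests on synthetic cohorts do **not** show: the generator
draws most fields independently given group membership (no
age–TBSA–mortality dependence, no missingness, no assay
detection-limit censoring, no calendar/site effects), so passing tests
certify the computational pipeline, not clinical validity on real
patients.

## Problem sizes and numerical conventions

Default test-suite sizes: moment-recovery at 10,000 per group;
stratification sign property over 200 seeds; group-separation property
over 100 seeds; bootstrap-coverage study over 2,000 simulated 17 + 17
cohorts at 10,000 replicates each (coverage ≈ 93%, inside the expected
95 ± 3% band — percentile intervals undercover slightly at these group
sizes). Model-table examples use 500–2,000 bootstrap replicates for
speed; analyses intended to mirror the published tables should keep the
10,000 default. All randomness flows through `numpy.random.Generator`
seeds recorded in outputs; Dunnett integration and bootstrap seeds are
stored alongside results, and a fixed seed reproduces every artifact
byte-identically.

## Known limitations

- Apparent (in-sample) discrimination only; no external validation.
- Episode-rule interpretations (anchor renewal, inclusive boundaries,
  unknown-never-matches) are documented choices where the published
  description is silent; the policy object exposes them.
- The Mann–Whitney exact/asymptotic crossover and the Youden operating
  rule are package conventions; printed operating points could have
  come from a different, unstated rule.
- The generator's independence simplifications above.
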