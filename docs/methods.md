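# Methods

This note documents the models, conventions and numerical choices behind
`hepascore`, and what the synthetic cohorts do and do not emulate.

## Score calculators

**Mortality Risk Score.** An additive point score over eight preoperative
factors with the published thresholds applied exactly as printed: the "≥"
thresholds (age 60 y, INR 1.1, GGT 60 U/l, creatinine 2 mg/dl) are
inclusive, the platelet threshold (< 120/nl) is strict. Points are summed
(maximum 1+1+1+1+2+3+2+5 = 16) and mapped to groups 1, 2A, 2B, 3A, 3B, 4.
The score is defined only for ASA I–IV; ASA V records are rejected with a
domain error rather than extrapolated. Any record missing a scored field
raises a named missing-data error — there is no imputation anywhere in the
package, because silent imputation would corrupt downstream validation
tables.

**labMELD.** The standard laboratory MELD formula with its usual guards:
creatinine capped at 4 mg/dl (and set to 4 mg/dl under dialysis ≥ 2×/week),
every component floored at 1 before the logarithm, and the result clamped
to [6, 40]. Rounding to the nearest integer is **half-up**, the UNOS
convention the score derives from; exact .5 values are vanishingly rare in
practice and the choice is visible in one line of `labmeld`. The floor
makes 10·0.643 = 6.43 → 6 the attainable minimum.

**P-POSSUM.** Item grading follows the original Copeland banding tables,
embedded as a versioned module constant (`POSSUM_BAND_TABLE_VERSION =
"copeland-1991"`). Continuous measurements are first rounded to the
resolution the banding table is printed at (1 mmHg, 0.1 g/dl, …) so the
printed bands tile the plausibility range exactly; values outside the
plausibility range raise a domain error naming the item. Because the
transcription of a 30-year-old table is the least auditable part of any
POSSUM implementation, pre-graded items (1/2/4/8) are accepted everywhere,
so the pipeline never *depends* on the transcription. The
operative-severity item is floored at "major" (grade 4) rather than
overwritten: a hepatectomy cohort contains no sub-major operations, but an
already-graded "major+" (8) case should not be downgraded by the
convention. The mortality equation is the Portsmouth logistic
ln(R/(1−R)) = −9.065 + 0.1692·PS + 0.1550·OS, evaluated with
`scipy.special.expit`; it is strictly increasing in both scores.

## Validation statistics

All stratum statistics reduce to the published 2×2 machinery:

- **Odds ratios** are cross-products (a·d)/(b·c) against the scheme's
  reference stratum (risk-score points 0–1; labMELD 6), with Woolf
  log-normal 95% CIs. A zero cell triggers the Haldane–Anscombe +0.5
  correction and a flag; a zero margin leaves the OR undefined (flagged,
  never dropped).
- **Stratum p-values** are two-sided Wald tests of ln(OR) = 0. For a
  saturated single-indicator logistic model the Wald z equals ln(OR)
  divided by the Woolf SE, so the test is computed in closed form; the unit
  suite verifies the equivalence against the Newton–Raphson fit to 1e-6.
  This estimator reproduces the published labMELD stratum p-values
  (0.2979, 0.0412, 0.2171, 0.0021, < 0.0001) to the printed precision.
- **Fisher's exact test** uses the point-probability two-sided definition
  (sum of hypergeometric probabilities ≤ the observed table's, with a 1e-7
  relative tolerance on the comparison), matching common package defaults;
  it is checked exhaustively against `scipy.stats.fisher_exact` for every
  table with total ≤ 30.
- **Mann-Whitney U** uses midranks. For n·m ≤ 400 the two-sided p is exact:
  the permutation distribution of the rank sum is computed by dynamic
  programming over the doubled midranks (integer-valued, tie-safe),
  equivalent to enumerating all C(n+m, n) assignments but feasible at any
  admissible size. Larger samples use the normal approximation with
  tie-corrected variance and continuity correction.
- **Logistic regression** is plain Newton–Raphson on the log-likelihood
  (convergence when the largest update < 1e-8, cap 100 iterations),
  covariance from the inverse observed information. Complete separation is
  detected (diverging coefficients without convergence) and flagged on the
  result rather than raised; rank-deficient designs are an error.
  `statsmodels` is the independent cross-check in the test suite, never the
  implementation.
- **C-index / ROC.** The C-index is the rank formula
  U/(n₁·n₀) with ties counted half; the ROC staircase places one operating
  point per distinct threshold, so tie blocks become diagonal segments and
  the trapezoidal area equals the rank formula to 1e-12 (cross-checked
  property). AUC standard errors and the default paired comparison use
  DeLong's structural components. The alternative comparison
  (`--roc-test wald`) is a Wald test of equal standardized slopes in a
  joint two-score logistic model — a likelihood-based contrast offered
  because the published description of the comparison procedure is
  ambiguous; the two methods agree on the null but answer slightly
  different questions and the DeLong test is the documented default.

Multiple-testing correction is deliberately absent (two-sided α = 0.05
throughout), matching the analysis the tables come from.

### What reproduces exactly, and what cannot

The per-stratum mortality percentages of both published stratification
tables, and every labMELD-table odds ratio (2.03, 4.38, 2.97, 9.67, 20.71)
and p-value, reproduce **exactly** from the printed counts via the
cross-product estimator. Two published quantities do not, and are treated
accordingly:

- The **risk-score table ORs** (0.50 … 43.33) are inconsistent with that
  table's own counts under any standard 2×2 estimator (group 4 vs group 1
  cross-product = 128, printed 43.33); they most likely originate in the
  score's development cohort. They are flagged as irreproducible, not
  guessed at.
- The published **C-indexes** (0.8421, 0.7352, 0.6953, 0.5413, 0.6795) and
  pairwise ROC p-values used unbinned patient-level scores that were never
  deposited. From the printed stratum counts the binned C-index computes to
  0.8399 (risk score) and 0.7334 (labMELD) — within 0.01 of the published
  values; the residual is binning, not error, and the checks are documented
  as approximate.

## Synthetic cohort generator

The generator emulates the *marginals* of the 529-patient validation
cohort: each scored-factor prevalence (trisectionectomy 7.4%, intrahepatic
CC 11.2%, perihilar CC 6.6%, INR ≥ 1.1 11.5%, GGT ≥ 60 53.9%, platelets
< 120 6.0%, creatinine ≥ 2 1.3%, bilirubin ≥ 2 6.2%, male 61.1%, ASA III/IV
45.9%), the age median/IQR (61.8, 52.8–69.0), and the per-risk-group
90-day death rates (0.5%, 0.8%, 6.1%, 9.1%, 9.4%, 40.0%).

Design, in sampling order:

- **Age** is skew-normal, with (shape, location, scale) solved once by
  least squares so the 25/50/75 percentiles match the printed quartiles
  (the mild left skew of the printed IQR), truncated at 18 by rejection.
- **Labs** are log-normal. Each law has two free parameters; the median is
  a documented convention (INR 1.0, GGT 65 U/l, platelets 220/nl,
  creatinine 0.9 mg/dl, bilirubin 0.7 mg/dl — unremarkable values for an
  elective hepatectomy population) and sigma is solved from the printed
  threshold prevalence. Binary factors are then *derived by thresholding
  the continuous draws*, so thresholds and prevalences are mutually
  consistent by construction; an inconsistent spec (median on the wrong
  side of its threshold) is rejected before sampling. Labs are stored at
  full precision because rounding near a scoring threshold would bias the
  factor prevalences.
- **Categorical draws**: diagnosis is a single three-way draw (the two
  cholangiocarcinoma categories are mutually exclusive); ASA uses the split
  I/II/III/IV = 0.100/0.441/0.440/0.019, a convention since only III+IV =
  45.9% is published; dialysis prevalence 0.4%.
- **POSSUM items** are iid categorical over {1,2,4,8}: physiological
  probabilities (0.78, 0.15, 0.055, 0.015) giving E[PS] ≈ 17.0, operative
  non-severity probabilities (0.38, 0.34, 0.21, 0.07) giving E[OS] ≈ 16.3
  with the severity item fixed at "major" (4) — matching the published
  PS/OS means of 17.1 and 16.2.
- **Outcome**: each record is scored, then `death_90d` is Bernoulli with
  its risk group's published death rate. This group-rate mechanism (rather
  than a smooth logistic in points) makes stratum-table validation exactly
  recoverable in expectation.
- **RNG**: one root seed, one `SeedSequence` substream per variable (keyed
  by a fixed stream index), so adding a variable never perturbs earlier
  streams; same (seed, spec) → byte-identical cohort.

Factors are **independent** apart from the deterministic ties above — the
simplest structure consistent with every published marginal, since the
source reports no correlations. Real cohorts are correlated (cholestatic
perihilar tumours raise GGT, INR and bilirubin together), and this matters
for one visible quantity: the closed-form expected death rate of the
independence model, Σ_g P(group g)·rate(g), computed exactly by convolving
the per-factor point distributions, is **3.9%**, below the observed 4.5% —
the real cohort's correlated risk factors concentrate more patients in the
high-risk groups than independence does. The gap is well inside the
binomial sampling band of a single 529-patient cohort (± 1.8 pp), and the
generator is validated against its *own* closed-form law, but passing those
tests says nothing about between-factor correlation in real data. A
correlated generator would need joint distributions the source does not
print.

Also not emulated: temporal trends, centre/surgeon effects, between-lab
correlation, and BMI/comorbidity missingness (no score uses those fields).

## Problem sizes and numerical conventions

Test and validation runs use: exhaustive Fisher cross-checks up to table
total 30; the full 85×43 PS/OS grid against a 50-digit decimal logistic
oracle at 1e-12; 2,000-point decimal checks of the labMELD formula at 1e-9
with a 100,000-point range sweep; 100 seeded 529-patient cohorts for
death-rate coverage and one 100,000-patient cohort for prevalence recovery
(3 SE) and C-index convergence (± 0.01 of the closed-form concordance);
logistic parameter recovery over 20 seeds at n = 5,000 (≥ 18/20 within
3 SE). Report CSVs round percentages to one decimal and ORs/CIs to two,
mirroring the published tables; all internal computation is at full double
precision and rounding happens only at render time.

## Known limitations

- The Copeland band transcription covers the printed bands; genuinely
  ambiguous raw values (e.g. a haemoglobin of 12.95 g/dl) are resolved by
  rounding to the table's printed resolution first.
- The exact-Mann-Whitney cutoff (n·m ≤ 400) is a speed/exactness trade;
  beyond it the tie-corrected normal approximation is accurate to the
  third decimal for the sample sizes this package targets.
- Woolf CIs are near, but not identical to, the published CIs (which were
  produced by a different, unstated method); CI endpoints are therefore
  not exact-reproduction targets anywhere in the suite.
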