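# Methods

## Overview

The package chains four components: (1) a synthetic-cohort generator
calibrated to published marginal summaries of a European secondary-
prevention ASCVD population; (2) a REACH-style 20-month recurrent-event
risk equation with constant-hazard horizon conversion; (3) per-patient
LDL-C gap arithmetic against fixed achieved goal levels; (4) Monte-Carlo
scaling of a meta-analytic rate ratio to those gaps, yielding relative and
absolute risk reductions and residual 10-year risk, summarized as median
(IQR) overall and by vascular-bed subtype.

## Synthetic cohort generator

**What it emulates.** The generator reproduces the printed marginals of a
2039-patient treated ASCVD cohort: 61% with LDL-C ≥ 70 mg/dl; LDL-C
median (IQR) 93 (81–115) mg/dl in the ≥70 stratum and 56 (46–63) mg/dl in
the <70 stratum; subtype mix CAD:CBD:PAD = 470:751:818; per-stratum
prevalences of female sex, diabetes, hypertension, CKD ≥ stage 3 and the
five-level smoking history; per-stratum means/SDs for age and blood
pressure and median/IQR for BMI; and the six therapy-category frequencies
(statin monotherapy by intensity, ezetimibe combination, PCSK9i
combination, other LLT).

**LDL-C marginal.** Three printed quantiles identify the three parameters
of a shifted lognormal in closed form:

    shift = (median² − q1·q3) / (2·median − q1 − q3)
    log_sd = ln((q3 − shift)/(median − shift)) / z₀.₇₅,   z₀.₇₅ = 0.6744897…

For (81, 93, 115) this gives shift 66.6 mg/dl and log-sd 0.899, and the
fitted quartiles reproduce the printed ones exactly.  Left-skewed triples
(median − q1 > q3 − median, e.g. the <70 stratum's 46/56/63) have no
right-skewed lognormal solution; the same closed form then lands above q3
and is used as the reflection point of the mirrored family
`X = shift − lognormal`.  Exactly symmetric triples degrade to a
quartile-matched normal with a warning.  The ≥70 stratum is truncated
below at 70 mg/dl (removing ≈1.1% of mass, shifting quartiles < 0.5
mg/dl); the <70 stratum is truncated to [20, 70) — the 20 mg/dl floor
avoids implausible near-zero concentrations.  Truncation uses rejection
sampling with an analytic acceptance-probability guard (< 10⁻³ is treated
as a mis-specification error).

**Unpublished marginals.** Chronic heart failure (12%), atrial
fibrillation (10%), an event within the last year (15%), the
vascular-bed-count distribution (1/2/3 beds = 0.81/0.16/0.03, chosen so the
mean matches the ~122% summed bed-involvement percentages of the source
tables) and region (70/30 western/eastern Europe) are not printed per
stratum; these defaults were fixed once at registry-literature values and
are part of the generator's contract, not tuning knobs.

**Joint structure.** Covariates are independent given the stratum (and the
subtype is independent of both).  The published tables contain only
marginals, so no correlation structure is assumed.  Consequences: gap and
relative-risk-reduction summaries — monotone functionals of the LDL-C
marginal alone — are faithfully reproduced, while absolute-risk and
residual-risk summaries depend on the unpublished joint distribution of
baseline risk and LDL-C and are only matched in ballpark.  Passing tests
therefore validate the pipeline's arithmetic and the marginal calibration,
not any claim about real-world covariate dependence.

**Seeding.** One master seed expands via `numpy.random.SeedSequence.spawn`
into four substreams (stratum/subtype, LDL-C, covariates, therapy), so
extending the generator never perturbs existing streams; identical specs
produce identical cohorts, byte for byte after CSV round-trip.

## Baseline risk engine

The 20-month risk of a recurrent cardiovascular event is a proportional-
hazards score: encoded covariates (linear with centering, indicators,
categorical level codes) times coefficients, mapped through
`p20 = 1 − S₀^exp(score − reference_score)`.  A logistic-intercept
parameterization is supported behind the same interface because published
recalibrations of such equations report either form.

Coefficients are configuration, never code.  The packaged default
(`data/reach_coefficients_synthetic.yaml`) is an explicitly **synthetic**
REACH-style set: the covariate list mirrors the usual secondary-prevention
risk factors with literature-plausible log-hazard magnitudes, and the
baseline block (S₀ = 0.937745 at reference score 0.6833, the median
linear predictor of the default ≥70 stratum) is calibrated once so the
median predicted 10-year risk in that stratum is 32%, matching the
published cohort-level figure.  The resulting dispersion (IQR ≈ 25–40%)
and the <70-stratum median (≈34%, driven by that stratum's higher diabetes
and smoking prevalence) emerge from the covariate model rather than being
targeted.  Any user-supplied coefficient file with the documented schema
replaces it; the unit tests run on toy coefficient sets with
hand-computable outputs.

**Horizon conversion.** `p_to = 1 − (1 − p_from)^(t_to/t_from)` assumes a
constant event rate (exponential survival).  Months are the time unit and
10 years is exactly 120 months.  No competing-risk adjustment is applied —
the conversion is a pure constant-hazard extrapolation, which will
overstate long-horizon risk in elderly strata.

## Goal simulation

Eligibility is LDL-C ≥ 70 mg/dl (the ≥ boundary includes exactly 70.0);
patients below it are excluded with a logged count.  Achieved levels are
fixed at 69, 54 and 39 mg/dl — the conservative "one unit below the
threshold" convention — never patient-specific.

The effect model treats the rate ratio per 39 mg/dl as lognormal:
`rr = exp(N(ln 0.78, σ))` with `σ = (ln 0.80 − ln 0.76)/(2·1.959964)`
derived from the 95% CI.  Sampling is inverse-CDF; setting the CI equal to
the point estimate gives the deterministic σ = 0 limit in which every
headline median reduces to closed-form quantile arithmetic (used as an
oracle in the tests).  The exponent denominator is 39 mg/dl exactly —
matching the effect measure's own unit — not 38.67 mg/dl per mmol/l; it is
configurable for sensitivity analysis.

Draw granularity: one independent rate-ratio draw per patient per
replicate (default 100 replicates), with summaries pooled over patients ×
replicates.  A shared-draw-per-replicate mode (one draw applied to the
whole cohort per replicate) is available for sensitivity analysis; it
leaves all medians unchanged and widens between-replicate spread.

Per row, `ARR = p120 × RRR` and `residual = p120 − ARR` hold exactly (the
residual is computed as the difference), and deeper goals dominate
shallower ones patient-by-patient when the same draws are used.

## Reporting conventions

Quartiles use linear interpolation between order statistics (position
`1 + (n−1)p`, numpy's default), so the median of {1,2,3,4} is 2.5 with
quartiles (1.75, 3.25).  Human-readable tables render percentages rounded
half-away-from-zero to integers; raw fractions are preserved in the tidy
CSV.  Rendering is byte-stable, and re-summarizing a written results CSV
reproduces the original summary exactly (floats are parsed in round-trip
mode).

## Problem sizes

Default runs use the full 2039-patient cohort with 100 replicates
(~200 000 simulated rows per scenario, < 1 s each).  Marginal-calibration
checks use 10⁵ LDL-C draws; the test suite uses cohorts of 100–60 000
records.  These sizes make quantile noise small relative to the ±1 mg/dl /
±1 percentage-point calibration tolerances used in the acceptance checks.

## Known limitations

* Independence of covariates given stratum — no LDL-C × comorbidity
  correlation beyond the two-stratum split, so absolute/residual risk
  medians are ballpark, not calibrated targets.
* The default coefficient file is synthetic; users reproducing a specific
  published recalibration must transcribe its coefficient table.
* Constant-hazard extrapolation from 20 months to 10 years ignores hazard
  decay and competing mortality.
* No treatment-assignment modelling: the simulation answers "what if the
  goal were attained", not which drug attains it, and no adherence or
  intensification pathway is modelled.
* One reported IQR in the source summaries ("27–91" for the reduction to
  54 mg/dl) is inconsistent with its own quartiles (115 − 54 = 61); the
  quartile-consistent 61 is used as the reference value.
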