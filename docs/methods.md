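# Methods

## Scope and model

The toolkit operationalises renal angina screening for a PICU cohort:

1. **Eligibility** — ages 1–168 months (both ends included; the source
   criteria say "1 month to 14 years" without stating whether 14 years
   exactly is in, so the closed interval is used), no pre-existing
   chronic kidney disease, parental consent, stay ≥ 72 h. A record
   failing several criteria is counted under exactly one reason, with
   priority age > CKD > short stay > consent, so exclusion counts are
   disjoint and sum to identified − eligible. Age gets its own counter
   (`n_excluded_age`) even though screening logs rarely contain
   out-of-window admissions.
2. **RAI at 8–12 h** — risk stratum (1 ICU / 3 transplant / 5
   ventilation-or-vasoactive, highest wins; the strata are exclusive,
   not additive — only a maximal multiplier of 5 is consistent with the
   1–40 range) times injury tier. The injury tier is the **maximum** of
   the clearance-decline tier and the fluid-overload tier, following
   the original renal-angina construction; the driving signal is
   recorded for audit. Tier bands are half-open with the lower bound
   inclusive ("25–<50"), a decline of exactly 0 and FO of exactly 5
   stay in tier 1. The assessment window end defaults to 12 h
   (`rai.window_h`, valid 8–12); support flags count if active at any
   time in the window (`rai.support_mode`, with an at-window-end
   alternative, since "at 12 hours of admission" is ambiguous).
3. **KDIGO day-3 staging** — the creatinine rules are implemented as
   operationalised in the source protocol, which omits the canonical
   1.5–1.9× stage-1 ratio; `kdigo.canonical = true` restores it. The
   0.3 mg/dL delta is checked across every pair of values ≤ 48 h apart,
   with the resolved baseline acting as an admission-time value; ratio
   criteria compare against the resolved baseline (with ≤ 4 in-study
   days, every value lies within 7 days of it). Urine criteria are
   evaluated on contiguous hourly windows: "6 to 12 hours" → [6, 12) h,
   "more than 12" → ≥ 13 h at hourly resolution, "for 24 hours" →
   ≥ 24 h. Missing hours break contiguity; a patient with no urine data
   is staged on creatinine alone and flagged. Dialysis never forces
   stage 3 — it is analysed as a secondary outcome.
4. **Diagnostics** — 2×2 tables, sensitivity/specificity/PPV/NPV (zero
   denominators yield NaN, never 0), ROC-AUC with half credit for ties
   (trapezoidal sweep over unique thresholds, equivalent to the
   midrank Mann–Whitney statistic), Pearson chi-square without
   continuity correction by default (Yates via config), two-sided
   tie-corrected Mann–Whitney U. Percentages print with one decimal,
   round half up; p-values below 0.001 print as "<.001".

## Baseline creatinine

The baseline is the lowest pre-admission creatinine when available.
When it is not, the baseline is **back-calculated** by inverting the
Schwartz equation at an assumed normal clearance
(`baseline.assumed_ecrcl`, default 120 mL/min/1.73 m², the convention
of the renal-angina literature); the alternative reading — substituting
an eGFR directly — is not used, and every back-calculation is logged.
Schwartz k defaults to the bedside constant 0.413; the original
age/sex-dependent constants (0.45 infant, 0.70 adolescent boy, 0.55
otherwise) are available via `schwartz.k_mode: age_sex`.

%FO uses the standard ICU definition, cumulative (intake − output) /
admission weight × 100 with fluid density 1 g/mL, because no explicit
formula is given in the source protocol. Negative balances are kept
(anything ≤ 5% maps to injury tier 1 regardless).

## Comparator predictors

Performance tables target **severe day-3 AKI** (stage ≥ 2, the primary
outcome). Four predictors are evaluated:

* RAI — RA± at threshold 8 for the 2×2; the raw score for AUC.
* Day-0 elevated creatinine — the latest day-0 value meets any
  stage-1+ creatinine criterion versus baseline (no explicit threshold
  is published for this comparator); the day-0/baseline ratio is the
  continuous score.
* Fluid overload > 5% alone — the assessment-window %FO.
* Illness severity — PRISM II (an input covariate, never computed
  here), dichotomised at `diagnostics.prism_threshold` (default 17,
  chosen to sit near the published operating point of roughly 50%
  sensitivity / 80% specificity; no threshold is published); the raw
  score is used for AUC.

## Synthetic cohort generator

The generator emulates the two-file cohort schema with the published
conditional structure: RA+ prevalence 19.9%; given RA status, day-3 AKI
74.1%/10.6%, severe AKI 60.6%/4.2%, ventilation 61.7%/18.4%, inotropes
61.7%/13.7%, dialysis 21.3%/1.1%, mortality 31.4%/2.8%, PICU stay
11.1 ± 3.5 / 5.5 ± 2.1 days (truncated at the 3-day eligibility floor);
the admission-diagnosis mix follows the published frequencies.

Generation is **backward**: latent labels are drawn first, then series
are constructed to hit them — a patient intended RA+ via the clearance
axis receives an assessment-window creatinine realising a decline drawn
inside the intended tier band; intended day-3 stages are realised by a
creatinine ramp (delta/ratio route) or a carved low-urine window,
whichever is feasible given the patient's baseline (a large creatinine
decline mathematically forces a ≥ 2× ratio, so tier-8 injury in a
patient intended to stay AKI-free is routed through fluid overload; a
stage-1 delta of 0.3 mg/dL forces a ≥ 2× ratio when the baseline is
≤ 0.3 mg/dL, so small infants take the urine route). Stage ≥ 2 patients
start their creatinine rise on day 1, as real AKI courses do, which
gives the day-0 comparator realistic behaviour. With `label_noise = 0`
the scorer and stager recover every latent label exactly — verified
over 100 seeds × 446 patients in the test suite — so observed cohort
rates are exact binomial draws of the configured probabilities.

Conventions the generator does **not** claim to model: creatinine
kinetics (values jump between constructed set-points), site effects,
informative missingness (urine data is always complete), the
correlation between fluid overload and urine output, and baseline
weight error in dehydrated patients. Passing tests therefore
demonstrate correctness of the *scoring and staging logic* and the
calibration of the *label structure*, not physiologic realism of the
trajectories. Demographic conventions: age uniform over 2–168 months,
height and weight from simple pediatric growth formulas with noise,
baseline creatinine lognormal with age-interpolated median 0.3 → 0.7
mg/dL (log-sd 0.15), 40% of patients carrying a historical baseline,
PRISM II normal (mean 12, sd 6) shifted +2 for AKI and +5 for severe
AKI.

## Numerical choices and degenerate inputs

* Creatinine units: canonical mg/dL; µmol/L inputs divided by 88.4.
* No creatinine in the assessment window → the patient is flagged
  unassessable, excluded from downstream metrics, and counted in the
  run manifest — never silently dropped.
* Single-class outcomes make AUC undefined → reported as NaN/"NA".
* Zero chi-square marginals raise; the report records the p-value as
  not computable.
* Numbers round-trip through CSV via `repr`, preserving them to within
  1e-9 (tested bit-for-bit for text fields).
* RA threshold behaviour needs no tolerance: composite scores are
  integers, the attainable set being {1,2,3,4,5,6,8,10,12,20,24,40}
  (12 values; 8 and 6 straddle the threshold).

## Problem sizes

The test suite exercises cohorts of 40–446 patients; the calibration
check runs 100 seeds at n = 446 (the published cohort size), comparing
each configured probability against the Clopper–Pearson 95% interval of
its realised rate, pooled across parameters. Oracle cross-checks run
brute-force enumeration on instances small enough to enumerate
(rank statistics at n ≤ 12, staging on ≤ 96-hour series).

## Known limitations

* Mean RAI moments reported descriptively for AKI vs non-AKI groups in
  the source study (9.3 ± 2.7 vs 6.1 ± 1.8) are not calibration
  targets: the discrete attainable-score set underdetermines a matching
  generator distribution.
* The published head-to-head performance table cannot be reconstructed
  from printed counts (its sensitivity/specificity are mutually
  inconsistent with the group tables), so empirical metrics on
  synthetic cohorts are validated for internal consistency, not
  against those figures.
* No day-28 restaging, renal-recovery classification, logistic
  regression, or biomarker axes.
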