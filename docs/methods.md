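# Methods note

This note records the modeling conventions, numerical choices and known
limitations of `afgtt`. It states what the code computes; it makes no
empirical claims beyond what the test suite verifies.

## Trigger engine

The default set contains 21 triggers in four blocks: laboratory (L1–L7),
note-keyword (S1–S10), antidote medication class (A1–A2) and intervention
flags (T1–T2).

* **Comparators are strict** and applied exactly as configured (e.g. L6
  fires on K⁺ < 2.9, not ≤). A value equal to the threshold never fires.
* **Deduplication:** one hit per (patient, trigger), dated at the earliest
  qualifying day. Per-trigger counts are therefore patient counts.
* **Exposure window:** symptom, antidote and intervention triggers are only
  evaluated on or after the first antifungal start day; laboratory triggers
  scan the whole stay (pre-exposure labs are legitimate baselines and
  deterioration evidence).
* **L4 (renal)** has two branches: creatinine rising to strictly more than
  2× the *first recorded* value, or creatinine clearance < 50 mL/min. The
  baseline is the first value by day, not the minimum.
* **L5 (hepatic)** is a compound trigger: both components must fire, and the
  hit is dated at the later of the two earliest qualifying days.
* **Keywords** match as case-insensitive, whitespace-normalized substrings.
  This deliberately over-triggers (e.g. a note reading "no rash" fires the
  rash trigger); the GTT design accepts low-specificity triggers because
  every hit is adjudicated by humans afterwards.
* **Monotonicity scope:** appending lab results at days at or after existing
  ones can only add hits, never remove them (property-tested). Prepending an
  *earlier* lab can legitimately un-fire the L4 2×-baseline branch by
  changing the baseline, so monotonicity is only claimed for appends.

## Adjudication

Causality follows the WHO-UMC category system with a fixed evaluation
order: unassessable → conditional → certain → probable → possible →
unlikely. The first category whose criteria are met is assigned; a negative
rechallenge vetoes "certain". A hit is counted as a confirmed ADE iff its
category is certain, probable or possible. Severity uses CTCAE v5.0 logic:
grade 5 death, 4 life-threatening/urgent intervention, 3 hospitalization or
prolongation / self-care ADL limitation, 2 minimal intervention /
instrumental ADL limitation, else 1. Consensus takes two junior reviews and
escalates disagreements to a senior review.

## Metrics conventions

* **PPV is instance-level:** confirmed ADE instances ÷ trigger instances
  (214/795 on the fixture). It is not a patient-level quotient.
* **The 2×2 table is patient-level:** trigger-positive × ADE-positive, where
  ADE-positive includes patients found only by full chart review. Such
  chart-review-only patients enter the false-negative cell and the
  false-negative rate, but **incidence counts only trigger-detected ADE
  patients** (138/480 = 28.75%, not 142/480). Per-100-admissions and
  per-1,000-patient-days rates use ADE instances in the numerator.
* Cohen's kappa is computed from the 2×2 as (p₀ − pₑ)/(1 − pₑ); the tests
  verify it against a brute-force expansion into paired rater labels.
* Sample size: N = Z²P(1−P)/δ², rounded half-up to an integer.
* The two-proportion comparison is a Pearson chi-square without continuity
  correction (scipy, `correction=False`); a warning is emitted when an
  expected cell is below 1.
* Reported decimals use round-half-up (`decimal.Decimal`), matching how
  clinical tables are conventionally rounded, rather than banker's rounding.

## Risk-factor model

Covariates are binned categorically (length of stay 1–10/11–20/21–30/≥31;
antifungal count 1/2/3; antibacterial count 0–3/4–6/≥7; trigger count
0–2/3–5/≥6; comorbidities 1–3/4–6/>6; etc.). A record with missing BMI maps
to no BMI level and is excluded from BMI analyses. The logistic regression
is IRLS with: convergence on max|score| < 1e-8, step-halving to keep the
deviance monotone non-increasing, divergence detection (|β| > 30 or a
singular weighted information matrix ⇒ `SeparationError`), and a greedy
QR-based rank scan that names aliased columns (`AliasedDesignError`). Wald
95% CIs are exp(β̂ ± 1.96·SE); the overall p-value is a likelihood-ratio
test against the intercept-only model. The estimator is verified against an
independent scipy likelihood maximization and against parameter recovery on
simulated cohorts.

## Synthetic generator and fixture

`simulate_cohort` draws ADE status per patient, then plants trigger
evidence (lab values, note keywords, antidote orders, flags) at
group-specific per-trigger rates, together with the adjudication evidence
that reproduces the intended labels. Defaults mirror study-scale conditions
(480 patients, prevalence 142/480, per-trigger rates derived from the
fixture's counts, log-normal length of stay). All randomness flows from a
single seed; equal seeds give byte-identical cohorts on disk.

`make_study_fixture` is deterministic (no RNG for any pinned quantity). It
realizes the published *margins* exactly — per-trigger positive and ADE
counts, patient-level 2×2, trigger-count histograms, causality and severity
splits, covariate bin margins per outcome group, and total patient-days
(6,476) — via a greedy bipartite degree realization, and then re-screens and
re-adjudicates itself, raising `FixtureError` if any target is missed. Only
the margins are constrained: the joint distribution across covariates is a
modeling choice. Within each outcome group, each covariate's level order is
permuted with a fixed per-covariate seed; without this, block-aligned
assignment makes the covariates collinear within groups and the
main-effects logistic design quasi-separable. Patient-level adjusted odds
ratios therefore cannot be recovered from published margins alone; the
fixture supports the model's *layout* (covariates, levels, reference
coding) while estimator correctness is established by simulation.

## Limitations

* Time is modeled in whole-day offsets; "antifungal course ≥ 24 h" is
  enforced as stop_day ≥ start_day + 1.
* Keyword triggers have no negation handling (by design, see above).
* The fixture's joint covariate/trigger structure is synthetic; only its
  margins are meaningful. Regression coefficients fitted on the fixture
  describe the fixture, not any patient population.
* WHO-UMC and CTCAE logic encode one defensible reading of the criteria as
  a deterministic decision tree; real adjudication involves judgment the
  tree cannot capture.
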