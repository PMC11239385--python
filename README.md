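# afgtt — an antifungal Global Trigger Tool

`afgtt` implements a Global Trigger Tool (GTT) for detecting adverse drug
events (ADEs) in hospitalized patients receiving systemic antifungal therapy.

Spontaneous reporting systems miss the large majority of ADEs. The GTT
approach instead screens every chart for *triggers* — cheap, objective clues
such as an abnormal lab value, a symptom keyword in a progress note, or an
antidote order — and sends only trigger-positive charts to structured human
review. This package provides the full pipeline:

1. **Records** (`afgtt.records`) — validated patient chart models
   (demographics, labs, medication orders, note events) with a byte-stable
   CSV/JSONL on-disk format.
2. **Trigger engine** (`afgtt.triggers`) — a 21-trigger screening set:
   7 laboratory triggers (thresholds, a drug-level trigger, a compound
   renal trigger, a 2×-baseline creatinine rule), 10 note-keyword triggers,
   2 antidote-class triggers and 2 intervention flags. Triggers are
   data-driven (YAML-serializable), deduplicated to one hit per patient and
   trigger, and windowed to the antifungal exposure period where applicable.
3. **Adjudication** (`afgtt.adjudication`) — WHO-UMC causality assessment
   (certain / probable / possible / unlikely / conditional / unassessable,
   evaluated in a fixed order with rechallenge veto), CTCAE v5.0 severity
   grading (1–5), and a two-junior-plus-senior consensus rule. A hit becomes
   a confirmed ADE iff its causality is certain, probable or possible.
4. **Metrics** (`afgtt.metrics`) — instance-level positive predictive value,
   patient-level 2×2 validity metrics (sensitivity, specificity, Youden
   index, Cohen's kappa against chart review), incidence and per-100
   admissions / per-1,000 patient-days rates, the `N = Z²P(1−P)/δ²` sample
   size, and a two-proportion chi-square test.
5. **Risk factors** (`afgtt.risk_factors`) — covariate binning, univariate
   chi-square / rank-sum tests, and a hand-verified IRLS logistic regression
   with Wald CIs, separation and aliasing diagnostics.
6. **Synthetic data** (`afgtt.synthetic`, `afgtt.fixture`) — a seeded random
   cohort generator and `make_study_fixture()`, a deterministic 480-patient
   cohort whose screening and adjudication output reproduces a full set of
   published-scale summary statistics exactly (the fixture self-verifies at
   build time).

## Worked example

```python
from afgtt import (
    make_study_fixture, default_trigger_set, screen_cohort,
    adjudicate_cohort, compute_cohort_metrics, per_trigger_performance,
)

cohort, truth = make_study_fixture()
screen = screen_cohort(cohort, default_trigger_set())
ades = adjudicate_cohort(screen, truth.evidence)
m = compute_cohort_metrics(
    screen, ades, set(cohort.patient_ids()),
    cohort.total_patient_days(),
    chart_review_ade_patients=truth.chart_review_only,
)
print(f"patients screened        {len(cohort)}")
print(f"trigger-positive         {len(screen.positive_patients)} "
      f"({100 * m.positive_trigger_rate:.2f}%)")
print(f"trigger instances        {screen.n_hits}")
print(f"confirmed ADE instances  {len(ades)}")
print(f"overall PPV              {100 * m.overall_ppv:.2f}%")
print(f"ADE incidence            {100 * m.incidence:.2f}%")
print(f"per 1,000 patient-days   {m.ades_per_1000_patient_days:.2f}")
```

Output:

```text
patients screened        480
trigger-positive         316 (65.83%)
trigger instances        795
confirmed ADE instances  214
overall PPV              26.92%
ADE incidence            28.75%
per 1,000 patient-days   33.05
```

Per-trigger performance is available too — the three highest-PPV triggers on
the fixture:

```text
S10  1/1  = 100.0%   (phlebitis / infusion reaction)
S6   23/55 = 41.8%   (gastrointestinal symptoms)
L6   21/53 = 39.6%   (hypokalemia, K+ < 2.9 mmol/L)
```

A `click` CLI mirrors the API: `afgtt simulate`, `afgtt fixture`,
`afgtt screen`, `afgtt adjudicate`, `afgtt evaluate`, `afgtt risk-factors`,
`afgtt export-triggers` (see `afgtt --help`).

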