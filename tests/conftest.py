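import pytest

from afgtt import (
    adjudicate_cohort,
    default_trigger_set,
    make_study_fixture,
    screen_cohort,
)
from afgtt.records import (
    Demographics,
    DrugClass,
    MedicationOrder,
    PatientRecord,
    Route,
)


@pytest.fixture(scope="session")
def study():
    """The deterministic study-scale cohort and its ground truth."""
    return make_study_fixture()


@pytest.fixture(scope="session")
def study_screen(study):
    cohort, _ = study
    return screen_cohort(cohort, default_trigger_set())


@pytest.fixture(scope="session")
def study_ades(study, study_screen):
    _, truth = study
    return adjudicate_cohort(study_screen, truth.evidence)


@pytest.fixture
def record_factory():
    """Build a minimal valid admission; keyword args override fields."""

    def make(
        patient_id="P1",
        los=10,
        labs=(),
        orders=None,
        notes=(),
        icu_or_rescue=False,
        antifungal_start=0,
        **demo_kw,
    ):
        base_orders = [
            MedicationOrder(
                drug_code="voriconazole",
                drug_class=DrugClass.antifungal,
                start_day=antifungal_start,
                stop_day=antifungal_start + 3,
                route=Route.iv,
            )
        ]
        if orders:
            base_orders.extend(orders)
        demo = dict(
            patient_id=patient_id,
            age_years=50.0,
            sex="male",
            bmi=22.0,
            department="internal",
            prior_hospitalizations=1,
        )
        demo.update(demo_kw)
        return PatientRecord(
            demographics=Demographics(**demo),
            length_of_stay_days=los,
            labs=list(labs),
            orders=base_orders,
            notes=list(notes),
            icu_or_rescue=icu_or_rescue,
            comorbidity_count=3,
        )

    return make
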