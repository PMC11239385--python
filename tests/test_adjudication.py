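"""Causality decision tree, severity grading and consensus arbitration."""

import itertools

import pytest

from afgtt import assess_causality, consensus, grade_severity
from afgtt.adjudication import (
    AdjudicationError,
    CausalityCategory,
    CausalityEvidence,
    Dechallenge,
    Intervention,
    OtherExplanation,
    Rechallenge,
    SeverityEvidence,
    TemporalRelationship,
    adjudicate_cohort,
)


def ev(**kw):
    base = dict(
        temporal_relationship="reasonable",
        other_explanation="possible",
        dechallenge="unknown",
        rechallenge="not_done",
    )
    base.update(kw)
    return CausalityEvidence(**base)


@pytest.mark.parametrize(
    "evidence, expected",
    [
        # plausible timing, no alternative, positive de- and rechallenge
        (
            ev(
                temporal_relationship="plausible",
                other_explanation="excluded",
                dechallenge="positive",
                rechallenge="positive",
            ),
            "certain",
        ),
        # negative rechallenge vetoes certainty
        (
            ev(
                temporal_relationship="plausible",
                other_explanation="excluded",
                dechallenge="positive",
                rechallenge="negative",
            ),
            "probable",
        ),
        # reasonable timing + positive withdrawal response, no rechallenge
        (
            ev(other_explanation="excluded", dechallenge="positive"),
            "probable",
        ),
        # could also be explained by disease; withdrawal unclear
        (ev(), "possible"),
        (ev(other_explanation="likely", dechallenge="positive"), "possible"),
        # improbable timing with a plausible alternative
        (
            ev(temporal_relationship="improbable", other_explanation="likely"),
            "unlikely",
        ),
        (ev(information_sufficient=False), "unassessable"),
        (ev(more_data_pending=True), "conditional"),
    ],
)
def test_causality_decision_tree(evidence, expected):
    assert assess_causality(evidence) is CausalityCategory(expected)


def test_causality_total_over_evidence_space():
    """Exhaustive enumeration: total, six categories only, and a certain
    judgement always satisfies the weaker possible-level criteria."""
    space = itertools.product(
        TemporalRelationship, OtherExplanation, Dechallenge, Rechallenge,
        (False, True), (False, True), (False, True),
    )
    seen = set()
    for t, o, d, r, pharm, info, pending in space:
        e = CausalityEvidence(
            temporal_relationship=t, other_explanation=o, dechallenge=d,
            rechallenge=r, pharmacologically_definitive=pharm,
            information_sufficient=info, more_data_pending=pending,
        )
        cat = assess_causality(e)
        seen.add(cat)
        if cat is CausalityCategory.certain:
            assert t in (
                TemporalRelationship.plausible, TemporalRelationship.reasonable
            )
    assert seen == set(CausalityCategory)


@pytest.mark.parametrize(
    "field, stronger, weaker",
    [
        ("other_explanation", "excluded", "possible"),
        ("other_explanation", "possible", "likely"),
        ("dechallenge", "positive", "unknown"),
        ("temporal_relationship", "plausible", "reasonable"),
        ("temporal_relationship", "reasonable", "improbable"),
    ],
)
def test_weakening_evidence_never_raises_category(field, stronger, weaker):
    rank = {
        "unlikely": 0, "possible": 1, "probable": 2, "certain": 3,
    }
    others = itertools.product(
        TemporalRelationship, OtherExplanation, Dechallenge, Rechallenge,
        (False, True),
    )
    for t, o, d, r, pharm in others:
        base = dict(
            temporal_relationship=t, other_explanation=o, dechallenge=d,
            rechallenge=r, pharmacologically_definitive=pharm,
        )
        strong = assess_causality(CausalityEvidence(**{**base, field: stronger}))
        weak = assess_causality(CausalityEvidence(**{**base, field: weaker}))
        assert rank[weak.value] <= rank[strong.value]


@pytest.mark.parametrize(
    "evidence, grade",
    [
        (SeverityEvidence(), 1),
        (SeverityEvidence(symptomatic=True), 1),
        (SeverityEvidence(intervention="minimal_local_noninvasive"), 2),
        (SeverityEvidence(limits_instrumental_adl=True), 2),
        (SeverityEvidence(intervention="hospitalization_or_prolongation"), 3),
        (SeverityEvidence(limits_selfcare_adl=True), 3),
        (SeverityEvidence(life_threatening=True), 4),
        (SeverityEvidence(intervention="urgent"), 4),
        (SeverityEvidence(death=True), 5),
    ],
)
def test_severity_grades(evidence, grade):
    assert grade_severity(evidence) == grade


def test_severity_monotone_in_each_flag():
    for interv in Intervention:
        for inst, selfc, life, death in itertools.product((False, True), repeat=4):
            base = SeverityEvidence(
                intervention=interv, limits_instrumental_adl=inst,
                limits_selfcare_adl=selfc, life_threatening=life, death=death,
            )
            g = grade_severity(base)
            for flag in (
                "limits_instrumental_adl", "limits_selfcare_adl",
                "life_threatening", "death",
            ):
                raised = base.model_copy(update={flag: True})
                assert grade_severity(raised) >= g


class TestConsensus:
    def test_agreement_stands(self):
        c = CausalityCategory.possible
        assert consensus(c, c) is c

    def test_senior_arbitrates_disagreement(self):
        out = consensus(
            CausalityCategory.possible,
            CausalityCategory.unlikely,
            CausalityCategory.probable,
        )
        assert out is CausalityCategory.probable

    def test_disagreement_without_senior_is_error(self):
        with pytest.raises(AdjudicationError):
            consensus(CausalityCategory.possible, CausalityCategory.unlikely)


class TestAdjudicateCohort:
    def test_ade_count_bounded_by_hits(self, study_screen, study_ades):
        assert len(study_ades) <= study_screen.n_hits

    def test_unlikely_evidence_yields_no_ade(self, record_factory):
        from afgtt import default_trigger_set, screen_cohort, Cohort
        from afgtt.records import LabResult
        from afgtt.synthetic import evidence_for

        rec = record_factory(labs=[LabResult(analyte="K", value=2.5, day=1)])
        screen = screen_cohort(Cohort(records=[rec]), default_trigger_set())
        assert screen.n_hits == 1
        ades = adjudicate_cohort(
            screen, {("P1", "L6"): evidence_for("L6", "unlikely", 1)}
        )
        assert ades == []
        # without any evidence the hit is likewise a false positive
        assert adjudicate_cohort(screen, {}) == []

    def test_dangling_evidence_key_is_error(self, study_screen):
        from afgtt.synthetic import evidence_for

        with pytest.raises(AdjudicationError, match="non-existent"):
            adjudicate_cohort(
                study_screen, {("GHOST", "L6"): evidence_for("L6", "possible", 2)}
            )
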