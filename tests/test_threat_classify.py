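import itertools

import pytest

from threatminer import (
    Category,
    Cue,
    CurationEntry,
    Mechanism,
    Severity,
    TaxonClass,
    TaxonRecord,
    Verdict,
    annotate,
    apply_review,
    classify_severity,
    tag_threat_types,
)
from threatminer.keyword_screen import MatchResult
from threatminer.threat_classify import ConfirmedRecord, MissingCurationError
from threatminer.types import DIRECT_IMPACT_CUES


def _record(tid, cls=TaxonClass.BIRD, cat=Category.EN):
    return TaxonRecord(
        taxon_id=tid,
        scientific_name="G s",
        taxon_class=cls,
        family="F",
        category=cat,
        threats_text="pigs",
        units=frozenset({"US"}),
    )


def _flag(tid):
    return MatchResult(taxon_id=tid, hits=())  # hits unused by review


# -- review ------------------------------------------------------------------


def test_false_positives_are_removed():
    records = {f"T{i}": _record(f"T{i}") for i in range(1, 6)}
    flagged = [_flag(t) for t in records]
    curation = {
        "T1": CurationEntry("T1", Verdict.CONFIRM, frozenset({Cue.CONSUMPTION})),
        "T2": CurationEntry("T2", Verdict.FALSE_POSITIVE),
        "T3": CurationEntry("T3", Verdict.CONFIRM, frozenset({Cue.DIRECT_PREDATION})),
        "T4": CurationEntry("T4", Verdict.FALSE_POSITIVE),
        "T5": CurationEntry("T5", Verdict.CONFIRM, frozenset({Cue.DISEASE})),
    }
    confirmed = apply_review(flagged, records, curation)
    assert {c.record.taxon_id for c in confirmed} == {"T1", "T3", "T5"}


@pytest.mark.parametrize(
    "cues",
    [
        {Cue.HUNTING_CATALYZED},
        {Cue.DOMESTIC_NOT_FREE_RANGING},
        {Cue.HUNTING_CATALYZED, Cue.DOMESTIC_NOT_FREE_RANGING},
    ],
)
def test_out_of_scope_mentions_are_noted_but_excluded(cues):
    records = {"T1": _record("T1")}
    curation = {"T1": CurationEntry("T1", Verdict.CONFIRM, frozenset(cues))}
    assert apply_review([_flag("T1")], records, curation) == []


def test_exclusion_cue_alongside_real_evidence_keeps_the_record():
    records = {"T1": _record("T1")}
    curation = {
        "T1": CurationEntry(
            "T1", Verdict.CONFIRM, frozenset({Cue.HUNTING_CATALYZED, Cue.DIRECT_PREDATION})
        )
    }
    (confirmed,) = apply_review([_flag("T1")], records, curation)
    assert confirmed.cues == frozenset({Cue.DIRECT_PREDATION})


def test_strict_mode_errors_on_missing_curation_naming_ids():
    records = {"T1": _record("T1"), "T2": _record("T2")}
    curation = {"T1": CurationEntry("T1", Verdict.CONFIRM, frozenset({Cue.DISEASE}))}
    with pytest.raises(MissingCurationError, match="T2"):
        apply_review([_flag("T1"), _flag("T2")], records, curation, strict=True)
    # lenient mode drops the unreviewed record instead
    confirmed = apply_review([_flag("T1"), _flag("T2")], records, curation, strict=False)
    assert [c.record.taxon_id for c in confirmed] == ["T1"]


# -- severity rules ----------------------------------------------------------


@pytest.mark.parametrize("category", list(Category))
@pytest.mark.parametrize("grade", list(Severity))
def test_stated_grade_always_wins(category, grade):
    assert classify_severity(category, {Cue.HABITAT_DISTURBANCE}, grade) is grade
    assert classify_severity(category, {Cue.OVERLAP_ONLY}, grade) is grade


@pytest.mark.parametrize("category", list(Category))
def test_overlap_only_evidence_grades_as_potential(category):
    assert classify_severity(category, {Cue.OVERLAP_ONLY}, None) is Severity.POTENTIAL


@pytest.mark.parametrize("category", [Category.EX, Category.EW, Category.CR])
@pytest.mark.parametrize("cue", sorted(DIRECT_IMPACT_CUES, key=lambda c: c.value))
def test_any_direct_mention_is_major_for_highest_risk_taxa(category, cue):
    assert classify_severity(category, {cue}, None) is Severity.MAJOR


@pytest.mark.parametrize("category", [Category.LC, Category.NT])
@pytest.mark.parametrize("cue", sorted(DIRECT_IMPACT_CUES, key=lambda c: c.value))
def test_least_concern_and_near_threatened_default_to_minor(category, cue):
    assert classify_severity(category, {cue}, None) is Severity.MINOR


@pytest.mark.parametrize("category", [Category.EN, Category.VU, Category.DD])
def test_mid_risk_taxa_need_direct_evidence_for_major(category):
    for cue in DIRECT_IMPACT_CUES:
        assert classify_severity(category, {cue}, None) is Severity.MAJOR
        # overlap evidence alongside direct evidence does not demote
        assert classify_severity(category, {cue, Cue.OVERLAP_ONLY}, None) is Severity.MAJOR
    assert classify_severity(category, frozenset(), None) is Severity.POTENTIAL


def test_stated_minor_overrides_critically_endangered_default():
    assert (
        classify_severity(Category.CR, {Cue.HABITAT_DISTURBANCE}, Severity.MINOR)
        is Severity.MINOR
    )


def test_severity_is_deterministic_and_total_over_cue_combinations():
    """Every (category, cue subset, grade) combination yields exactly one
    severity, identical on repeated evaluation."""
    analysis_cues = sorted(DIRECT_IMPACT_CUES | {Cue.OVERLAP_ONLY}, key=lambda c: c.value)
    for category in Category:
        for r in range(0, 3):
            for combo in itertools.combinations(analysis_cues, r):
                for grade in [None, *Severity]:
                    first = classify_severity(category, frozenset(combo), grade)
                    assert first in set(Severity)
                    assert classify_severity(category, frozenset(combo), grade) is first


# -- mechanism rules ---------------------------------------------------------


@pytest.mark.parametrize(
    "cls,cues,expected",
    [
        # plant consumption is both predation and disturbance
        (TaxonClass.PLANT, {Cue.CONSUMPTION}, {Mechanism.PREDATION, Mechanism.DISTURBANCE}),
        # animal consumption is predation only
        (TaxonClass.MAMMAL, {Cue.CONSUMPTION}, {Mechanism.PREDATION}),
        # nest digging for herpetofauna and birds is both
        (TaxonClass.REPTILE, {Cue.NEST_DIGGING}, {Mechanism.PREDATION, Mechanism.DISTURBANCE}),
        (TaxonClass.AMPHIBIAN, {Cue.NEST_DIGGING}, {Mechanism.PREDATION, Mechanism.DISTURBANCE}),
        (TaxonClass.BIRD, {Cue.NEST_DIGGING}, {Mechanism.PREDATION, Mechanism.DISTURBANCE}),
        # one-to-one cues
        (TaxonClass.MAMMAL, {Cue.HYBRIDIZATION}, {Mechanism.HYBRIDIZATION}),
        (TaxonClass.MAMMAL, {Cue.DISEASE}, {Mechanism.DISEASE_RISK}),
        (TaxonClass.INVERTEBRATE, {Cue.DIRECT_PREDATION}, {Mechanism.PREDATION}),
        (TaxonClass.PLANT, {Cue.HABITAT_DISTURBANCE}, {Mechanism.DISTURBANCE}),
        (TaxonClass.MAMMAL, {Cue.COMPETITION}, {Mechanism.COMPETITION}),
        # bare overlap defaults to disturbance
        (TaxonClass.BIRD, {Cue.OVERLAP_ONLY}, {Mechanism.DISTURBANCE}),
        # compound cue sets union their mechanisms
        (
            TaxonClass.PLANT,
            {Cue.CONSUMPTION, Cue.HABITAT_DISTURBANCE},
            {Mechanism.PREDATION, Mechanism.DISTURBANCE},
        ),
    ],
)
def test_cue_to_mechanism_mapping(cls, cues, expected):
    assert tag_threat_types(cls, cues) == frozenset(expected)


def test_every_class_and_cue_combination_yields_a_mechanism():
    analysis_cues = sorted(DIRECT_IMPACT_CUES | {Cue.OVERLAP_ONLY}, key=lambda c: c.value)
    for cls in TaxonClass:
        for r in (1, 2):
            for combo in itertools.combinations(analysis_cues, r):
                mechs = tag_threat_types(cls, frozenset(combo))
                assert mechs and mechs <= set(Mechanism)


def test_empty_cues_are_rejected():
    with pytest.raises(ValueError):
        tag_threat_types(TaxonClass.BIRD, frozenset())


def test_annotate_builds_consistent_annotations():
    confirmed = [
        ConfirmedRecord(
            record=_record("T1", cls=TaxonClass.PLANT, cat=Category.CR),
            cues=frozenset({Cue.CONSUMPTION}),
            stated_grade=None,
        ),
        ConfirmedRecord(
            record=_record("T2", cls=TaxonClass.BIRD, cat=Category.LC),
            cues=frozenset({Cue.NEST_DIGGING}),
            stated_grade=None,
        ),
    ]
    a1, a2 = annotate(confirmed)
    assert a1.severity is Severity.MAJOR
    assert a1.mechanisms == {Mechanism.PREDATION, Mechanism.DISTURBANCE}
    assert a2.severity is Severity.MINOR
    assert all(a.pig_threatened for a in (a1, a2))
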