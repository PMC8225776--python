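"""Rule-based severity and threat-mechanism classification.

A *threat* is any process that impacted, is impacting, or may impact the
assessed taxon.  Confirmed records are graded major / minor / potential
from three inputs: the curator's stated grade (when the narrative carried
enough detail to grade the threat directly), the evidence cues, and the
taxon's Red List category.  Mechanisms are mapped from cues, with two
compound rules: consumption of a plant is both predation and disturbance
(it removes individuals and restructures vegetation), and nest digging for
reptiles, amphibians and ground-nesting birds is likewise both (direct
mortality plus destruction of the nest site).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .keyword_screen import MatchResult
from .types import (
    Category,
    Cue,
    CurationEntry,
    DIRECT_IMPACT_CUES,
    EXCLUSION_CUES,
    Mechanism,
    Severity,
    TaxonClass,
    TaxonRecord,
    ThreatAnnotation,
    Verdict,
)

logger = logging.getLogger(__name__)


class MissingCurationError(ValueError):
    """Strict mode: flagged records lack curation entries."""

    def __init__(self, taxon_ids: Sequence[str]):
        self.taxon_ids = list(taxon_ids)
        super().__init__(
            f"{len(self.taxon_ids)} flagged record(s) have no curation entry: "
            + ", ".join(sorted(self.taxon_ids))
        )


@dataclass(frozen=True)
class ConfirmedRecord:
    """A flagged record that survived manual review, with its evidence."""

    record: TaxonRecord
    cues: frozenset[Cue]
    stated_grade: Optional[Severity]


def apply_review(
    flagged: Sequence[MatchResult],
    records_by_id: Mapping[str, TaxonRecord],
    curation: Mapping[str, CurationEntry],
    strict: bool = True,
) -> list[ConfirmedRecord]:
    """Resolve the review queue against curation judgements.

    Removes false positives, and removes records whose only evidence is a
    hunting-catalyzed threat or a domestic (not free-ranging) animal —
    those mentions are noted but not part of the analysis.  In strict mode
    a flagged record without a curation entry is an error; in lenient mode
    it is dropped with a warning.
    """
    missing = [m.taxon_id for m in flagged if m.taxon_id not in curation]
    if missing:
        if strict:
            raise MissingCurationError(missing)
        logger.warning(
            "dropping %d flagged record(s) without curation: %s",
            len(missing),
            ", ".join(sorted(missing)),
        )
    confirmed: list[ConfirmedRecord] = []
    for match in flagged:
        entry = curation.get(match.taxon_id)
        if entry is None or entry.verdict is Verdict.FALSE_POSITIVE:
            continue
        if not entry.cues:
            raise ValueError(
                f"curation confirms {match.taxon_id!r} but carries no evidence cues"
            )
        if entry.cues <= EXCLUSION_CUES:
            continue  # noted but not included
        confirmed.append(
            ConfirmedRecord(
                record=records_by_id[match.taxon_id],
                cues=entry.cues - EXCLUSION_CUES,
                stated_grade=entry.stated_grade,
            )
        )
    return confirmed


def classify_severity(
    category: Category,
    cues: frozenset[Cue] | set[Cue],
    stated_grade: Optional[Severity] = None,
) -> Severity:
    """Grade a confirmed threat as major, minor or potential.

    Rule order:

    1. A stated grade wins: the narrative carried enough detail to grade
       the threat directly.
    2. Overlap-only evidence (threat inferred from co-occurring
       distributions, no direct impact documented) grades as potential.
    3. Extinct, extinct-in-the-wild and critically endangered taxa: any
       threat mention grades as major.
    4. Least-concern taxa default to minor, as do secondary threats to
       near-threatened taxa.
    5. Endangered, vulnerable and data-deficient taxa grade as major when
       any direct-impact cue is present, potential otherwise.
    """
    cues = frozenset(cues)
    if stated_grade is not None:
        return stated_grade
    if cues and cues <= {Cue.OVERLAP_ONLY}:
        return Severity.POTENTIAL
    if category in (Category.EX, Category.EW, Category.CR):
        return Severity.MAJOR
    if category in (Category.LC, Category.NT):
        return Severity.MINOR
    # EN, VU, DD
    if cues & DIRECT_IMPACT_CUES:
        return Severity.MAJOR
    return Severity.POTENTIAL


#: taxa whose nests are dug up suffer both direct mortality and nest-site loss
_NEST_CLASSES = frozenset({TaxonClass.REPTILE, TaxonClass.AMPHIBIAN, TaxonClass.BIRD})

_SIMPLE_CUE_MECHANISMS: dict[Cue, frozenset[Mechanism]] = {
    Cue.DIRECT_PREDATION: frozenset({Mechanism.PREDATION}),
    Cue.HABITAT_DISTURBANCE: frozenset({Mechanism.DISTURBANCE}),
    Cue.DISEASE: frozenset({Mechanism.DISEASE_RISK}),
    Cue.COMPETITION: frozenset({Mechanism.COMPETITION}),
    Cue.HYBRIDIZATION: frozenset({Mechanism.HYBRIDIZATION}),
}


def tag_threat_types(
    taxon_class: TaxonClass, cues: frozenset[Cue] | set[Cue]
) -> frozenset[Mechanism]:
    """Map evidence cues to the mechanism categories the taxon is tallied
    under: predation, disturbance, disease risk, competition, hybridization.

    Overlap-only evidence with no other cue defaults to disturbance — the
    broadest impact of an ecosystem engineer whose mere presence alters
    habitat — unless the curator supplied a more specific cue.
    """
    cues = frozenset(cues) - EXCLUSION_CUES
    if not cues:
        raise ValueError("cannot tag threat types without cues")
    mechanisms: set[Mechanism] = set()
    for cue in cues:
        if cue in _SIMPLE_CUE_MECHANISMS:
            mechanisms |= _SIMPLE_CUE_MECHANISMS[cue]
        elif cue is Cue.CONSUMPTION:
            if taxon_class is TaxonClass.PLANT:
                mechanisms |= {Mechanism.PREDATION, Mechanism.DISTURBANCE}
            else:
                mechanisms.add(Mechanism.PREDATION)
        elif cue is Cue.NEST_DIGGING:
            if taxon_class in _NEST_CLASSES:
                mechanisms |= {Mechanism.PREDATION, Mechanism.DISTURBANCE}
            else:
                mechanisms.add(Mechanism.DISTURBANCE)
    if not mechanisms and Cue.OVERLAP_ONLY in cues:
        mechanisms.add(Mechanism.DISTURBANCE)
    if not mechanisms:
        raise ValueError(f"cues {sorted(c.value for c in cues)} yield no mechanism")
    return frozenset(mechanisms)


def annotate(confirmed: Iterable[ConfirmedRecord]) -> list[ThreatAnnotation]:
    """Build one threat annotation per confirmed record."""
    annotations = []
    for item in confirmed:
        annotations.append(
            ThreatAnnotation(
                taxon_id=item.record.taxon_id,
                pig_threatened=True,
                severity=classify_severity(
                    item.record.category, item.cues, item.stated_grade
                ),
                mechanisms=tag_threat_types(item.record.taxon_class, item.cues),
                cues=item.cues,
            )
        )
    return annotations
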