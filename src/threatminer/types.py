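"""Core domain types for Red-List threat assessment.

The unit of analysis is a *taxon record*: one Red List listing (usually a
species, sometimes a subspecies or variety) carrying an extinction-risk
category, occurrence units (countries or finer administrative codes), and
free-text threat and range narratives.  A *curation entry* encodes the
two-reviewer manual reading of a flagged narrative as a verdict plus a set
of evidence cues; a *threat annotation* is the per-taxon outcome of the
classification rules.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class TaxonClass(str, enum.Enum):
    """Broad taxonomic class used for reporting groups."""

    REPTILE = "reptile"
    AMPHIBIAN = "amphibian"
    BIRD = "bird"
    MAMMAL = "mammal"
    PLANT = "plant"
    INVERTEBRATE = "invertebrate"


class Category(str, enum.Enum):
    """IUCN Red List extinction-risk category."""

    EX = "EX"
    EW = "EW"
    CR = "CR"
    EN = "EN"
    VU = "VU"
    NT = "NT"
    LC = "LC"
    DD = "DD"


class RangeStatus(str, enum.Enum):
    """Focal-species range status of an administrative unit."""

    NATIVE = "native"
    NONNATIVE = "nonnative"
    POTENTIAL = "potential"
    ABSENT = "absent"


class Severity(str, enum.Enum):
    """Three-level threat grading."""

    MAJOR = "major"
    MINOR = "minor"
    POTENTIAL = "potential"


class Mechanism(str, enum.Enum):
    """Process by which the focal species threatens a taxon."""

    PREDATION = "predation"
    DISTURBANCE = "disturbance"
    DISEASE_RISK = "disease_risk"
    COMPETITION = "competition"
    HYBRIDIZATION = "hybridization"


class Cue(str, enum.Enum):
    """Evidence cue recorded by a curator from the threat narrative."""

    DIRECT_PREDATION = "direct_predation"
    CONSUMPTION = "consumption"
    HABITAT_DISTURBANCE = "habitat_disturbance"
    NEST_DIGGING = "nest_digging"
    DISEASE = "disease"
    COMPETITION = "competition"
    HYBRIDIZATION = "hybridization"
    OVERLAP_ONLY = "overlap_only"
    HUNTING_CATALYZED = "hunting_catalyzed"
    DOMESTIC_NOT_FREE_RANGING = "domestic_not_free_ranging"


class Verdict(str, enum.Enum):
    CONFIRM = "confirm"
    FALSE_POSITIVE = "false_positive"


#: cues that record direct evidence of impact (as opposed to inference from
#: overlapping distribution or out-of-scope mentions)
DIRECT_IMPACT_CUES: frozenset[Cue] = frozenset(
    {
        Cue.DIRECT_PREDATION,
        Cue.CONSUMPTION,
        Cue.HABITAT_DISTURBANCE,
        Cue.NEST_DIGGING,
        Cue.DISEASE,
        Cue.COMPETITION,
        Cue.HYBRIDIZATION,
    }
)

#: cues that, when they are the only evidence, exclude the record from the
#: analysis (mentions noted but not attributable to free-ranging wild animals)
EXCLUSION_CUES: frozenset[Cue] = frozenset(
    {Cue.HUNTING_CATALYZED, Cue.DOMESTIC_NOT_FREE_RANGING}
)


@dataclass(frozen=True)
class TaxonRecord:
    """One Red List listing.

    ``units`` are opaque administrative-unit codes matched exactly against
    the range and region tables.  ``endemic_to`` is a structured stand-in
    for an endemism statement in the range narrative: the region the taxon
    is actually restricted to, used to prune cross-listings under governing
    continental countries.
    """

    taxon_id: str
    scientific_name: str
    taxon_class: TaxonClass
    family: str
    category: Category
    threats_text: str = ""
    range_text: str = ""
    units: frozenset[str] = field(default_factory=frozenset)
    endemic_to: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.units and self.category is not Category.EX:
            raise ValueError(
                f"taxon {self.taxon_id!r}: units may be empty only for EX records"
            )


@dataclass(frozen=True)
class PigRangeMap:
    """Administrative unit -> focal-species range status.

    Units absent from the map are treated as ``absent``.
    """

    status_by_unit: dict[str, RangeStatus]

    def status(self, unit: str) -> RangeStatus:
        return self.status_by_unit.get(unit, RangeStatus.ABSENT)


@dataclass(frozen=True)
class RegionTable:
    """Administrative unit -> region, and region -> island/continental."""

    region_by_unit: dict[str, str]
    system_by_region: dict[str, str]  # region id -> "island" | "continental"

    def __post_init__(self) -> None:
        for region, system in self.system_by_region.items():
            if system not in ("island", "continental"):
                raise ValueError(f"region {region!r}: bad system class {system!r}")
        missing = {r for r in self.region_by_unit.values()} - set(self.system_by_region)
        if missing:
            raise ValueError(f"regions without a system class: {sorted(missing)}")

    def is_island(self, region: str) -> bool:
        return self.system_by_region[region] == "island"

    @property
    def island_regions(self) -> set[str]:
        return {r for r, s in self.system_by_region.items() if s == "island"}

    @property
    def continental_regions(self) -> set[str]:
        return {r for r, s in self.system_by_region.items() if s == "continental"}


@dataclass(frozen=True)
class CurationEntry:
    """One manual-review judgement for a flagged taxon."""

    taxon_id: str
    verdict: Verdict
    cues: frozenset[Cue] = field(default_factory=frozenset)
    stated_grade: Optional[Severity] = None


@dataclass(frozen=True)
class ThreatAnnotation:
    """Per-taxon classification outcome.

    Invariants: a threatened taxon has a severity and at least one
    mechanism; a record whose only cues are exclusion cues is never
    threatened.
    """

    taxon_id: str
    pig_threatened: bool
    severity: Optional[Severity] = None
    mechanisms: frozenset[Mechanism] = field(default_factory=frozenset)
    cues: frozenset[Cue] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.pig_threatened:
            if self.severity is None:
                raise ValueError(f"{self.taxon_id}: threatened but no severity")
            if not self.mechanisms:
                raise ValueError(f"{self.taxon_id}: threatened but no mechanisms")
        if self.cues and self.cues <= EXCLUSION_CUES and self.pig_threatened:
            raise ValueError(
                f"{self.taxon_id}: exclusion-only cues cannot mark a threatened taxon"
            )


@dataclass(frozen=True)
class RangeOverlap:
    """How a taxon's units overlap the focal-species range."""

    taxon_id: str
    in_native: bool
    in_nonnative: bool
    in_potential_only: bool

    def __post_init__(self) -> None:
        if self.in_potential_only and (self.in_native or self.in_nonnative):
            raise ValueError(
                f"{self.taxon_id}: potential-only contradicts native/non-native flags"
            )

    @property
    def any_overlap(self) -> bool:
        return self.in_native or self.in_nonnative or self.in_potential_only
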