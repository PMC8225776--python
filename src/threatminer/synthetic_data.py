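"""Seeded generator of Red-List-style corpora with ground truth.

The generator emulates the statistical structure of a real Red List
export as seen by this pipeline: a mix of taxonomic groups, a minority of
records whose threat narrative mentions the focal species through the
keyword forms the screen looks for, distractor tokens that trip the
wildcard patterns without being about pigs ("pigeon", "pigment",
"boardwalk", "hogweed"), out-of-scope mentions (hunting catalyzed by pig
presence, penned domestic animals), category-skewed threat rates,
compound threat types, and island endemics cross-listed under the
continental country that governs the island.

Everything is drawn from a single pseudo-random stream seeded from the
config; per taxon the draw order is group, category, geography, threat
flag, cues, narrative, so the same seed always yields byte-identical
output files.  Ground truth is derived by independent inline logic (not
by calling the pipeline), so end-to-end agreement between the pipeline's
report and :meth:`GroundTruth.summary_dict` is a genuine dual-route
check, not a tautology.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Optional

import numpy as np

from . import corpus_io
from .geography import (
    DEFAULT_ISLAND_REGIONS,
    DEFAULT_UNITS_BY_REGION,
    _GOVERNING_CONTINENTAL_UNIT,
    default_region_table,
)
from .types import (
    Category,
    Cue,
    CurationEntry,
    PigRangeMap,
    RangeStatus,
    RegionTable,
    Severity,
    TaxonClass,
    TaxonRecord,
    Verdict,
)


class ConfigError(ValueError):
    """A simulation config violates a probability or rate constraint."""


_CLASSES = tuple(TaxonClass)

#: Default group mix: plants and invertebrates dominate assessed terrestrial
#: taxa, vertebrate classes are smaller.
_DEFAULT_GROUP_MIX = {
    TaxonClass.PLANT: 0.34,
    TaxonClass.INVERTEBRATE: 0.20,
    TaxonClass.BIRD: 0.14,
    TaxonClass.REPTILE: 0.11,
    TaxonClass.AMPHIBIAN: 0.11,
    TaxonClass.MAMMAL: 0.10,
}

#: Overall Red List category mix for assessed terrestrial taxa.
_DEFAULT_CATEGORY_MIX = {
    Category.LC: 0.46,
    Category.NT: 0.11,
    Category.VU: 0.12,
    Category.EN: 0.10,
    Category.CR: 0.09,
    Category.DD: 0.08,
    Category.EX: 0.03,
    Category.EW: 0.01,
}

#: Multiplier on the per-group threat rate by category: threat reporting is
#: denser for at-risk taxa, so the threatened subset skews CR/EN.
_CATEGORY_THREAT_WEIGHT = {
    Category.EX: 2.0,
    Category.EW: 2.0,
    Category.CR: 4.0,
    Category.EN: 3.0,
    Category.VU: 1.5,
    Category.NT: 0.8,
    Category.LC: 0.5,
    Category.DD: 0.8,
}

#: Per-class distribution over evidence-cue sets for threatened taxa.
#: Disturbance- and predation-type cues dominate, with rarer disease,
#: competition and hybridization mentions concentrated in mammals.
_DEFAULT_MECHANISM_PROFILES: dict[TaxonClass, dict[tuple[Cue, ...], float]] = {
    TaxonClass.PLANT: {
        (Cue.CONSUMPTION,): 0.45,
        (Cue.HABITAT_DISTURBANCE,): 0.30,
        (Cue.CONSUMPTION, Cue.HABITAT_DISTURBANCE): 0.15,
        (Cue.OVERLAP_ONLY,): 0.10,
    },
    TaxonClass.REPTILE: {
        (Cue.NEST_DIGGING,): 0.35,
        (Cue.DIRECT_PREDATION,): 0.30,
        (Cue.HABITAT_DISTURBANCE,): 0.20,
        (Cue.DIRECT_PREDATION, Cue.HABITAT_DISTURBANCE): 0.05,
        (Cue.OVERLAP_ONLY,): 0.10,
    },
    TaxonClass.AMPHIBIAN: {
        (Cue.NEST_DIGGING,): 0.25,
        (Cue.DIRECT_PREDATION,): 0.25,
        (Cue.HABITAT_DISTURBANCE,): 0.35,
        (Cue.OVERLAP_ONLY,): 0.15,
    },
    TaxonClass.BIRD: {
        (Cue.NEST_DIGGING,): 0.40,
        (Cue.DIRECT_PREDATION,): 0.25,
        (Cue.HABITAT_DISTURBANCE,): 0.25,
        (Cue.OVERLAP_ONLY,): 0.10,
    },
    TaxonClass.MAMMAL: {
        (Cue.COMPETITION,): 0.30,
        (Cue.DISEASE,): 0.20,
        (Cue.HYBRIDIZATION,): 0.15,
        (Cue.DIRECT_PREDATION,): 0.20,
        (Cue.OVERLAP_ONLY,): 0.15,
    },
    TaxonClass.INVERTEBRATE: {
        (Cue.DIRECT_PREDATION,): 0.45,
        (Cue.HABITAT_DISTURBANCE,): 0.40,
        (Cue.DIRECT_PREDATION, Cue.HABITAT_DISTURBANCE): 0.05,
        (Cue.OVERLAP_ONLY,): 0.10,
    },
}

#: Default focal-species range status for every unit of the default region
#: table.  Native: Eurasian units.  Non-native: the Americas, Oceania and
#: most islands.  A few units are only potentially occupied or unoccupied.
DEFAULT_PIG_STATUS: dict[str, RangeStatus] = {
    # native range (Eurasia)
    **{u: RangeStatus.NATIVE for u in ("FR", "DE", "ES", "IT", "GB", "PL")},
    **{u: RangeStatus.NATIVE for u in ("CN", "JP", "KR")},
    **{u: RangeStatus.NATIVE for u in ("IN", "PK", "LK", "NP")},
    **{u: RangeStatus.NATIVE for u in ("ID", "MY", "TH", "VN", "PH")},
    **{u: RangeStatus.NATIVE for u in ("KZ", "UZ", "MN")},
    # non-native range (introductions)
    **{u: RangeStatus.NONNATIVE for u in ("US", "CA", "MX")},
    **{u: RangeStatus.NONNATIVE for u in ("BR", "AR", "CO", "CL", "EC")},
    **{u: RangeStatus.NONNATIVE for u in ("ZA", "KE", "TZ")},
    **{u: RangeStatus.NONNATIVE for u in ("AU", "NZ")},
    **{u: RangeStatus.NONNATIVE for u in ("US-HI", "PF", "WS")},
    **{u: RangeStatus.NONNATIVE for u in ("FJ", "NC", "PG", "FM", "SB")},
    **{u: RangeStatus.NONNATIVE for u in ("EC-GAL",)},
    **{u: RangeStatus.NONNATIVE for u in ("CU", "JM", "PR", "DO")},
    **{u: RangeStatus.NONNATIVE for u in ("MG", "MU", "PT-AZ", "ES-CN")},
    # potentially occurring
    "TO": RangeStatus.POTENTIAL,
    "KM": RangeStatus.POTENTIAL,
    # unoccupied
    "CV": RangeStatus.ABSENT,
    "SC": RangeStatus.ABSENT,
    "ET": RangeStatus.ABSENT,
    "NG": RangeStatus.ABSENT,
}


@dataclass(frozen=True)
class SimConfig:
    """Conditions of a synthetic corpus.

    Probability vectors must sum to 1 (tolerance 1e-9); all rates lie in
    [0, 1].  ``threat_rate_by_group`` is the base chance a record of a
    class is pig-threatened, modulated upward for at-risk categories; the
    realised threatened fraction sits around 10-15%, a clear minority, so
    that the screen-and-curate workflow is exercised on realistic class
    imbalance.
    """

    n_taxa: int = 500
    seed: int = 0
    group_mix: dict[TaxonClass, float] = field(
        default_factory=lambda: dict(_DEFAULT_GROUP_MIX)
    )
    category_mix: dict[Category, float] = field(
        default_factory=lambda: dict(_DEFAULT_CATEGORY_MIX)
    )
    threat_rate_by_group: dict[TaxonClass, float] = field(
        default_factory=lambda: {
            TaxonClass.PLANT: 0.12,
            TaxonClass.REPTILE: 0.12,
            TaxonClass.AMPHIBIAN: 0.10,
            TaxonClass.BIRD: 0.10,
            TaxonClass.MAMMAL: 0.06,
            TaxonClass.INVERTEBRATE: 0.08,
        }
    )
    severity_mix: tuple[float, float, float] = (0.59, 0.21, 0.20)  # major/minor/potential
    mechanism_profiles: dict[TaxonClass, dict[tuple[Cue, ...], float]] = field(
        default_factory=lambda: {
            cls: dict(profile) for cls, profile in _DEFAULT_MECHANISM_PROFILES.items()
        }
    )
    distractor_rate: float = 0.06
    excluded_mention_rate: float = 0.02
    island_endemic_rate: float = 0.30
    cross_listing_rate: float = 0.50
    region_count: int = 17

    def __post_init__(self) -> None:
        def check_vector(vec, name):
            if abs(sum(vec) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1, got {sum(vec)!r}")
            if any(p < 0 for p in vec):
                raise ConfigError(f"{name} has negative entries")

        check_vector(self.group_mix.values(), "group_mix")
        check_vector(self.category_mix.values(), "category_mix")
        check_vector(self.severity_mix, "severity_mix")
        for cls, profile in self.mechanism_profiles.items():
            check_vector(profile.values(), f"mechanism_profiles[{cls.value}]")
        for name in (
            "distractor_rate",
            "excluded_mention_rate",
            "island_endemic_rate",
            "cross_listing_rate",
        ):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {rate!r}")
        for cls, rate in self.threat_rate_by_group.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"threat_rate_by_group[{cls.value}] out of [0, 1]")
        if self.n_taxa < 0:
            raise ConfigError("n_taxa must be non-negative")
        if self.region_count != 17:
            raise ConfigError("only the default 17-region scheme is supported")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SimConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key, value in raw.items():
            if key == "group_mix":
                value = {TaxonClass(k): float(v) for k, v in value.items()}
            elif key == "category_mix":
                value = {Category(k): float(v) for k, v in value.items()}
            elif key == "threat_rate_by_group":
                value = {TaxonClass(k): float(v) for k, v in value.items()}
            elif key == "severity_mix":
                value = tuple(float(v) for v in value)
            elif key == "mechanism_profiles":
                value = {
                    TaxonClass(cls): {
                        tuple(Cue(c) for c in cues.split(";")): float(p)
                        for cues, p in profile.items()
                    }
                    for cls, profile in value.items()
                }
            kwargs[key] = value
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# narrative templates


_CUE_SENTENCES: dict[Cue, str] = {
    Cue.DIRECT_PREDATION: "Direct predation by feral pigs (Sus scrofa) reduces survival of juveniles and adults.",
    Cue.CONSUMPTION: "Browsing and consumption by feral pigs suppresses recruitment.",
    Cue.HABITAT_DISTURBANCE: "Rooting and trampling by wild boar degrade habitat structure across the range.",
    Cue.NEST_DIGGING: "Nests are dug up and depredated by feral hogs during the breeding season.",
    Cue.DISEASE: "Free-ranging swine act as reservoirs of pathogens transmissible to this species.",
    Cue.COMPETITION: "Competition with wild pigs for food resources limits population growth.",
    Cue.HYBRIDIZATION: "Hybridization with wild boar erodes the genetic integrity of remaining populations.",
    Cue.OVERLAP_ONLY: "Feral pigs occur throughout the range of this species and may pose a threat.",
    Cue.HUNTING_CATALYZED: "Hunters drawn to the area by wild pigs cause incidental mortality and disturbance.",
    Cue.DOMESTIC_NOT_FREE_RANGING: "Domestic pigs are kept in nearby settlements but are not free-ranging.",
}

_FILLER_SENTENCES = (
    "Habitat loss from logging and agricultural expansion is ongoing.",
    "Predation by introduced rats and cats has been recorded.",
    "Drought linked to a changing climate reduces breeding success.",
    "Collection for the horticultural trade affects some subpopulations.",
    "Fire regimes have shifted markedly in recent decades.",
    "Grazing by goats degrades remnant vegetation.",
    "Urban development continues to fragment remaining habitat.",
    "Invasive grasses alter understorey composition.",
)

#: sentences containing tokens that trip the wildcard patterns without
#: being about the focal species
_DISTRACTOR_SENTENCES = (
    "Pigeons compete for the few available nesting cavities.",
    "Pigment loss has been observed in stressed individuals.",
    "Boardwalk construction for tourism fragments the habitat.",
    "Invasive hogweed displaces native vegetation along watercourses.",
)

_EPITHETS = (
    "montana", "sylvestris", "insularis", "robusta", "gracilis", "australis",
    "borealis", "maculata", "elegans", "minor", "grandis", "obscura",
)
_GENERA = {
    TaxonClass.PLANT: ("Cyanea", "Pritchardia", "Bidens", "Clermontia", "Schiedea"),
    TaxonClass.REPTILE: ("Emoia", "Chelonoidis", "Brachylophus", "Oligosoma"),
    TaxonClass.AMPHIBIAN: ("Litoria", "Philoria", "Leptodactylus", "Eleutherodactylus"),
    TaxonClass.BIRD: ("Pterodroma", "Gallicolumba", "Todiramphus", "Acrocephalus"),
    TaxonClass.MAMMAL: ("Sus", "Babyrousa", "Pteropus", "Zyzomys"),
    TaxonClass.INVERTEBRATE: ("Partula", "Achatinella", "Placostylus", "Deinacrida"),
}
_FAMILIES = {
    TaxonClass.PLANT: ("Campanulaceae", "Arecaceae", "Asteraceae", "Orchidaceae"),
    TaxonClass.REPTILE: ("Scincidae", "Testudinidae", "Iguanidae"),
    TaxonClass.AMPHIBIAN: ("Myobatrachidae", "Hylidae", "Leptodactylidae"),
    TaxonClass.BIRD: ("Procellariidae", "Columbidae", "Acrocephalidae"),
    TaxonClass.MAMMAL: ("Suidae", "Pteropodidae", "Muridae"),
    TaxonClass.INVERTEBRATE: ("Partulidae", "Achatinellidae", "Helicidae"),
}

_CONTINENTAL_REGIONS = tuple(
    r for r in DEFAULT_UNITS_BY_REGION if r not in DEFAULT_ISLAND_REGIONS
)


@dataclass(frozen=True)
class TruthRow:
    """Ground truth for one generated taxon."""

    taxon_id: str
    taxon_class: TaxonClass
    category: Category
    threatened: bool
    cues: frozenset[Cue]
    stated_grade: Optional[Severity]
    severity: Optional[Severity]
    mechanisms: frozenset[str]
    regions: frozenset[str]
    endemic_to: Optional[str]
    units: frozenset[str]
    flagged: bool  # narrative contains a token the screen will hit
    in_native: bool
    in_nonnative: bool
    in_potential_only: bool


@dataclass
class GroundTruth:
    """Per-taxon truth plus independently computed summary expectations."""

    rows: dict[str, TruthRow]
    regions: RegionTable

    @property
    def threatened_ids(self) -> set[str]:
        return {tid for tid, row in self.rows.items() if row.threatened}

    @property
    def flagged_ids(self) -> set[str]:
        return {tid for tid, row in self.rows.items() if row.flagged}

    def retained_ids(self) -> set[str]:
        """Taxa surviving the range filter, by direct re-derivation."""
        active_potential_units = {
            u
            for row in self.rows.values()
            if row.threatened
            for u in row.units
            if DEFAULT_PIG_STATUS.get(u) is RangeStatus.POTENTIAL
        }
        retained = set()
        for tid, row in self.rows.items():
            if row.in_native or row.in_nonnative:
                retained.add(tid)
            elif row.in_potential_only:
                potential = {
                    u
                    for u in row.units
                    if DEFAULT_PIG_STATUS.get(u) is RangeStatus.POTENTIAL
                }
                if potential & active_potential_units:
                    retained.add(tid)
        return retained

    def summary_dict(self) -> dict:
        """Expected report, recomputed with plain loops over the truth table.

        Mirrors :meth:`threatminer.summarize.SummaryReport.to_json_dict`
        field-for-field so pipeline output can be compared exactly.
        """
        retained = self.retained_ids()
        threatened = [
            row
            for tid, row in self.rows.items()
            if row.threatened and tid in retained
        ]
        group_names = {
            TaxonClass.PLANT: "plant",
            TaxonClass.REPTILE: "herpetofauna",
            TaxonClass.AMPHIBIAN: "herpetofauna",
            TaxonClass.BIRD: "bird",
            TaxonClass.MAMMAL: "mammal",
            TaxonClass.INVERTEBRATE: "invertebrate",
        }
        by_category = {c.value: 0 for c in Category}
        by_group = {g: 0 for g in ("plant", "herpetofauna", "bird", "invertebrate", "mammal")}
        by_mechanism = {m: 0 for m in ("predation", "disturbance", "disease_risk", "competition", "hybridization")}
        by_severity = {s.value: 0 for s in Severity}
        for row in threatened:
            by_category[row.category.value] += 1
            by_group[group_names[row.taxon_class]] += 1
            by_severity[row.severity.value] += 1
            for mech in row.mechanisms:
                by_mechanism[mech] += 1
        n_threatened = len(threatened)
        if n_threatened:
            severity_percent = {
                s.value: float(
                    Decimal(repr(100.0 * by_severity[s.value] / n_threatened)).quantize(
                        Decimal(1), rounding=ROUND_HALF_UP
                    )
                )
                for s in Severity
            }
        else:
            severity_percent = {s.value: 0.0 for s in Severity}

        # per-(region, group) cells over retained records
        assessed: dict[tuple[str, str], int] = {}
        thr_cells: dict[tuple[str, str], int] = {}
        threatened_ids = {row.taxon_id for row in threatened}
        for tid in retained:
            row = self.rows[tid]
            group = group_names[row.taxon_class]
            for region in row.regions:
                is_island = self.regions.system_by_region[region] == "island"
                if is_island and row.endemic_to != region:
                    continue
                key = (region, group)
                assessed[key] = assessed.get(key, 0) + 1
                if tid in threatened_ids:
                    thr_cells[key] = thr_cells.get(key, 0) + 1
        region_props = [
            {
                "region": region,
                "group": group,
                "threatened": thr_cells.get((region, group), 0),
                "assessed": n,
                "proportion": thr_cells.get((region, group), 0) / n,
            }
            for (region, group), n in sorted(assessed.items())
        ]

        def system_summary(system: str) -> dict:
            regions_in = sorted(
                r for r, s in self.regions.system_by_region.items() if s == system
            )
            out = {}
            for group in ("plant", "herpetofauna", "bird", "invertebrate", "mammal"):
                props = [
                    thr_cells.get((r, group), 0) / assessed[(r, group)]
                    for r in regions_in
                    if (r, group) in assessed
                ]
                if not props:
                    continue
                mean = sum(props) / len(props)
                if len(props) > 1:
                    sd = math.sqrt(
                        sum((p - mean) ** 2 for p in props) / (len(props) - 1)
                    )
                    defined = True
                else:
                    sd, defined = 0.0, False
                out[group] = {
                    "mean": mean,
                    "sd": sd,
                    "sd_defined": defined,
                    "n_regions": len(props),
                    "total_threatened": sum(
                        thr_cells.get((r, group), 0)
                        for r in regions_in
                        if (r, group) in assessed
                    ),
                }
            pooled, pooled_thr = [], 0
            for r in regions_in:
                tot = sum(
                    assessed[(r, g)]
                    for g in ("plant", "herpetofauna", "bird", "invertebrate", "mammal")
                    if (r, g) in assessed
                )
                if not tot:
                    continue
                thr = sum(
                    thr_cells.get((r, g), 0)
                    for g in ("plant", "herpetofauna", "bird", "invertebrate", "mammal")
                    if (r, g) in assessed
                )
                pooled.append(thr / tot)
                pooled_thr += thr
            if pooled:
                mean = sum(pooled) / len(pooled)
                if len(pooled) > 1:
                    sd = math.sqrt(
                        sum((p - mean) ** 2 for p in pooled) / (len(pooled) - 1)
                    )
                    defined = True
                else:
                    sd, defined = 0.0, False
                out["overall"] = {
                    "mean": mean,
                    "sd": sd,
                    "sd_defined": defined,
                    "n_regions": len(pooled),
                    "total_threatened": pooled_thr,
                }
            return out

        n_native = sum(1 for row in threatened if row.in_native)
        n_nonnative = sum(1 for row in threatened if row.in_nonnative)
        n_both = sum(1 for row in threatened if row.in_native and row.in_nonnative)
        n_overlap = sum(
            1 for row in threatened if row.in_native or row.in_nonnative
        )

        def comparator(island_only: bool) -> dict:
            counts = {"reptile": 0, "bird": 0, "mammal": 0}
            for row in threatened:
                if row.taxon_class.value not in counts:
                    continue
                if row.category in (Category.LC, Category.NT):
                    continue
                if island_only:
                    if row.endemic_to is None:
                        continue
                    if self.regions.system_by_region[row.endemic_to] != "island":
                        continue
                counts[row.taxon_class.value] += 1
            counts["total"] = sum(counts.values())
            return counts

        return {
            "n_threatened": n_threatened,
            "by_category": by_category,
            "by_group": by_group,
            "by_mechanism": by_mechanism,
            "by_severity": by_severity,
            "severity_percent": severity_percent,
            "concern_count": by_category["CR"] + by_category["EN"],
            "region_props": region_props,
            "island_summary": system_summary("island"),
            "continental_summary": system_summary("continental"),
            "range_partition": {
                "n_native": n_native,
                "n_nonnative": n_nonnative,
                "n_both": n_both,
            },
            "n_range_overlap": n_overlap,
            "comparator_counts": {
                "doherty2016": comparator(island_only=False),
                "medina2011_island": comparator(island_only=True),
            },
        }


@dataclass
class SimOutput:
    """Everything one simulated study comprises."""

    records: list[TaxonRecord]
    pig_range: PigRangeMap
    regions: RegionTable
    curation: dict[str, CurationEntry]
    truth: GroundTruth
    config: SimConfig

    def write(self, out_dir: str | os.PathLike) -> dict[str, Path]:
        """Write corpus.csv, pig_range.csv, regions.csv, curation.csv and
        truth.json; byte-identical across runs with the same config."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "corpus": out / "corpus.csv",
            "pig_range": out / "pig_range.csv",
            "regions": out / "regions.csv",
            "curation": out / "curation.csv",
            "truth": out / "truth.json",
        }
        corpus_io.write_corpus(self.records, paths["corpus"])
        with open(paths["pig_range"], "w", encoding="utf-8", newline="") as fh:
            fh.write("unit,status\n")
            for unit in sorted(self.pig_range.status_by_unit):
                fh.write(f"{unit},{self.pig_range.status_by_unit[unit].value}\n")
        with open(paths["regions"], "w", encoding="utf-8", newline="") as fh:
            fh.write("unit,region,system\n")
            for unit in sorted(self.regions.region_by_unit):
                region = self.regions.region_by_unit[unit]
                fh.write(
                    f'{unit},"{region}",{self.regions.system_by_region[region]}\n'
                )
        with open(paths["curation"], "w", encoding="utf-8", newline="") as fh:
            fh.write("taxon_id,verdict,cues,stated_grade\n")
            for tid in sorted(self.curation):
                e = self.curation[tid]
                cues = ";".join(sorted(c.value for c in e.cues))
                grade = e.stated_grade.value if e.stated_grade else ""
                fh.write(f"{tid},{e.verdict.value},{cues},{grade}\n")
        with open(paths["truth"], "w", encoding="utf-8") as fh:
            json.dump(self.truth.summary_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths


def _severity_by_rules(
    category: Category, cues: frozenset[Cue], stated_grade: Optional[Severity]
) -> Severity:
    # independent restatement of the grading rules for truth derivation
    if stated_grade is not None:
        return stated_grade
    if cues == {Cue.OVERLAP_ONLY}:
        return Severity.POTENTIAL
    if category in (Category.EX, Category.EW, Category.CR):
        return Severity.MAJOR
    if category in (Category.LC, Category.NT):
        return Severity.MINOR
    direct = cues - {Cue.OVERLAP_ONLY}
    return Severity.MAJOR if direct else Severity.POTENTIAL


def _mechanisms_by_rules(taxon_class: TaxonClass, cues: frozenset[Cue]) -> frozenset[str]:
    # independent restatement of the cue -> mechanism mapping
    mechs: set[str] = set()
    for cue in cues:
        if cue is Cue.DIRECT_PREDATION:
            mechs.add("predation")
        elif cue is Cue.HABITAT_DISTURBANCE:
            mechs.add("disturbance")
        elif cue is Cue.DISEASE:
            mechs.add("disease_risk")
        elif cue is Cue.COMPETITION:
            mechs.add("competition")
        elif cue is Cue.HYBRIDIZATION:
            mechs.add("hybridization")
        elif cue is Cue.CONSUMPTION:
            mechs.add("predation")
            if taxon_class is TaxonClass.PLANT:
                mechs.add("disturbance")
        elif cue is Cue.NEST_DIGGING:
            mechs.add("disturbance")
            if taxon_class in (TaxonClass.REPTILE, TaxonClass.AMPHIBIAN, TaxonClass.BIRD):
                mechs.add("predation")
    if not mechs and Cue.OVERLAP_ONLY in cues:
        mechs.add("disturbance")
    return frozenset(mechs)


def generate_corpus(config: SimConfig) -> SimOutput:
    """Generate a corpus, range/region tables, oracle curation and truth.

    Deterministic for a fixed config (single pseudo-random stream).  Every
    threatened record's narrative embeds at least one keyword form matching
    its cues; non-threatened narratives contain no keyword token, except
    distractors (reviewed as false positives) and out-of-scope mentions of
    hunting or penned domestic animals (confirmed but excluded from the
    analysis by their cues).
    """
    rng = np.random.default_rng(config.seed)
    regions = default_region_table()
    pig_range = PigRangeMap(status_by_unit=dict(DEFAULT_PIG_STATUS))

    classes = list(config.group_mix)
    class_p = np.array([config.group_mix[c] for c in classes], dtype=float)
    class_p = class_p / class_p.sum()
    categories = list(config.category_mix)
    cat_p = np.array([config.category_mix[c] for c in categories], dtype=float)
    cat_p = cat_p / cat_p.sum()
    island_regions = list(DEFAULT_ISLAND_REGIONS)

    records: list[TaxonRecord] = []
    curation: dict[str, CurationEntry] = {}
    truth_rows: dict[str, TruthRow] = {}

    for i in range(config.n_taxa):
        taxon_id = f"T{i + 1:05d}"
        cls = classes[rng.choice(len(classes), p=class_p)]
        category = categories[rng.choice(len(categories), p=cat_p)]

        # geography
        endemic_to: Optional[str] = None
        if rng.random() < config.island_endemic_rate:
            region = island_regions[rng.integers(len(island_regions))]
            pool = list(DEFAULT_UNITS_BY_REGION[region])
            k = int(rng.integers(1, min(2, len(pool)) + 1))
            idx = rng.permutation(len(pool))[:k]
            units = {pool[j] for j in idx}
            if rng.random() < config.cross_listing_rate:
                units.add(_GOVERNING_CONTINENTAL_UNIT[region])
            endemic_to = region
        else:
            n_regions = 1 + int(rng.random() < 0.25)
            idx = rng.permutation(len(_CONTINENTAL_REGIONS))[:n_regions]
            units = set()
            for j in idx:
                pool = list(DEFAULT_UNITS_BY_REGION[_CONTINENTAL_REGIONS[j]])
                k = int(rng.integers(1, min(2, len(pool)) + 1))
                sel = rng.permutation(len(pool))[:k]
                units |= {pool[s] for s in sel}

        # threat flag, modulated by category
        base = config.threat_rate_by_group[cls]
        p_threat = min(1.0, base * _CATEGORY_THREAT_WEIGHT[category])
        threatened = bool(rng.random() < p_threat)

        cues: frozenset[Cue] = frozenset()
        stated_grade: Optional[Severity] = None
        severity: Optional[Severity] = None
        sentences: list[str] = []
        flagged = False

        if threatened:
            profile = config.mechanism_profiles[cls]
            cue_sets = list(profile)
            cue_p = np.array([profile[cs] for cs in cue_sets], dtype=float)
            cue_p = cue_p / cue_p.sum()
            cues = frozenset(cue_sets[rng.choice(len(cue_sets), p=cue_p)])
            desired = (Severity.MAJOR, Severity.MINOR, Severity.POTENTIAL)[
                rng.choice(3, p=np.array(config.severity_mix))
            ]
            if _severity_by_rules(category, cues, None) is not desired:
                stated_grade = desired
            severity = desired
            sentences = [_CUE_SENTENCES[c] for c in sorted(cues, key=lambda c: c.value)]
            flagged = True
            curation[taxon_id] = CurationEntry(
                taxon_id=taxon_id,
                verdict=Verdict.CONFIRM,
                cues=cues,
                stated_grade=stated_grade,
            )
        else:
            r = rng.random()
            if r < config.excluded_mention_rate:
                cue = (
                    Cue.HUNTING_CATALYZED
                    if rng.random() < 0.5
                    else Cue.DOMESTIC_NOT_FREE_RANGING
                )
                sentences = [_CUE_SENTENCES[cue]]
                flagged = True
                curation[taxon_id] = CurationEntry(
                    taxon_id=taxon_id,
                    verdict=Verdict.CONFIRM,
                    cues=frozenset({cue}),
                    stated_grade=None,
                )
            elif r < config.excluded_mention_rate + config.distractor_rate:
                sentences = [
                    _DISTRACTOR_SENTENCES[rng.integers(len(_DISTRACTOR_SENTENCES))]
                ]
                flagged = True
                curation[taxon_id] = CurationEntry(
                    taxon_id=taxon_id,
                    verdict=Verdict.FALSE_POSITIVE,
                )

        # filler prose around the informative sentences
        n_filler = int(rng.integers(1, 3))
        filler_idx = rng.permutation(len(_FILLER_SENTENCES))[:n_filler]
        sentences += [_FILLER_SENTENCES[j] for j in filler_idx]
        threats_text = " ".join(sentences)

        genus = _GENERA[cls][rng.integers(len(_GENERA[cls]))]
        epithet = _EPITHETS[rng.integers(len(_EPITHETS))]
        family = _FAMILIES[cls][rng.integers(len(_FAMILIES[cls]))]
        range_text = (
            f"Endemic to {endemic_to}." if endemic_to else "Widespread on continents."
        )

        record = TaxonRecord(
            taxon_id=taxon_id,
            scientific_name=f"{genus} {epithet}",
            taxon_class=cls,
            family=family,
            category=category,
            threats_text=threats_text,
            range_text=range_text,
            units=frozenset(units),
            endemic_to=endemic_to,
        )
        records.append(record)

        statuses = {DEFAULT_PIG_STATUS.get(u, RangeStatus.ABSENT) for u in units}
        in_native = RangeStatus.NATIVE in statuses
        in_nonnative = RangeStatus.NONNATIVE in statuses
        in_potential_only = (
            not in_native
            and not in_nonnative
            and RangeStatus.POTENTIAL in statuses
        )
        resolved = (
            frozenset({endemic_to})
            if endemic_to
            else frozenset(regions.region_by_unit[u] for u in units)
        )
        truth_rows[taxon_id] = TruthRow(
            taxon_id=taxon_id,
            taxon_class=cls,
            category=category,
            threatened=threatened,
            cues=cues,
            stated_grade=stated_grade,
            severity=severity,
            mechanisms=_mechanisms_by_rules(cls, cues) if threatened else frozenset(),
            regions=resolved,
            endemic_to=endemic_to,
            units=frozenset(units),
            flagged=flagged,
            in_native=in_native,
            in_nonnative=in_nonnative,
            in_potential_only=in_potential_only,
        )

    return SimOutput(
        records=records,
        pig_range=pig_range,
        regions=regions,
        curation=curation,
        truth=GroundTruth(rows=truth_rows, regions=regions),
        config=config,
    )
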