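"""Biogeographic stratification: regions, endemism, and range overlap.

Taxon occurrence is recorded as administrative-unit codes (countries, or
states/provinces where both sides of a join have that resolution).  Units
map to one of 17 biogeographic regions, each classified as an island or a
continental system.  Because occurrence data are listed by country, island
endemics are frequently cross-listed under the continental country that
governs the island; those cross-listings would inflate continental tallies
and are pruned using the structured ``endemic_to`` field.

No spatial geometry is involved anywhere: every join is an exact match on
unit codes.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from .types import (
    PigRangeMap,
    RangeOverlap,
    RangeStatus,
    RegionTable,
    TaxonRecord,
    ThreatAnnotation,
)


class UnmappedUnitError(ValueError):
    """A record occurs in units missing from the region table."""


class EndemismInconsistencyError(ValueError):
    """A record claims endemism to a region it is not listed in."""


#: Default 17-region scheme (8 island, 9 continental).  Placeholder
#: convention: real analyses supply their own unit->region table; this one
#: exists so the synthetic generator and the examples share a realistic map.
DEFAULT_ISLAND_REGIONS: tuple[str, ...] = (
    "Polynesia",
    "Micronesia/Melanesia",
    "Galapagos",
    "New Zealand",
    "Caribbean",
    "Madagascar",
    "Macaronesia",
    "Indian Ocean Islands",
)
DEFAULT_CONTINENTAL_REGIONS: tuple[str, ...] = (
    "North America",
    "South America",
    "Europe",
    "Africa",
    "Central Asia",
    "East Asia",
    "Southeast Asia",
    "South Asia",
    "Australia",
)

DEFAULT_UNITS_BY_REGION: dict[str, tuple[str, ...]] = {
    "Polynesia": ("US-HI", "PF", "WS", "TO"),
    "Micronesia/Melanesia": ("FJ", "NC", "PG", "FM", "SB"),
    "Galapagos": ("EC-GAL",),
    "New Zealand": ("NZ",),
    "Caribbean": ("CU", "JM", "PR", "DO"),
    "Madagascar": ("MG",),
    "Macaronesia": ("PT-AZ", "ES-CN", "CV"),
    "Indian Ocean Islands": ("MU", "SC", "KM"),
    "North America": ("US", "CA", "MX"),
    "South America": ("BR", "AR", "CO", "CL", "EC"),
    "Europe": ("FR", "DE", "ES", "IT", "GB", "PL"),
    "Africa": ("ZA", "KE", "NG", "TZ", "ET"),
    "Central Asia": ("KZ", "UZ", "MN"),
    "East Asia": ("CN", "JP", "KR"),
    "Southeast Asia": ("ID", "MY", "TH", "VN", "PH"),
    "South Asia": ("IN", "PK", "LK", "NP"),
    "Australia": ("AU",),
}

#: island region -> continental country cross-listings arise under
_GOVERNING_CONTINENTAL_UNIT: dict[str, str] = {
    "Polynesia": "US",
    "Micronesia/Melanesia": "FR",
    "Galapagos": "EC",
    "New Zealand": "AU",
    "Caribbean": "US",
    "Madagascar": "FR",
    "Macaronesia": "ES",
    "Indian Ocean Islands": "FR",
}


def default_region_table() -> RegionTable:
    """The shipped 17-region table over the default unit codes."""
    region_by_unit = {
        unit: region
        for region, units in DEFAULT_UNITS_BY_REGION.items()
        for unit in units
    }
    system_by_region = {r: "island" for r in DEFAULT_ISLAND_REGIONS}
    system_by_region.update({r: "continental" for r in DEFAULT_CONTINENTAL_REGIONS})
    return RegionTable(region_by_unit=region_by_unit, system_by_region=system_by_region)


def assign_regions(record: TaxonRecord, regions: RegionTable) -> frozenset[str]:
    """Regions a record occurs in: the image of its units under the table.

    Every unit of the record must appear in the region table; an extinct
    record with no units yields the empty set.
    """
    unmapped = sorted(u for u in record.units if u not in regions.region_by_unit)
    if unmapped:
        raise UnmappedUnitError(
            f"taxon {record.taxon_id!r}: units not in region table: {', '.join(unmapped)}"
        )
    return frozenset(regions.region_by_unit[u] for u in record.units)


def resolve_endemic_cross_listings(
    record: TaxonRecord, region_set: frozenset[str] | set[str]
) -> frozenset[str]:
    """Prune cross-listings for endemics.

    A taxon endemic to one region but listed under a governing continental
    country would be counted in both; when ``endemic_to`` is set, the
    region set collapses to that single region.  Claiming endemism to a
    region the record is not listed in is an inconsistency.
    """
    region_set = frozenset(region_set)
    if record.endemic_to is None:
        return region_set
    if record.endemic_to not in region_set:
        raise EndemismInconsistencyError(
            f"taxon {record.taxon_id!r}: endemic_to {record.endemic_to!r} "
            f"not among assigned regions {sorted(region_set)}"
        )
    return frozenset({record.endemic_to})


def resolve_regions(record: TaxonRecord, regions: RegionTable) -> frozenset[str]:
    """Assign regions and prune endemic cross-listings in one step."""
    return resolve_endemic_cross_listings(record, assign_regions(record, regions))


def range_overlap(record: TaxonRecord, pigs: PigRangeMap) -> RangeOverlap:
    """How the record's units overlap the focal species' range.

    ``in_potential_only`` is set when no unit is native or non-native but
    at least one is listed as potentially occupied.
    """
    statuses = {pigs.status(u) for u in record.units}
    in_native = RangeStatus.NATIVE in statuses
    in_nonnative = RangeStatus.NONNATIVE in statuses
    in_potential_only = (
        not in_native and not in_nonnative and RangeStatus.POTENTIAL in statuses
    )
    return RangeOverlap(
        taxon_id=record.taxon_id,
        in_native=in_native,
        in_nonnative=in_nonnative,
        in_potential_only=in_potential_only,
    )


def apply_potential_rule(
    records: Sequence[TaxonRecord],
    annotations: Iterable[ThreatAnnotation],
    pigs: PigRangeMap,
) -> list[TaxonRecord]:
    """Resolve potentially-occupied areas.

    Taxa are included initially when they occur where the focal species is
    described as potentially occurring; but if no taxon in such a unit is
    confirmed threatened, the whole unit's taxa are dropped (when their
    retention depended only on potential units).  A single pass suffices:
    the rule is monotone, since removing unthreatened taxa cannot create
    new threatened ones.
    """
    threatened_ids = {a.taxon_id for a in annotations if a.pig_threatened}
    active_units = {
        u
        for rec in records
        if rec.taxon_id in threatened_ids
        for u in rec.units
        if pigs.status(u) is RangeStatus.POTENTIAL
    }
    retained = []
    for rec in records:
        overlap = range_overlap(rec, pigs)
        if overlap.in_potential_only:
            potential_units = {
                u for u in rec.units if pigs.status(u) is RangeStatus.POTENTIAL
            }
            if potential_units & active_units:
                retained.append(rec)
        else:
            retained.append(rec)
    return retained


def retain_in_range(
    records: Sequence[TaxonRecord],
    annotations: Iterable[ThreatAnnotation],
    pigs: PigRangeMap,
) -> list[TaxonRecord]:
    """Full range filter: drop taxa wholly outside the focal species'
    native, non-native and potential range, then apply the potential rule."""
    overlapping = [r for r in records if range_overlap(r, pigs).any_overlap]
    return apply_potential_rule(overlapping, annotations, pigs)


def partition_island_continental(
    records: Iterable[TaxonRecord], regions: RegionTable
) -> tuple[set[str], set[str]]:
    """Split taxon ids into the island subset and the continental subset.

    Any occurrence in a continental region places the taxon in the
    continental subset; only taxa confined to island regions are eligible
    for the island (endemic) comparison.  Records with no units (extinct,
    range unknown) fall to the continental side so that the partition stays
    exhaustive.
    """
    island_ids: set[str] = set()
    continental_ids: set[str] = set()
    for rec in records:
        resolved = resolve_regions(rec, regions)
        if resolved and all(regions.is_island(r) for r in resolved):
            island_ids.add(rec.taxon_id)
        else:
            continental_ids.add(rec.taxon_id)
    return island_ids, continental_ids


def is_island_endemic(record: TaxonRecord, regions: RegionTable) -> bool:
    """True when the record is endemic to a single island region."""
    if record.endemic_to is None:
        return False
    resolved = resolve_regions(record, regions)
    return len(resolved) == 1 and regions.is_island(next(iter(resolved)))
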