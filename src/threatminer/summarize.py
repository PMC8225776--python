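"""Results-style summary statistics for a classified corpus.

Counts by Red List category, reporting group, mechanism and severity;
per-region threatened proportions; island vs continental means +/- SD; the
native / non-native range partition; and comparator subsets that apply the
inclusion criteria of earlier invasive-predator meta-analyses (vertebrates
only, at-risk categories only) so totals can be placed alongside published
figures for cats, dogs, rats and mongoose.

Reporting groups collapse reptiles and amphibians into "herpetofauna".
Proportions are threatened / assessed within each (region, group) cell and
are omitted where nothing was assessed.  Island cells count only taxa
endemic to that island region; taxa that also occur on a continent are
counted on the continental side only.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Optional, Sequence

from .geography import is_island_endemic, resolve_regions
from .types import (
    Category,
    Mechanism,
    RangeOverlap,
    RegionTable,
    Severity,
    TaxonClass,
    TaxonRecord,
    ThreatAnnotation,
)

#: reporting groups, in the conventional display order
GROUPS: tuple[str, ...] = ("plant", "herpetofauna", "bird", "invertebrate", "mammal")

_GROUP_OF_CLASS: dict[TaxonClass, str] = {
    TaxonClass.PLANT: "plant",
    TaxonClass.REPTILE: "herpetofauna",
    TaxonClass.AMPHIBIAN: "herpetofauna",
    TaxonClass.BIRD: "bird",
    TaxonClass.INVERTEBRATE: "invertebrate",
    TaxonClass.MAMMAL: "mammal",
}


def group_of(taxon_class: TaxonClass) -> str:
    """Reporting group of a taxonomic class (reptile+amphibian -> herpetofauna)."""
    return _GROUP_OF_CLASS[taxon_class]


def round_half_up(x: float, digits: int = 0) -> float:
    """Round half away from zero at ``digits`` decimals (report style)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RegionCell:
    """One (region, group) cell: threatened and assessed taxon counts."""

    threatened: int
    assessed: int

    @property
    def proportion(self) -> float:
        return self.threatened / self.assessed


@dataclass(frozen=True)
class SystemGroupSummary:
    """Mean +/- SD of per-region proportions for one group within one
    system class (island or continental)."""

    mean: float
    sd: float
    sd_defined: bool  # False when computed over a single region
    n_regions: int
    total_threatened: int


@dataclass
class SummaryReport:
    """Every corpus-level tally the pipeline reports.

    Construction validates the accounting identities: group counts and
    severity counts each sum to the threatened total, and the native +
    non-native - both identity holds for the range partition.
    """

    n_threatened: int
    by_category: dict[Category, int]
    by_group: dict[str, int]
    by_mechanism: dict[Mechanism, int]
    by_severity: dict[Severity, int]
    severity_percent: dict[Severity, float]
    concern_count: int
    region_props: dict[tuple[str, str], RegionCell]
    island_summary: dict[str, SystemGroupSummary]
    continental_summary: dict[str, SystemGroupSummary]
    range_partition: tuple[int, int, int]  # (n_native, n_nonnative, n_both)
    n_range_overlap: int  # unique threatened taxa with native-or-nonnative overlap
    comparator_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sum(self.by_group.values()) != self.n_threatened:
            raise ValueError("group counts do not sum to the threatened total")
        if sum(self.by_severity.values()) != self.n_threatened:
            raise ValueError("severity counts do not sum to the threatened total")
        if sum(self.by_category.values()) != self.n_threatened:
            raise ValueError("category counts do not sum to the threatened total")
        n_native, n_nonnative, n_both = self.range_partition
        if n_native + n_nonnative - n_both != self.n_range_overlap:
            raise ValueError("range partition violates inclusion-exclusion")
        for (region, group), cell in self.region_props.items():
            if not 0 <= cell.proportion <= 1:
                raise ValueError(f"proportion out of [0,1] for {(region, group)}")

    # -- serialization ----------------------------------------------------

    def to_json_dict(self) -> dict:
        return {
            "n_threatened": self.n_threatened,
            "by_category": {c.value: n for c, n in self.by_category.items()},
            "by_group": dict(self.by_group),
            "by_mechanism": {m.value: n for m, n in self.by_mechanism.items()},
            "by_severity": {s.value: n for s, n in self.by_severity.items()},
            "severity_percent": {s.value: p for s, p in self.severity_percent.items()},
            "concern_count": self.concern_count,
            "region_props": [
                {
                    "region": region,
                    "group": group,
                    "threatened": cell.threatened,
                    "assessed": cell.assessed,
                    "proportion": cell.proportion,
                }
                for (region, group), cell in sorted(self.region_props.items())
            ],
            "island_summary": _summary_json(self.island_summary),
            "continental_summary": _summary_json(self.continental_summary),
            "range_partition": {
                "n_native": self.range_partition[0],
                "n_nonnative": self.range_partition[1],
                "n_both": self.range_partition[2],
            },
            "n_range_overlap": self.n_range_overlap,
            "comparator_counts": {
                profile: dict(counts) for profile, counts in self.comparator_counts.items()
            },
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_json_dict(), indent=indent, sort_keys=True)

    def to_markdown(self) -> str:
        return report_markdown(self)


def _summary_json(summary: Mapping[str, SystemGroupSummary]) -> dict:
    return {
        group: {
            "mean": s.mean,
            "sd": s.sd,
            "sd_defined": s.sd_defined,
            "n_regions": s.n_regions,
            "total_threatened": s.total_threatened,
        }
        for group, s in summary.items()
    }


def tally(
    annotations: Sequence[ThreatAnnotation],
    records_by_id: Mapping[str, TaxonRecord],
) -> tuple[
    dict[Category, int], dict[str, int], dict[Mechanism, int], dict[Severity, int]
]:
    """Count threatened taxa by category, group, mechanism and severity.

    Each taxon contributes once to its category, group and severity, and
    once per mechanism it carries — mechanism counts may therefore exceed
    the threatened total.
    """
    by_category: dict[Category, int] = {c: 0 for c in Category}
    by_group: dict[str, int] = {g: 0 for g in GROUPS}
    by_mechanism: dict[Mechanism, int] = {m: 0 for m in Mechanism}
    by_severity: dict[Severity, int] = {s: 0 for s in Severity}
    for ann in annotations:
        if not ann.pig_threatened:
            continue
        rec = records_by_id[ann.taxon_id]
        by_category[rec.category] += 1
        by_group[group_of(rec.taxon_class)] += 1
        by_severity[ann.severity] += 1
        for mech in ann.mechanisms:
            by_mechanism[mech] += 1
    return by_category, by_group, by_mechanism, by_severity


def concern_count(by_category: Mapping[Category, int]) -> int:
    """Taxa of greatest conservation concern: critically endangered plus
    endangered."""
    return by_category.get(Category.CR, 0) + by_category.get(Category.EN, 0)


def severity_percentages(
    by_severity: Mapping[Severity, int], digits: int = 0
) -> dict[Severity, float]:
    """Severity shares as percentages of the threatened total, rounded
    half-up; raw counts stay authoritative."""
    total = sum(by_severity.values())
    if total == 0:
        return {s: 0.0 for s in Severity}
    return {
        s: round_half_up(100.0 * by_severity.get(s, 0) / total, digits)
        for s in Severity
    }


def region_proportions(
    annotations: Sequence[ThreatAnnotation],
    records: Sequence[TaxonRecord],
    regions: RegionTable,
) -> dict[tuple[str, str], RegionCell]:
    """Per-(region, group) threatened / assessed proportions.

    Continental cells count every taxon resolved to the region.  Island
    cells count only taxa endemic to that island region, so that
    cross-listed continental populations never inflate island tallies and
    island/continental comparisons contrast endemics with everything else.
    Cells with zero assessed taxa are omitted.
    """
    threatened_ids = {a.taxon_id for a in annotations if a.pig_threatened}
    assessed: dict[tuple[str, str], int] = {}
    threatened: dict[tuple[str, str], int] = {}
    for rec in records:
        group = group_of(rec.taxon_class)
        for region in resolve_regions(rec, regions):
            if regions.is_island(region) and not (
                is_island_endemic(rec, regions) and rec.endemic_to == region
            ):
                continue
            key = (region, group)
            assessed[key] = assessed.get(key, 0) + 1
            if rec.taxon_id in threatened_ids:
                threatened[key] = threatened.get(key, 0) + 1
    return {
        key: RegionCell(threatened=threatened.get(key, 0), assessed=n)
        for key, n in assessed.items()
    }


def _mean_sd(values: Sequence[float]) -> tuple[float, float, bool]:
    n = len(values)
    mean = sum(values) / n
    if n < 2:
        return mean, 0.0, False
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var), True


def island_continental_summary(
    region_props: Mapping[tuple[str, str], RegionCell],
    regions: RegionTable,
) -> tuple[dict[str, SystemGroupSummary], dict[str, SystemGroupSummary]]:
    """Mean and sample SD (n-1 divisor) of per-region proportions, per
    group, separately for island and continental regions.

    Regions where a group was never assessed do not enter that group's
    mean.  A group observed in a single region reports SD 0 with
    ``sd_defined=False``.  The special group ``"overall"`` pools all groups
    within each region before averaging.
    """
    island: dict[str, SystemGroupSummary] = {}
    continental: dict[str, SystemGroupSummary] = {}
    for system, out in (("island", island), ("continental", continental)):
        system_regions = sorted(
            r for r, s in regions.system_by_region.items() if s == system
        )
        for group in GROUPS:
            cells = [
                region_props[(r, group)]
                for r in system_regions
                if (r, group) in region_props
            ]
            if not cells:
                continue
            mean, sd, defined = _mean_sd([c.proportion for c in cells])
            out[group] = SystemGroupSummary(
                mean=mean,
                sd=sd,
                sd_defined=defined,
                n_regions=len(cells),
                total_threatened=sum(c.threatened for c in cells),
            )
        pooled = []
        pooled_threatened = 0
        for r in system_regions:
            cells = [region_props[(r, g)] for g in GROUPS if (r, g) in region_props]
            if not cells:
                continue
            thr = sum(c.threatened for c in cells)
            tot = sum(c.assessed for c in cells)
            pooled.append(thr / tot)
            pooled_threatened += thr
        if pooled:
            mean, sd, defined = _mean_sd(pooled)
            out["overall"] = SystemGroupSummary(
                mean=mean,
                sd=sd,
                sd_defined=defined,
                n_regions=len(pooled),
                total_threatened=pooled_threatened,
            )
    return island, continental


def range_partition(
    overlaps: Iterable[RangeOverlap],
    annotations: Sequence[ThreatAnnotation],
) -> tuple[int, int, int]:
    """(n_native, n_nonnative, n_both) over threatened taxa.

    A taxon spanning both ranges is counted in both tallies, so
    ``n_native + n_nonnative - n_both`` equals the number of unique
    threatened taxa with any native-or-non-native overlap.
    """
    threatened_ids = {a.taxon_id for a in annotations if a.pig_threatened}
    n_native = n_nonnative = n_both = 0
    for ov in overlaps:
        if ov.taxon_id not in threatened_ids:
            continue
        if ov.in_native:
            n_native += 1
        if ov.in_nonnative:
            n_nonnative += 1
        if ov.in_native and ov.in_nonnative:
            n_both += 1
    return n_native, n_nonnative, n_both


COMPARATOR_PROFILES = ("doherty2016", "medina2011_island")

#: classes retained by the invasive-predator meta-analysis criteria
_COMPARATOR_CLASSES = (TaxonClass.REPTILE, TaxonClass.BIRD, TaxonClass.MAMMAL)


def comparator_filter(
    annotations: Sequence[ThreatAnnotation],
    records_by_id: Mapping[str, TaxonRecord],
    profile: str,
    regions: Optional[RegionTable] = None,
) -> dict[str, int]:
    """Apply a published meta-analysis' inclusion criteria to our
    threatened set, for like-for-like comparison.

    ``doherty2016`` keeps reptiles, birds and mammals whose category is not
    least-concern or near-threatened (terrestrial invertebrates, amphibians
    and plants excluded).  ``medina2011_island`` applies the same criteria
    restricted to island endemics, for comparison with island-focused cat
    impact totals; it requires a region table.
    """
    if profile not in COMPARATOR_PROFILES:
        raise ValueError(f"unknown comparator profile {profile!r}")
    if profile == "medina2011_island" and regions is None:
        raise ValueError("medina2011_island requires a region table")
    counts = {cls.value: 0 for cls in _COMPARATOR_CLASSES}
    for ann in annotations:
        if not ann.pig_threatened:
            continue
        rec = records_by_id[ann.taxon_id]
        if rec.taxon_class not in _COMPARATOR_CLASSES:
            continue
        if rec.category in (Category.LC, Category.NT):
            continue
        if profile == "medina2011_island" and not is_island_endemic(rec, regions):
            continue
        counts[rec.taxon_class.value] += 1
    counts["total"] = sum(counts.values())
    return counts


def build_report(
    annotations: Sequence[ThreatAnnotation],
    records: Sequence[TaxonRecord],
    regions: RegionTable,
    overlaps: Sequence[RangeOverlap],
) -> SummaryReport:
    """Assemble the full summary report for a classified, retained corpus."""
    records_by_id = {r.taxon_id: r for r in records}
    threatened = [a for a in annotations if a.pig_threatened]
    by_category, by_group, by_mechanism, by_severity = tally(threatened, records_by_id)
    props = region_proportions(threatened, records, regions)
    island, continental = island_continental_summary(props, regions)
    partition = range_partition(overlaps, threatened)
    threatened_ids = {a.taxon_id for a in threatened}
    n_overlap = sum(
        1
        for ov in overlaps
        if ov.taxon_id in threatened_ids and (ov.in_native or ov.in_nonnative)
    )
    comparators = {
        "doherty2016": comparator_filter(threatened, records_by_id, "doherty2016"),
        "medina2011_island": comparator_filter(
            threatened, records_by_id, "medina2011_island", regions=regions
        ),
    }
    return SummaryReport(
        n_threatened=len(threatened),
        by_category=by_category,
        by_group=by_group,
        by_mechanism=by_mechanism,
        by_severity=by_severity,
        severity_percent=severity_percentages(by_severity),
        concern_count=concern_count(by_category),
        region_props=props,
        island_summary=island,
        continental_summary=continental,
        range_partition=partition,
        n_range_overlap=n_overlap,
        comparator_counts=comparators,
    )


def _md_table(header: Sequence[str], rows: Sequence[Sequence[object]]) -> str:
    lines = [
        "| " + " | ".join(header) + " |",
        "| " + " | ".join("---" for _ in header) + " |",
    ]
    lines += ["| " + " | ".join(str(c) for c in row) + " |" for row in rows]
    return "\n".join(lines)


def report_markdown(report: SummaryReport) -> str:
    """Human-readable report: counts plus percentages to one decimal."""
    parts = [f"# Threat assessment summary\n\nThreatened taxa: **{report.n_threatened}**"]
    parts.append(
        "\n## By Red List category\n\n"
        + _md_table(
            ["category", "count"],
            [(c.value, n) for c, n in report.by_category.items() if n],
        )
        + f"\n\nCritically endangered + endangered: {report.concern_count}"
    )
    parts.append(
        "\n## By group\n\n"
        + _md_table(["group", "count"], [(g, n) for g, n in report.by_group.items()])
    )
    parts.append(
        "\n## By mechanism\n\n"
        + _md_table(
            ["mechanism", "count"],
            [(m.value, n) for m, n in report.by_mechanism.items()],
        )
    )
    parts.append(
        "\n## By severity\n\n"
        + _md_table(
            ["severity", "count", "percent"],
            [
                (s.value, report.by_severity.get(s, 0), f"{report.severity_percent.get(s, 0.0):g}%")
                for s in Severity
            ],
        )
    )
    for label, summary in (
        ("Island endemics", report.island_summary),
        ("Continental taxa", report.continental_summary),
    ):
        rows = [
            (
                group,
                f"{round_half_up(100 * s.mean, 1)}%",
                (f"{round_half_up(100 * s.sd, 1)}%" if s.sd_defined else "n/a"),
                s.n_regions,
                s.total_threatened,
            )
            for group, s in summary.items()
        ]
        parts.append(
            f"\n## {label} (per-region mean)\n\n"
            + _md_table(["group", "mean", "sd", "regions", "threatened"], rows)
        )
    n_native, n_nonnative, n_both = report.range_partition
    parts.append(
        "\n## Native / non-native range\n\n"
        + _md_table(
            ["subset", "threatened taxa"],
            [
                ("native range", n_native),
                ("non-native range", n_nonnative),
                ("both", n_both),
                ("unique with overlap", report.n_range_overlap),
            ],
        )
    )
    if report.comparator_counts:
        for profile, counts in report.comparator_counts.items():
            parts.append(
                f"\n## Comparator subset: {profile}\n\n"
                + _md_table(["class", "count"], list(counts.items()))
            )
    return "\n".join(parts) + "\n"


def region_csv_rows(
    region_props: Mapping[tuple[str, str], RegionCell]
) -> list[dict[str, object]]:
    """Per-region CSV rows mirroring the regional counts and percentages."""
    return [
        {
            "region": region,
            "group": group,
            "threatened": cell.threatened,
            "assessed": cell.assessed,
            "percent": round_half_up(100 * cell.proportion, 1),
        }
        for (region, group), cell in sorted(region_props.items())
    ]
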