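import math
import random
from collections import Counter

import pytest

from threatminer import (
    Category,
    Cue,
    Mechanism,
    RangeOverlap,
    Severity,
    TaxonClass,
    TaxonRecord,
    ThreatAnnotation,
    build_report,
    comparator_filter,
    concern_count,
    default_region_table,
    tally,
)
from threatminer.summarize import (
    RegionCell,
    group_of,
    island_continental_summary,
    range_partition,
    region_proportions,
    round_half_up,
    severity_percentages,
)

REGIONS = default_region_table()


def _record(tid, cls=TaxonClass.BIRD, cat=Category.EN, units=("FR",), endemic_to=None):
    return TaxonRecord(
        taxon_id=tid,
        scientific_name="G s",
        taxon_class=cls,
        family="F",
        category=cat,
        units=frozenset(units),
        endemic_to=endemic_to,
    )


def _ann(tid, severity=Severity.MAJOR, mechanisms=(Mechanism.PREDATION,)):
    return ThreatAnnotation(
        taxon_id=tid,
        pig_threatened=True,
        severity=severity,
        mechanisms=frozenset(mechanisms),
        cues=frozenset({Cue.DIRECT_PREDATION}),
    )


# -- tally -------------------------------------------------------------------


def test_taxa_count_once_per_mechanism_they_carry():
    records = {
        "T1": _record("T1"),
        "T2": _record("T2"),
    }
    anns = [
        _ann("T1", mechanisms=(Mechanism.PREDATION, Mechanism.DISTURBANCE)),
        _ann("T2", mechanisms=(Mechanism.PREDATION, Mechanism.DISTURBANCE)),
    ]
    by_category, by_group, by_mechanism, by_severity = tally(anns, records)
    assert by_mechanism[Mechanism.PREDATION] == 2
    assert by_mechanism[Mechanism.DISTURBANCE] == 2
    assert sum(by_group.values()) == 2  # mechanism counts exceed the total
    assert by_severity[Severity.MAJOR] == 2


def test_empty_annotations_give_all_zero_counts():
    by_category, by_group, by_mechanism, by_severity = tally([], {})
    assert sum(by_category.values()) == 0
    assert sum(by_group.values()) == 0
    assert sum(by_mechanism.values()) == 0
    assert sum(by_severity.values()) == 0


def test_tally_matches_bruteforce_recount_on_random_corpus():
    rng = random.Random(1234)
    records, anns = {}, []
    for i in range(300):
        tid = f"T{i}"
        cls = rng.choice(list(TaxonClass))
        cat = rng.choice(list(Category))
        records[tid] = _record(tid, cls=cls, cat=cat)
        mechs = rng.sample(list(Mechanism), rng.randint(1, 3))
        anns.append(_ann(tid, severity=rng.choice(list(Severity)), mechanisms=mechs))
    by_category, by_group, by_mechanism, by_severity = tally(anns, records)
    assert by_category == {
        c: Counter(records[a.taxon_id].category for a in anns)[c] for c in Category
    }
    assert by_group == {
        g: Counter(group_of(records[a.taxon_id].taxon_class) for a in anns)[g]
        for g in by_group
    }
    mech_counter = Counter(m for a in anns for m in a.mechanisms)
    assert by_mechanism == {m: mech_counter[m] for m in Mechanism}
    assert by_severity == {
        s: Counter(a.severity for a in anns)[s] for s in Severity
    }


def test_herpetofauna_pools_reptiles_and_amphibians():
    records = {
        "T1": _record("T1", cls=TaxonClass.REPTILE),
        "T2": _record("T2", cls=TaxonClass.AMPHIBIAN),
    }
    _, by_group, _, _ = tally([_ann("T1"), _ann("T2")], records)
    assert by_group["herpetofauna"] == 2


# -- concern count -----------------------------------------------------------


def test_concern_count_is_cr_plus_en():
    by_category = {Category.CR: 267, Category.EN: 147, Category.VU: 50}
    assert concern_count(by_category) == 414
    assert concern_count({Category.CR: 0, Category.EN: 0}) == 0


def test_concern_count_matches_filter_and_count_on_random_maps():
    rng = random.Random(7)
    for _ in range(50):
        by_category = {c: rng.randint(0, 500) for c in Category}
        expected = sum(
            n for c, n in by_category.items() if c in (Category.CR, Category.EN)
        )
        assert concern_count(by_category) == expected


# -- proportions and island/continental summaries ----------------------------


def test_region_proportion_is_threatened_over_assessed():
    records = [_record(f"B{i}", units=("FR",)) for i in range(10)]
    anns = [_ann("B0"), _ann("B1")]
    props = region_proportions(anns, records, REGIONS)
    cell = props[("Europe", "bird")]
    assert (cell.threatened, cell.assessed) == (2, 10)
    assert cell.proportion == pytest.approx(0.2)


def test_cell_omitted_when_nothing_assessed():
    records = [_record("B1", units=("FR",))]
    props = region_proportions([], records, REGIONS)
    assert ("Europe", "invertebrate") not in props


def test_island_cells_count_only_endemics():
    records = [
        _record("E1", units=("US-HI",), endemic_to="Polynesia"),
        _record("V1", units=("US-HI", "US")),  # visitor: continental too
    ]
    props = region_proportions([_ann("E1"), _ann("V1")], records, REGIONS)
    assert props[("Polynesia", "bird")].assessed == 1
    assert props[("North America", "bird")].assessed == 1


def test_island_continental_means_use_sample_sd():
    props = {
        ("Polynesia", "bird"): RegionCell(threatened=1, assessed=10),  # 0.1
        ("Galapagos", "bird"): RegionCell(threatened=3, assessed=10),  # 0.3
        ("Europe", "bird"): RegionCell(threatened=2, assessed=10),  # 0.2
    }
    island, continental = island_continental_summary(props, REGIONS)
    assert island["bird"].mean == pytest.approx(0.2)
    assert island["bird"].sd == pytest.approx(math.sqrt(((0.1 - 0.2) ** 2 + (0.3 - 0.2) ** 2) / 1))
    assert island["bird"].sd == pytest.approx(0.1414, abs=1e-4)
    assert island["bird"].sd_defined and island["bird"].n_regions == 2
    # a single continental region: mean is its proportion, SD flagged undefined
    assert continental["bird"].mean == pytest.approx(0.2)
    assert continental["bird"].sd == 0.0
    assert not continental["bird"].sd_defined


def test_equal_proportions_have_zero_sd():
    props = {
        ("Polynesia", "bird"): RegionCell(threatened=1, assessed=4),
        ("Galapagos", "bird"): RegionCell(threatened=2, assessed=8),
        ("New Zealand", "bird"): RegionCell(threatened=5, assessed=20),
    }
    island, _ = island_continental_summary(props, REGIONS)
    assert island["bird"].sd == pytest.approx(0.0)
    assert island["bird"].sd_defined


def test_pooled_overall_summary_combines_groups_within_regions():
    props = {
        ("Polynesia", "bird"): RegionCell(threatened=1, assessed=5),
        ("Polynesia", "plant"): RegionCell(threatened=3, assessed=5),
    }
    island, _ = island_continental_summary(props, REGIONS)
    assert island["overall"].mean == pytest.approx(4 / 10)
    assert island["overall"].total_threatened == 4


# -- range partition ---------------------------------------------------------


def test_range_partition_counts_both_ranges():
    anns = [_ann("T1"), _ann("T2"), _ann("T3")]
    overlaps = [
        RangeOverlap("T1", in_native=True, in_nonnative=False, in_potential_only=False),
        RangeOverlap("T2", in_native=False, in_nonnative=True, in_potential_only=False),
        RangeOverlap("T3", in_native=True, in_nonnative=True, in_potential_only=False),
    ]
    assert range_partition(overlaps, anns) == (2, 2, 1)


def test_range_partition_empty():
    assert range_partition([], []) == (0, 0, 0)


def test_partition_identity_on_random_overlaps():
    rng = random.Random(99)
    anns, overlaps = [], []
    for i in range(200):
        tid = f"T{i}"
        native, nonnative = rng.random() < 0.3, rng.random() < 0.6
        overlaps.append(
            RangeOverlap(
                tid,
                in_native=native,
                in_nonnative=nonnative,
                in_potential_only=not (native or nonnative) and rng.random() < 0.5,
            )
        )
        if rng.random() < 0.7:
            anns.append(_ann(tid))
    n_native, n_nonnative, n_both = range_partition(overlaps, anns)
    threatened = {a.taxon_id for a in anns}
    unique = sum(
        1
        for ov in overlaps
        if ov.taxon_id in threatened and (ov.in_native or ov.in_nonnative)
    )
    assert n_native + n_nonnative - n_both == unique
    assert n_native == sum(
        1 for ov in overlaps if ov.taxon_id in threatened and ov.in_native
    )


# -- comparator profiles -----------------------------------------------------


def test_comparator_filter_matches_hand_filtered_fixture():
    """Six taxa, filtered by hand: only the CR reptile and the CR bird
    survive the vertebrates-only at-risk-only criteria."""
    fixture = [
        ("T1", TaxonClass.REPTILE, Category.LC),
        ("T2", TaxonClass.REPTILE, Category.CR),
        ("T3", TaxonClass.AMPHIBIAN, Category.EN),
        ("T4", TaxonClass.BIRD, Category.CR),
        ("T5", TaxonClass.MAMMAL, Category.NT),
        ("T6", TaxonClass.PLANT, Category.CR),
    ]
    records = {t: _record(t, cls=cls, cat=cat) for t, cls, cat in fixture}
    anns = [_ann(t) for t, _, _ in fixture]
    counts = comparator_filter(anns, records, "doherty2016")
    assert counts == {"reptile": 1, "bird": 1, "mammal": 0, "total": 2}


def test_comparator_all_plants_is_zero():
    records = {"T1": _record("T1", cls=TaxonClass.PLANT, cat=Category.CR)}
    assert comparator_filter([_ann("T1")], records, "doherty2016")["total"] == 0


def test_island_comparator_on_continental_fixture_is_zero():
    records = {"T1": _record("T1", cls=TaxonClass.BIRD, cat=Category.CR, units=("FR",))}
    counts = comparator_filter([_ann("T1")], records, "medina2011_island", regions=REGIONS)
    assert counts["total"] == 0


def test_island_comparator_keeps_island_endemics_only():
    records = {
        "T1": _record("T1", cls=TaxonClass.BIRD, cat=Category.CR, units=("US-HI",), endemic_to="Polynesia"),
        "T2": _record("T2", cls=TaxonClass.BIRD, cat=Category.CR, units=("FR",)),
    }
    counts = comparator_filter(
        [_ann("T1"), _ann("T2")], records, "medina2011_island", regions=REGIONS
    )
    assert counts == {"reptile": 0, "bird": 1, "mammal": 0, "total": 1}


def test_unknown_profile_rejected():
    with pytest.raises(ValueError):
        comparator_filter([], {}, "nosuch2020")


# -- report invariants and shuffle invariance --------------------------------


def test_rounding_is_half_up():
    assert round_half_up(58.5) == 59.0
    assert round_half_up(0.25, 1) == 0.3
    assert round_half_up(20.4) == 20.0


def test_severity_percentages_sum_to_about_100():
    pct = severity_percentages({Severity.MAJOR: 397, Severity.MINOR: 141, Severity.POTENTIAL: 134})
    assert sum(pct.values()) == pytest.approx(100, abs=1)
    assert pct[Severity.MAJOR] == 59.0


def test_report_is_invariant_under_record_shuffling(sim500):
    from threatminer import run

    base = run(sim500.records, sim500.pig_range, sim500.regions, sim500.curation)
    shuffled = list(sim500.records)
    random.Random(5).shuffle(shuffled)
    again = run(shuffled, sim500.pig_range, sim500.regions, sim500.curation)
    assert again.report.to_json_dict() == base.report.to_json_dict()


def test_report_accounting_identities_on_random_corpora():
    """Group, severity and category counts each sum to the threatened
    total, and the native + non-native - both identity holds, across
    several seeded synthetic corpora."""
    from threatminer import SimConfig, generate_corpus, run

    for seed in (11, 12, 13):
        sim = generate_corpus(SimConfig(n_taxa=250, seed=seed))
        report = run(sim.records, sim.pig_range, sim.regions, sim.curation).report
        assert sum(report.by_group.values()) == report.n_threatened
        assert sum(report.by_severity.values()) == report.n_threatened
        assert sum(report.by_category.values()) == report.n_threatened
        n_native, n_nonnative, n_both = report.range_partition
        assert n_native + n_nonnative - n_both == report.n_range_overlap
        assert all(0 <= c.proportion <= 1 for c in report.region_props.values())


def test_markdown_report_renders(result500):
    md = result500.report.to_markdown()
    assert "Threatened taxa" in md
    assert "| severity | count | percent |" in md
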