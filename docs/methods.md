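# Methods

## The assessment model

The unit of analysis is a *taxon record*: one Red-List-style listing
(species, subspecies or variety) with an extinction-risk category
(EX, EW, CR, EN, VU, NT, LC, DD), a set of occurrence units
(country codes, or finer administrative codes where both sides of a join
have them), a free-text threat narrative, and a free-text range
description. A *threat* is any process that impacted, is impacting, or may
impact the assessed taxon; the pipeline restricts attention to threats
attributable to one focal invasive taxon, by default wild pigs
(*Sus scrofa*).

The pipeline has five stages, each a pure function of its inputs, so a
rerun on identical inputs is byte-identical.

### 1. Keyword screening

Narratives are tokenized into maximal runs of letters (digits, hyphens and
punctuation separate tokens) and lower-cased. A token hits when it equals a
literal pattern or begins with a wildcard stem; `pig*` therefore matches
*pig*, *pigs*, *piglet* — and *pigeon*. This over-matching is intentional:
screening builds a manual-review queue, and precision is recovered by
curation, never by narrowing the screen. Only the threat narrative is
screened, not the range text. The default pattern list (13 patterns:
literals `pig, pigs, domesticus, sus, scrofa, boar, boars, hog, hogs,
swine`; stems `pig, boar, hog`) covers the names used for the species in
management literature; `swine` carries no wildcard. The tokenizer and case
rules are this package's own conventions, stated here because keyword
screens are rarely documented at that level.

### 2. Curation

Curation entries are the structured form of a two-reviewer manual reading:
a verdict (`confirm` / `false_positive`), a set of evidence cues, and
optionally a stated severity grade where the narrative carried enough
detail to grade the threat directly. Records whose only cues are
`hunting_catalyzed` (harm from hunters drawn by pigs, not pigs themselves)
or `domestic_not_free_ranging` are excluded from the analysis; free-ranging
domestic animals count as wild. In strict mode an unreviewed flagged record
is an error listing the ids; lenient mode drops it with a warning. A
confirmed record must carry at least one cue — an empty confirmation is a
curation error, caught early.

### 3. Severity and mechanism rules

Severity (first matching rule wins):

1. a stated grade;
2. cues = {overlap_only} → **potential** (threat inferred from overlapping
   distributions, no direct impact documented);
3. EX, EW, CR → **major** (any threat mention to the most at-risk taxa);
4. LC, NT → **minor** (default for least-concern taxa and secondary
   threats to near-threatened taxa);
5. EN, VU, DD → **major** with any direct-impact cue, else **potential**.

Rule 5 is a declared convention: no default is conventionally stated for
the mid-risk categories, and mirroring the CR treatment (at-risk status
plus direct evidence) is the most conservative consistent choice. Rule 2
sits above rule 3 deliberately: overlap-only inference is treated as
"sufficient detail to grade otherwise" even for CR taxa. Primary versus
secondary threat status for NT taxa is not modelled separately; a stated
grade is the override channel.

Mechanisms map from cues one-to-one (direct_predation → predation,
habitat_disturbance → disturbance, disease → disease_risk, competition,
hybridization), with two compound rules: consumption of a **plant** is
both predation and disturbance (individuals are destroyed and vegetation
structure altered); nest digging for **reptiles, amphibians and birds** is
both predation and disturbance (direct mortality plus nest-site
destruction). Consumption of an animal is predation only; nest digging
recorded against other classes falls back to disturbance alone.
`overlap_only` with no other cue defaults to disturbance — the broadest
impact of an ecosystem engineer — unless the curator supplied something
more specific. Every confirmed taxon receives exactly one severity and at
least one mechanism; both properties are asserted as invariants.

### 4. Geography

Administrative-unit codes are opaque strings matched exactly; no spatial
geometry or unit hierarchy is modelled (sub-country units are simply more
codes, and all tables must share the code set). Units map to 17 regions,
8 island and 9 continental. Because occurrence is listed by country,
island endemics are frequently cross-listed under the governing
continental country; the structured `endemic_to` field collapses such a
record's region set to the single endemic region. Endemism is a structured
input rather than parsed from prose, because resolving it reliably
requires reading the range description — a manual judgement.

Range filtering: a taxon is retained when any unit is native or
non-native for the focal species. Taxa occurring only in *potentially*
occupied units are retained initially, then dropped per potential unit if
no confirmed-threatened taxon occurs there; one pass suffices because the
rule is monotone. Taxa wholly outside all three range classes are
excluded. Threatened taxa overlapping both the native and non-native range
are counted in both tallies, so native + non-native − both equals the
number of unique threatened taxa with overlap (asserted on every report).

The island/continental comparison contrasts **island endemics** with
continental taxa: island per-region cells count only taxa endemic to that
island region, while any occurrence in a continental region places a taxon
on the continental side. Taxa confined to islands without recorded
endemism are excluded from island proportions (they still appear in
corpus-level tallies); this matches the endemic-only filtering of the
island subset and keeps the island/continental partition exhaustive and
exclusive.

The shipped 17-region table is a convention: it fixes the named regions
(Polynesia, Micronesia/Melanesia, Galapagos, New Zealand, Australia,
Europe, North America) and fills the remainder with realistic placeholders
so the generator and examples share a map. Real analyses supply their own
unit→region table.

### 5. Summaries

Per-(region, group) proportion = threatened / assessed, omitted where
nothing was assessed. The quotient is threatened over total — the only
orientation that yields percentages ≤ 100. Island and continental means
are taken over the per-region proportions within each system class with
the sample standard deviation (n − 1 divisor); a group observed in a
single region reports SD 0 with an explicit `sd_defined = False` flag.
Both per-group and pooled "overall" summaries are emitted, since either
may be wanted when comparing island with continental exposure. Reporting
groups are plant, herpetofauna (reptiles + amphibians pooled), bird,
invertebrate, mammal. Percentages in human-readable output are rounded
half-up; machine output keeps raw proportions.

Comparator profiles re-apply the inclusion criteria of earlier
invasive-predator meta-analyses so totals are like-for-like:
`doherty2016` keeps reptiles, birds and mammals not listed LC or NT;
`medina2011_island` additionally keeps island endemics only.

## The synthetic-data generator

Real Red List snapshots cannot be redistributed, so the generator
produces corpora with the properties this pipeline is sensitive to:

- a minority of records (roughly 10–15% at the defaults) whose narrative
  embeds keyword forms matching their ground-truth cues;
- distractor narratives (rate 0.06) containing wildcard-trapping tokens —
  *pigeon*, *pigment*, *boardwalk*, *hogweed* — reviewed as false
  positives;
- out-of-scope mentions (rate 0.02) of hunting catalyzed by pigs or of
  penned domestic pigs, confirmed by curation but excluded by their cues;
- a Red-List-like category mix with threat rates weighted up for at-risk
  categories (×4 for CR, ×3 for EN), so the threatened subset skews
  CR/EN as real threat reporting does;
- severity shares drawn as 59 / 21 / 20% major / minor / potential, with a
  stated grade emitted exactly when the drawn severity differs from the
  rule default — so stated-grade overrides are exercised;
- per-class cue-set profiles that make disturbance and predation the
  dominant mechanisms, with disease, competition and hybridization
  concentrated in mammals;
- island endemics (rate 0.30) cross-listed under their governing
  continental country half the time, plus a default range map with
  native Eurasian units, non-native introduced units, two potentially
  occupied units and several unoccupied ones, so every branch of the
  range filter runs.

One pseudo-random stream is drawn per corpus (seeded from the config);
per taxon the draw order is group, category, geography, threat flag,
cues, narrative. Output files are byte-identical across runs with the
same config. Ground truth is derived by independent inline logic — the
severity and mechanism rules are restated in the generator rather than
imported — so the end-to-end closure check (pipeline report equals
ground-truth summary, exactly) is a dual-route comparison rather than a
tautology.

What the generator does **not** emulate: real narrative prose and its
ambiguity (templates are plain sentences), inter-reviewer disagreement,
taxonomically structured range sizes, data-deficiency bias in which taxa
get assessed at all, and the real corpus' marginal distributions beyond
the configured rates. Passing tests therefore demonstrate that the
*pipeline machinery* is correct under controlled conditions — not that
any particular real-world count would be reproduced, which depends on the
snapshot screened and on manual review.

## Problem sizes and numerical choices

The test suite exercises closure at 500 and 5,000 taxa (the latter is the
scale the acceptance script reports at), property checks on randomized
corpora of a few hundred records, and exhaustive enumeration of the
severity and mechanism rule grids; the full suite runs in a few seconds.
Proportions are exact rational arithmetic on counts until the final
division; means and SDs are accumulated in double precision; report-level
percentages round half-up at one decimal (or whole percent for severity
shares). Ties and degenerate inputs: empty corpora produce an all-zero
report; extinct records may have no occurrence units and then belong to
no region; a single-region group reports its proportion with an undefined
SD flag rather than NaN.

## Known limitations

- Exact-code joins mean a unit present in the corpus but missing from the
  region table is a hard configuration error, by design; there is no
  fuzzy country-name matching.
- Severity rule 5 (EN/VU/DD) and the NT collapse are conventions; real
  analyses may prefer different defaults, settable per record through the
  curation file's stated grade.
- The curation file is authoritative: the package offers no automatic cue
  extraction from prose, so screening recall is bounded by the keyword
  list and classification quality by the reviewers.
- Mechanism counts are per-taxon-per-mechanism and intentionally exceed
  the threatened total when compound rules fire; they must not be summed
  across mechanisms to estimate taxa.
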