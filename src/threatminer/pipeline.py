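"""End-to-end orchestration: screen -> review -> classify -> geography ->
summarize, with a manifest for auditability.

Stage counts mirror the natural checkpoints of a threat-screening study
(records read, flagged for review, confirmed after curation, retained
within the focal species' range, threatened among retained), so a run on
a real corpus can be audited against published narrative figures.
Rerunning on identical inputs writes byte-identical outputs.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from . import corpus_io, geography, keyword_screen, summarize, threat_classify
from .keyword_screen import KeywordSet
from .summarize import SummaryReport
from .types import (
    CurationEntry,
    PigRangeMap,
    RegionTable,
    TaxonRecord,
    ThreatAnnotation,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass(frozen=True)
class RunConfig:
    """File-based pipeline configuration."""

    corpus: str
    pig_range: str
    regions: str
    curation: str
    keywords: Optional[str] = None
    strict: bool = True
    out_dir: str = "threatminer_out"
    corpus_schema: str = "csv"
    log_level: str = "INFO"

    def validate(self) -> None:
        missing = [
            p
            for p in (self.corpus, self.pig_range, self.regions, self.curation, self.keywords)
            if p is not None and not os.path.exists(p)
        ]
        if missing:
            raise FileNotFoundError(f"input file(s) not found: {', '.join(missing)}")


@dataclass
class RunResult:
    """In-memory result of one pipeline run."""

    report: SummaryReport
    annotations: list[ThreatAnnotation]
    retained: list[TaxonRecord]
    flagged: list[keyword_screen.MatchResult]
    stage_counts: dict[str, int] = field(default_factory=dict)


def run(
    records: Sequence[TaxonRecord],
    pig_range: PigRangeMap,
    regions: RegionTable,
    curation: Mapping[str, CurationEntry],
    keywords: Optional[KeywordSet] = None,
    strict: bool = True,
) -> RunResult:
    """Run the full analysis on in-memory inputs."""
    records_by_id = {r.taxon_id: r for r in records}

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise PipelineError(name, exc) from exc

    flagged = stage("screen", keyword_screen.screen_corpus, records, keywords)
    confirmed = stage(
        "review",
        threat_classify.apply_review,
        flagged,
        records_by_id,
        curation,
        strict=strict,
    )
    annotations = stage("classify", threat_classify.annotate, confirmed)
    retained = stage(
        "geography", geography.retain_in_range, records, annotations, pig_range
    )
    retained_ids = {r.taxon_id for r in retained}
    kept_annotations = [a for a in annotations if a.taxon_id in retained_ids]
    overlaps = [geography.range_overlap(r, pig_range) for r in retained]
    report = stage(
        "summarize", summarize.build_report, kept_annotations, retained, regions, overlaps
    )
    counts = {
        "n_records": len(records),
        "n_flagged": len(flagged),
        "n_confirmed": len(confirmed),
        "n_retained": len(retained),
        "n_threatened": report.n_threatened,
    }
    logger.info(
        "pipeline: %(n_records)d records, %(n_flagged)d flagged, "
        "%(n_confirmed)d confirmed, %(n_retained)d retained, "
        "%(n_threatened)d threatened",
        counts,
    )
    return RunResult(
        report=report,
        annotations=kept_annotations,
        retained=retained,
        flagged=flagged,
        stage_counts=counts,
    )


def _sha256(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> RunResult:
    """Run from files and write all stage outputs plus a manifest.

    Outputs: ``review_queue.csv`` (the flagged subset), ``annotated.csv``
    (per-taxon classifications), ``report.json`` / ``report.md`` (the full
    summary), ``region_stats.csv`` (per-region counts and percentages) and
    ``manifest.json`` (input hashes and stage counts).
    """
    config.validate()
    records = corpus_io.read_corpus(config.corpus, schema=config.corpus_schema)
    pig_range = corpus_io.read_pig_range(config.pig_range)
    regions = corpus_io.read_regions(config.regions)
    curation = corpus_io.read_curation(config.curation)
    keywords = (
        keyword_screen.load_keywords(config.keywords) if config.keywords else None
    )
    result = run(
        records, pig_range, regions, curation, keywords=keywords, strict=config.strict
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "review_queue.csv", "w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["taxon_id", "tokens", "patterns", "prefix_only"]
        )
        writer.writeheader()
        writer.writerows(keyword_screen.review_queue_rows(result.flagged))
    corpus_io.write_annotations(result.annotations, out / "annotated.csv")
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        fh.write(result.report.to_json())
        fh.write("\n")
    with open(out / "report.md", "w", encoding="utf-8") as fh:
        fh.write(result.report.to_markdown())
    with open(out / "region_stats.csv", "w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["region", "group", "threatened", "assessed", "percent"]
        )
        writer.writeheader()
        writer.writerows(summarize.region_csv_rows(result.report.region_props))
    manifest = {
        "inputs": {
            name: {"path": str(path), "sha256": _sha256(path)}
            for name, path in (
                ("corpus", config.corpus),
                ("pig_range", config.pig_range),
                ("regions", config.regions),
                ("curation", config.curation),
                *((("keywords", config.keywords),) if config.keywords else ()),
            )
        },
        "strict": config.strict,
        "stage_counts": result.stage_counts,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return result
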