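"""Read and write the tabular inputs and outputs of the pipeline.

All tables are plain UTF-8 CSV (comma-separated, first row header, quoted
fields may contain commas and newlines); the corpus may alternatively be a
JSON array of objects with the same field names.  Administrative-unit codes
are opaque strings joined exactly (case-sensitive) across the corpus, range
and region tables.
"""

from __future__ import annotations

import csv
import json
import os
from typing import Iterable, Sequence

import pandas as pd

from .types import (
    Category,
    Cue,
    CurationEntry,
    Mechanism,
    PigRangeMap,
    RangeStatus,
    RegionTable,
    Severity,
    TaxonClass,
    TaxonRecord,
    ThreatAnnotation,
    Verdict,
)


class SchemaError(ValueError):
    """A table is missing a mandatory column or uses an unknown layout."""


class ValidationError(ValueError):
    """A row violates a field constraint (bad enum token, duplicate id...)."""


CORPUS_COLUMNS = [
    "taxon_id",
    "scientific_name",
    "taxon_class",
    "family",
    "category",
    "units",
    "threats_text",
    "range_text",
    "endemic_to",
]


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing mandatory column(s): {', '.join(missing)}")


def _parse_enum(enum_cls, token: str, row: int, field: str):
    try:
        return enum_cls(token)
    except ValueError:
        raise ValidationError(
            f"row {row}: unknown {field} code {token!r} "
            f"(expected one of {[e.value for e in enum_cls]})"
        ) from None


def _record_from_fields(row_num: int, fields: dict[str, str]) -> TaxonRecord:
    units_raw = (fields.get("units") or "").strip()
    units = frozenset(u for u in (p.strip() for p in units_raw.split(";")) if u)
    endemic = (fields.get("endemic_to") or "").strip() or None
    try:
        return TaxonRecord(
            taxon_id=fields["taxon_id"].strip(),
            scientific_name=fields.get("scientific_name", "").strip(),
            taxon_class=_parse_enum(
                TaxonClass, fields["taxon_class"].strip(), row_num, "taxon_class"
            ),
            family=fields.get("family", "").strip(),
            category=_parse_enum(
                Category, fields["category"].strip(), row_num, "category"
            ),
            threats_text=fields.get("threats_text") or "",
            range_text=fields.get("range_text") or "",
            units=units,
            endemic_to=endemic,
        )
    except ValueError as exc:
        if isinstance(exc, (SchemaError, ValidationError)):
            raise
        raise ValidationError(f"row {row_num}: {exc}") from None


def read_corpus(path: str | os.PathLike, schema: str = "csv") -> list[TaxonRecord]:
    """Read a taxon corpus; row order is preserved.

    ``schema`` is ``"csv"`` or ``"json"``.  Duplicate taxon_id values are an
    error; unknown category or class codes raise :class:`ValidationError`
    citing the 1-based data row.
    """
    if schema == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        _require_columns(df, ["taxon_id", "taxon_class", "category"], "corpus")
        rows = df.to_dict(orient="records")
    elif schema == "json":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        if not isinstance(data, list):
            raise SchemaError("corpus JSON must be an array of objects")
        rows = data
        for i, row in enumerate(rows, start=1):
            missing = [c for c in ("taxon_id", "taxon_class", "category") if c not in row]
            if missing:
                raise SchemaError(
                    f"corpus row {i}: missing mandatory column(s): {', '.join(missing)}"
                )
    else:
        raise SchemaError(f"unknown corpus schema {schema!r}")

    records: list[TaxonRecord] = []
    seen: set[str] = set()
    for i, fields in enumerate(rows, start=1):
        if isinstance(fields.get("units"), list):  # JSON may carry a real array
            fields = dict(fields, units=";".join(fields["units"]))
        rec = _record_from_fields(i, {k: ("" if v is None else str(v)) for k, v in fields.items()})
        if rec.taxon_id in seen:
            raise ValidationError(f"row {i}: duplicate taxon_id {rec.taxon_id!r}")
        seen.add(rec.taxon_id)
        records.append(rec)
    return records


def write_corpus(records: Iterable[TaxonRecord], path: str | os.PathLike) -> None:
    """Write records to corpus CSV; round-trips exactly through read_corpus."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CORPUS_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.taxon_id,
                    rec.scientific_name,
                    rec.taxon_class.value,
                    rec.family,
                    rec.category.value,
                    ";".join(sorted(rec.units)),
                    rec.threats_text,
                    rec.range_text,
                    rec.endemic_to or "",
                ]
            )


def read_pig_range(path: str | os.PathLike) -> PigRangeMap:
    """Read the two-column ``unit,status`` range table.

    Conflicting duplicate rows for a unit are an error; an empty file yields
    an empty map (every unit absent).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ["unit", "status"], "range table")
    status_by_unit: dict[str, RangeStatus] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        unit = row.unit.strip()
        status = _parse_enum(RangeStatus, row.status.strip(), i, "range status")
        if unit in status_by_unit and status_by_unit[unit] is not status:
            raise ValidationError(
                f"row {i}: conflicting status for unit {unit!r} "
                f"({status_by_unit[unit].value} vs {status.value})"
            )
        status_by_unit[unit] = status
    return PigRangeMap(status_by_unit=status_by_unit)


def read_regions(path: str | os.PathLike) -> RegionTable:
    """Read the ``unit,region,system`` region table."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ["unit", "region", "system"], "region table")
    region_by_unit: dict[str, str] = {}
    system_by_region: dict[str, str] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        unit, region, system = row.unit.strip(), row.region.strip(), row.system.strip()
        if system not in ("island", "continental"):
            raise ValidationError(f"row {i}: unknown system class {system!r}")
        if unit in region_by_unit and region_by_unit[unit] != region:
            raise ValidationError(f"row {i}: conflicting region for unit {unit!r}")
        if region in system_by_region and system_by_region[region] != system:
            raise ValidationError(f"row {i}: conflicting system class for region {region!r}")
        region_by_unit[unit] = region
        system_by_region[region] = system
    return RegionTable(region_by_unit=region_by_unit, system_by_region=system_by_region)


def read_curation(path: str | os.PathLike) -> dict[str, CurationEntry]:
    """Read the curation table keyed by taxon_id.

    Columns: ``taxon_id, verdict, cues (semicolon-joined), stated_grade``.
    Unknown cue or verdict tokens are validation errors.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ["taxon_id", "verdict"], "curation table")
    entries: dict[str, CurationEntry] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        taxon_id = row.taxon_id.strip()
        verdict = _parse_enum(Verdict, row.verdict.strip(), i, "verdict")
        cues_raw = getattr(row, "cues", "") or ""
        cues = frozenset(
            _parse_enum(Cue, tok, i, "cue")
            for tok in (p.strip() for p in cues_raw.split(";"))
            if tok
        )
        grade_raw = (getattr(row, "stated_grade", "") or "").strip()
        grade = _parse_enum(Severity, grade_raw, i, "stated_grade") if grade_raw else None
        if taxon_id in entries:
            raise ValidationError(f"row {i}: duplicate curation entry for {taxon_id!r}")
        entries[taxon_id] = CurationEntry(
            taxon_id=taxon_id, verdict=verdict, cues=cues, stated_grade=grade
        )
    return entries


def write_annotations(
    annotations: Iterable[ThreatAnnotation], path: str | os.PathLike
) -> None:
    """Write the annotated corpus: taxon_id, severity, mechanisms, cues."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["taxon_id", "pig_threatened", "severity", "mechanisms", "cues"])
        for ann in annotations:
            writer.writerow(
                [
                    ann.taxon_id,
                    str(ann.pig_threatened).lower(),
                    ann.severity.value if ann.severity else "",
                    ";".join(sorted(m.value for m in ann.mechanisms)),
                    ";".join(sorted(c.value for c in ann.cues)),
                ]
            )


def read_annotations(path: str | os.PathLike) -> list[ThreatAnnotation]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ["taxon_id", "pig_threatened"], "annotations")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        severity = row.severity.strip() if row.severity.strip() else None
        out.append(
            ThreatAnnotation(
                taxon_id=row.taxon_id.strip(),
                pig_threatened=row.pig_threatened.strip().lower() == "true",
                severity=_parse_enum(Severity, severity, i, "severity") if severity else None,
                mechanisms=frozenset(
                    _parse_enum(Mechanism, tok, i, "mechanism")
                    for tok in row.mechanisms.split(";")
                    if tok
                ),
                cues=frozenset(
                    _parse_enum(Cue, tok, i, "cue") for tok in row.cues.split(";") if tok
                ),
            )
        )
    return out


def corpus_to_frame(records: Iterable[TaxonRecord]) -> pd.DataFrame:
    """Corpus as a DataFrame (one row per record) for ad-hoc analysis."""
    rows = [
        {
            "taxon_id": r.taxon_id,
            "scientific_name": r.scientific_name,
            "taxon_class": r.taxon_class.value,
            "family": r.family,
            "category": r.category.value,
            "units": ";".join(sorted(r.units)),
            "threats_text": r.threats_text,
            "range_text": r.range_text,
            "endemic_to": r.endemic_to or "",
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=CORPUS_COLUMNS)
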