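"""Systematic keyword search over "Major Threats" narratives.

Matching is deliberately over-inclusive: wildcard patterns such as ``pig*``
match any token starting with the stem (``pig``, ``pigs``, ``piglet`` — but
also ``pigeon`` and ``pigment``).  Screening therefore produces a
*review queue*, not a final answer; false positives are removed later by
curation (:func:`threatminer.threat_classify.apply_review`).  Nothing is
auto-excluded at screen time.

Only the threats narrative of a record is screened, never the range text.
"""

from __future__ import annotations

import importlib.resources
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import yaml

from .types import TaxonRecord


@dataclass(frozen=True)
class KeywordSet:
    """Literal tokens and wildcard prefix stems, all lower-cased.

    ``literals`` match a token exactly; ``prefixes`` match any token that
    starts with the stem (the token itself included, so a stem subsumes the
    identical literal).
    """

    literals: frozenset[str]
    prefixes: frozenset[str]

    def __post_init__(self) -> None:
        for tok in self.literals | self.prefixes:
            if not tok or not tok.isalpha() or tok != tok.lower():
                raise ValueError(f"keyword patterns must be lower-case words: {tok!r}")

    @classmethod
    def from_patterns(cls, patterns: Iterable[str]) -> "KeywordSet":
        """Build from raw patterns; a trailing ``*`` marks a prefix stem."""
        literals, prefixes = set(), set()
        for pat in patterns:
            pat = pat.strip().lower()
            if not pat:
                continue
            if pat.endswith("*"):
                prefixes.add(pat[:-1])
            else:
                literals.add(pat)
        return cls(literals=frozenset(literals), prefixes=frozenset(prefixes))

    def with_pattern(self, pattern: str) -> "KeywordSet":
        return KeywordSet.from_patterns(
            list(self.literals) + [p + "*" for p in self.prefixes] + [pattern]
        )


def default_keywords() -> KeywordSet:
    """The shipped 13-pattern wild-pig keyword list."""
    ref = importlib.resources.files("threatminer").joinpath("data/keywords.yaml")
    cfg = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return KeywordSet.from_patterns(cfg["patterns"])


def load_keywords(path: str | os.PathLike) -> KeywordSet:
    """Load a keyword config: YAML with a ``patterns`` list, or a one-column
    CSV/plain list with one pattern per line."""
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    if str(path).endswith((".yaml", ".yml")):
        cfg = yaml.safe_load(text)
        patterns = cfg["patterns"] if isinstance(cfg, dict) else cfg
    else:
        lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
        if lines and lines[0].lower() in ("pattern", "patterns"):
            lines = lines[1:]
        patterns = lines
    return KeywordSet.from_patterns(patterns)


@dataclass(frozen=True)
class Hit:
    """One matched token: where it sits in the text and which patterns hit."""

    token: str
    offset: int
    via_literals: frozenset[str]
    via_prefixes: frozenset[str]


@dataclass(frozen=True)
class MatchResult:
    taxon_id: str
    hits: tuple[Hit, ...] = field(default_factory=tuple)

    @property
    def flagged(self) -> bool:
        return bool(self.hits)

    @property
    def prefix_only(self) -> bool:
        """True when every hit matched only via a wildcard prefix.

        Prefix-only flags (e.g. a narrative mentioning only "pigeons") are
        the archetypal false positives and the first thing reviewers check.
        """
        return bool(self.hits) and all(not h.via_literals for h in self.hits)


def tokenize(text: str) -> list[tuple[str, int]]:
    """Split text into maximal runs of letters, lower-cased, with offsets.

    Digits, hyphens, parentheses and all punctuation are separators, so
    "pig-nosed" yields the tokens "pig" and "nosed".
    """
    tokens: list[tuple[str, int]] = []
    start = None
    for i, ch in enumerate(text):
        if ch.isalpha():
            if start is None:
                start = i
        elif start is not None:
            tokens.append((text[start:i].lower(), start))
            start = None
    if start is not None:
        tokens.append((text[start:].lower(), start))
    return tokens


def match_keywords(text: str, kw: KeywordSet, taxon_id: str = "") -> MatchResult:
    """Match every token of ``text`` against the keyword set.

    A token hits iff it equals a literal or begins with a prefix stem; all
    matching patterns are recorded on the hit.
    """
    if not (kw.literals or kw.prefixes):
        raise ValueError("keyword set is empty")
    hits = []
    for token, offset in tokenize(text):
        via_literals = frozenset(l for l in kw.literals if token == l)
        via_prefixes = frozenset(p for p in kw.prefixes if token.startswith(p))
        if via_literals or via_prefixes:
            hits.append(
                Hit(
                    token=token,
                    offset=offset,
                    via_literals=via_literals,
                    via_prefixes=via_prefixes,
                )
            )
    return MatchResult(taxon_id=taxon_id, hits=tuple(hits))


def screen_corpus(
    records: Iterable[TaxonRecord], kw: KeywordSet | None = None
) -> list[MatchResult]:
    """Screen each record's threats narrative; return the flagged subset.

    The flagged subset is the manual-review queue: every downstream threat
    analysis is restricted to it.  Records whose narrative contains no
    keyword token are dropped from the analysis here.
    """
    kw = kw or default_keywords()
    flagged = []
    for rec in records:
        result = match_keywords(rec.threats_text, kw, taxon_id=rec.taxon_id)
        if result.flagged:
            flagged.append(result)
    return flagged


def review_queue_rows(results: Sequence[MatchResult]) -> list[dict[str, str]]:
    """Review-queue CSV rows: taxon_id, matched tokens, patterns, prefix_only."""
    rows = []
    for res in results:
        patterns = sorted(
            {l for h in res.hits for l in h.via_literals}
            | {p + "*" for h in res.hits for p in h.via_prefixes}
        )
        rows.append(
            {
                "taxon_id": res.taxon_id,
                "tokens": ";".join(sorted({h.token for h in res.hits})),
                "patterns": ";".join(patterns),
                "prefix_only": str(res.prefix_only).lower(),
            }
        )
    return rows
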