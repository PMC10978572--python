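"""Parse OpenIE triples in the bracketed-context dialect and entity-link them.

An extractor emits subject–predicate–object triples where each argument
carries its sentence context in square brackets, e.g.::

    (RB1 [the retinoblastoma protein RB1]; EXPRESSES [expresses an aberrant
     underphosphorylated form]; NCI-H209 [small-cell lung cancer cell line
     (NCI-H209)])

The extractor itself is a pluggable input — this module owns only the
contract: parsing the dialect from TSV/JSONL (malformed records are
collected into an error report, never silently dropped), and linking each
side's text (head plus context) against the entity dictionary. Predicates
stay open-vocabulary; normalization is display-only (uppercased head).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .entity_dictionary import EntityDictionary, match_text

EXPLICIT_COLUMNS = (
    "pmid",
    "sentence_index",
    "subject_head",
    "subject_context",
    "predicate_head",
    "predicate_context",
    "object_head",
    "object_context",
)
BRACKET_COLUMNS = ("pmid", "sentence_index", "subject", "predicate", "object")


class TripleFormatError(ValueError):
    """Raised when a triples file as a whole cannot be interpreted."""


@dataclass(frozen=True)
class RawTriple:
    """One extraction as read from the input, contexts included."""

    pmid: str
    sentence_index: int
    subject_head: str
    subject_context: str
    predicate_head: str
    predicate_context: str
    object_head: str
    object_context: str


@dataclass(frozen=True)
class LinkedTriple:
    """A raw triple with its subject/object resolved to entity ids."""

    raw: RawTriple
    subject_entities: frozenset[str]
    object_entities: frozenset[str]
    predicate_label: str

    @property
    def is_linked(self) -> bool:
        """True when both sides matched at least one entity."""
        return bool(self.subject_entities) and bool(self.object_entities)

    @property
    def self_referential(self) -> bool:
        """True when the same entity appears on both sides (excluded from edges)."""
        return bool(self.subject_entities & self.object_entities)

    def entity_pairs(self) -> list[tuple[str, str]]:
        """All (subject_entity, object_entity) combinations, self-pairs excluded."""
        return [
            (s, o)
            for s in sorted(self.subject_entities)
            for o in sorted(self.object_entities)
            if s != o
        ]


def split_head_context(arg: str) -> tuple[str, str]:
    """Split ``"head [context]"`` into (head, context).

    The context is the bracket group that closes at the end of the
    argument, found by balanced matching so heads that themselves contain
    brackets (``"p16 [INK4a]"``) survive. An argument with no bracketed
    context is its own context.
    """
    arg = arg.strip()
    if arg.endswith("]"):
        depth = 0
        for i in range(len(arg) - 1, -1, -1):
            if arg[i] == "]":
                depth += 1
            elif arg[i] == "[":
                depth -= 1
                if depth == 0:
                    if i > 0 and arg[i - 1] == " ":
                        return arg[: i - 1].strip(), arg[i + 1 : -1].strip()
                    break
    return arg, arg


def _split_top_level(body: str) -> list[str]:
    """Split a triple body on ';' outside square brackets."""
    parts, depth, buf = [], 0, []
    for ch in body:
        if ch == "[":
            depth += 1
        elif ch == "]":
            depth = max(0, depth - 1)
        if ch == ";" and depth == 0:
            parts.append("".join(buf))
            buf = []
        else:
            buf.append(ch)
    parts.append("".join(buf))
    return [p.strip() for p in parts]


def parse_triple_string(s: str, pmid: str = "", sentence_index: int = 0) -> RawTriple:
    """Parse one full bracketed triple string ``(subj [..]; pred [..]; obj [..])``."""
    body = s.strip()
    if body.startswith("(") and body.endswith(")"):
        body = body[1:-1]
    parts = _split_top_level(body)
    if len(parts) != 3:
        raise TripleFormatError(f"expected 3 ';'-separated arguments, got {len(parts)}: {s!r}")
    (sh, sc), (ph, pc), (oh, oc) = (split_head_context(p) for p in parts)
    if not (sh and ph and oh):
        raise TripleFormatError(f"empty head in triple: {s!r}")
    return RawTriple(pmid, sentence_index, sh, sc, ph, pc, oh, oc)


@dataclass
class ParseReport:
    """Outcome of parsing a triples file: records plus per-record errors."""

    triples: list[RawTriple] = field(default_factory=list)
    errors: list[dict] = field(default_factory=list)

    @property
    def n_parsed(self) -> int:
        return len(self.triples)

    @property
    def n_failed(self) -> int:
        return len(self.errors)


def _triple_from_record(rec: dict, lineno: int) -> RawTriple:
    if all(c in rec for c in EXPLICIT_COLUMNS):
        vals = {c: str(rec[c]).strip() for c in EXPLICIT_COLUMNS}
    elif all(c in rec for c in BRACKET_COLUMNS):
        vals = {"pmid": str(rec["pmid"]).strip()}
        for side in ("subject", "predicate", "object"):
            head, ctx = split_head_context(str(rec[side]))
            vals[f"{side}_head"], vals[f"{side}_context"] = head, ctx
        vals["sentence_index"] = str(rec["sentence_index"]).strip()
    else:
        raise TripleFormatError(f"record {lineno}: unrecognized fields {sorted(rec)}")
    for side in ("subject", "predicate", "object"):
        if not vals[f"{side}_head"]:
            raise TripleFormatError(f"record {lineno}: empty {side} head")
        if not vals[f"{side}_context"]:
            vals[f"{side}_context"] = vals[f"{side}_head"]
    try:
        sent = int(vals["sentence_index"])
    except ValueError as exc:
        raise TripleFormatError(f"record {lineno}: bad sentence_index") from exc
    return RawTriple(
        pmid=vals["pmid"],
        sentence_index=sent,
        subject_head=vals["subject_head"],
        subject_context=vals["subject_context"],
        predicate_head=vals["predicate_head"],
        predicate_context=vals["predicate_context"],
        object_head=vals["object_head"],
        object_context=vals["object_context"],
    )


def parse_triples(path: str | Path) -> ParseReport:
    """Parse a triples file (TSV with header, or JSON Lines).

    TSV accepts either the explicit eight-column layout or the five-column
    bracket dialect (subject/predicate/object cells as ``head [context]``).
    Per-record failures go into the report's error list with line numbers;
    an unreadable file raises.
    """
    path = Path(path)
    report = ParseReport()
    if path.suffix in (".jsonl", ".json"):
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                try:
                    report.triples.append(_triple_from_record(json.loads(line), lineno))
                except (TripleFormatError, json.JSONDecodeError) as exc:
                    report.errors.append({"line": lineno, "error": str(exc)})
    else:
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            header = set(reader.fieldnames or [])
            if not (set(EXPLICIT_COLUMNS) <= header or set(BRACKET_COLUMNS) <= header):
                raise TripleFormatError(f"{path}: unrecognized header {sorted(header)}")
            for lineno, row in enumerate(reader, 2):
                try:
                    if any(v is None for v in row.values()):
                        raise TripleFormatError(f"record {lineno}: missing field(s)")
                    report.triples.append(_triple_from_record(row, lineno))
                except TripleFormatError as exc:
                    report.errors.append({"line": lineno, "error": str(exc)})
    return report


def _side_text(head: str, context: str) -> str:
    return head if context == head else f"{head} {context}"


def link_triple(t: RawTriple, dictionary: EntityDictionary) -> LinkedTriple:
    """Entity-link one raw triple against the dictionary.

    Mention detection runs over the concatenation of head and context for
    each side; every matched entity id is kept (a context naming two cell
    lines links both). A triple with an unmatched side is retained but
    reports ``is_linked == False``.
    """
    subject = frozenset(
        m.entity_id for m in match_text(_side_text(t.subject_head, t.subject_context), dictionary)
    )
    obj = frozenset(
        m.entity_id for m in match_text(_side_text(t.object_head, t.object_context), dictionary)
    )
    return LinkedTriple(
        raw=t,
        subject_entities=subject,
        object_entities=obj,
        predicate_label=t.predicate_head.upper(),
    )


def link_triples(
    triples: Iterable[RawTriple],
    dictionary: EntityDictionary,
    corpus_pmids: set[str] | None = None,
) -> tuple[list[LinkedTriple], list[RawTriple]]:
    """Link a collection; triples citing a PMID absent from the corpus are
    quarantined (returned separately, never silently dropped)."""
    linked: list[LinkedTriple] = []
    quarantined: list[RawTriple] = []
    for t in triples:
        if corpus_pmids is not None and t.pmid not in corpus_pmids:
            quarantined.append(t)
        else:
            linked.append(link_triple(t, dictionary))
    return linked, quarantined


def evidence_snippet(t: RawTriple) -> str:
    """Human-readable evidence string for a triple's provenance."""
    return f"{t.subject_context} | {t.predicate_context} | {t.object_context}"
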