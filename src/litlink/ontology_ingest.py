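"""Load heterogeneous ontology and nomenclature sources into uniform records.

Five entity categories are supported, each from the file dialect a small,
testable deployment can actually carry:

* ``disease`` / ``anatomy`` — OBO 1.2/1.4 ontologies (e.g. an NCIt cancer
  subset, UBERON), parsed with :mod:`obonet`;
* ``cell_line`` — a registry dump TSV (accession, name, pipe-separated
  synonyms, parent accession), the shape of a Cellosaurus-style index;
* ``gene`` — a nomenclature TSV (symbol, full name, pipe-separated aliases),
  the shape of an HGNC export;
* ``cytoband`` — a TSV of band label, chromosome, start, end.

Every record gets a namespaced ``entity_id`` so identical strings from
different sources never collide (``gene:TP53`` vs a disease CURIE). Parent
links (``is_a`` targets, parental cell-line accessions) feed a directed
acyclic :class:`HierarchyGraph` used for parent-of edges in the knowledge
graph.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

CATEGORIES = ("disease", "anatomy", "cell_line", "cytoband", "gene")


class OntologyFormatError(ValueError):
    """Raised for malformed or inconsistent ontology/nomenclature input."""


@dataclass(frozen=True)
class EntityRecord:
    """One ontology concept: identifier, category, names, parent links."""

    entity_id: str
    category: str
    canonical_name: str
    synonyms: tuple[str, ...] = ()
    parent_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.entity_id:
            raise ValueError("entity_id must be non-empty")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if not self.canonical_name:
            raise ValueError(f"canonical_name empty for {self.entity_id}")


@dataclass
class HierarchyGraph:
    """Directed parent→child DAG over entity ids."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges)

    def children(self, parent_id: str) -> list[str]:
        return sorted(self.graph.successors(parent_id))

    def parents(self, child_id: str) -> list[str]:
        return sorted(self.graph.predecessors(child_id))


def build_hierarchy(
    records: Iterable[EntityRecord], on_dangling: str = "error"
) -> HierarchyGraph:
    """Assemble the parent→child DAG from the records' parent links.

    ``on_dangling`` controls parent ids that reference no loaded record:
    ``"error"`` rejects the collection, ``"drop"`` logs and skips the link.
    Self-loops and cycles are always rejected.
    """
    if on_dangling not in ("error", "drop"):
        raise ValueError("on_dangling must be 'error' or 'drop'")
    records = list(records)
    known = {r.entity_id for r in records}
    g = nx.DiGraph()
    g.add_nodes_from(known)
    for rec in records:
        for parent in rec.parent_ids:
            if parent == rec.entity_id:
                raise OntologyFormatError(f"self-loop on {rec.entity_id}")
            if parent not in known:
                if on_dangling == "error":
                    raise OntologyFormatError(
                        f"dangling parent {parent!r} referenced by {rec.entity_id}"
                    )
                logger.warning("dropping dangling parent %s of %s", parent, rec.entity_id)
                continue
            g.add_edge(parent, rec.entity_id)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise OntologyFormatError(f"hierarchy contains a cycle: {cycle}")
    return HierarchyGraph(graph=g)


def validate_records(records: Sequence[EntityRecord]) -> None:
    """Check entity_id uniqueness within a collection."""
    seen: set[str] = set()
    for rec in records:
        if rec.entity_id in seen:
            raise OntologyFormatError(f"duplicate entity_id {rec.entity_id!r}")
        seen.add(rec.entity_id)


_OBO_SYNONYM_RE = re.compile(r'"((?:[^"\\]|\\.)*)"')


def _obo_synonyms(data: dict) -> list[str]:
    """Extract synonym strings from an obonet node, all scopes."""
    out = []
    for raw in data.get("synonym", []):
        m = _OBO_SYNONYM_RE.search(raw)
        if m:
            out.append(m.group(1).replace('\\"', '"'))
    return out


def load_obo(
    path: str | Path, category: str, include_obsolete: bool = False
) -> list[EntityRecord]:
    """Read an OBO 1.2/1.4 ontology into entity records.

    One record per non-obsolete term (obsolete terms are excluded unless
    ``include_obsolete``, favouring dictionary precision); synonyms are
    collected from all synonym scopes; ``is_a`` targets become parent ids.
    """
    if category not in ("disease", "anatomy"):
        raise ValueError(f"OBO sources map to disease/anatomy, not {category!r}")
    path = Path(path)
    try:
        graph = obonet.read_obo(str(path), ignore_obsolete=not include_obsolete)
    except OSError:
        raise
    except Exception as exc:  # obonet raises assorted parse errors
        raise OntologyFormatError(f"malformed OBO file {path}: {exc}") from exc
    records = []
    for term_id, data in graph.nodes(data=True):
        name = data.get("name")
        if not name:
            raise OntologyFormatError(f"OBO term {term_id} has no name")
        records.append(
            EntityRecord(
                entity_id=term_id,
                category=category,
                canonical_name=name,
                synonyms=tuple(_obo_synonyms(data)),
                parent_ids=tuple(sorted(data.get("is_a", []))),
            )
        )
    records.sort(key=lambda r: r.entity_id)
    validate_records(records)
    return records


def _split_multi(value: str) -> tuple[str, ...]:
    """Split a pipe- or semicolon-separated synonym field."""
    if not value:
        return ()
    parts = re.split(r"[|;]", value)
    return tuple(p.strip() for p in parts if p.strip())


def _read_tsv(path: str | Path, required: Sequence[str]) -> list[dict[str, str]]:
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in required if c not in header]
        if missing:
            raise OntologyFormatError(f"{path}: missing column(s) {missing}")
        return [{k: (v or "").strip() for k, v in row.items()} for row in reader]


def load_cell_line_registry(path: str | Path) -> list[EntityRecord]:
    """Read a cell-line registry TSV (accession, name, synonyms, parent_accession).

    The registry name is the canonical name (matched case-exactly downstream);
    the parental/originating line's accession becomes the parent id, so a
    derivation chain loads as a parent-of path.
    """
    rows = _read_tsv(path, ("accession", "name"))
    records = []
    for row in rows:
        if not row["accession"]:
            raise OntologyFormatError(f"{path}: row with empty accession: {row}")
        parent = row.get("parent_accession", "")
        records.append(
            EntityRecord(
                entity_id=f"cell_line:{row['accession']}",
                category="cell_line",
                canonical_name=row["name"],
                synonyms=_split_multi(row.get("synonyms", "")),
                parent_ids=(f"cell_line:{parent}",) if parent else (),
            )
        )
    validate_records(records)
    return records


def load_gene_nomenclature(
    path: str | Path, on_duplicate: str = "reject"
) -> list[EntityRecord]:
    """Read a gene nomenclature TSV (symbol, name, aliases).

    The official symbol is the canonical name, stored case-exact; the full
    name and all aliases become synonyms. ``on_duplicate`` is ``"reject"``
    (error on a repeated symbol) or ``"keep-first"`` (log and skip).
    """
    if on_duplicate not in ("reject", "keep-first"):
        raise ValueError("on_duplicate must be 'reject' or 'keep-first'")
    rows = _read_tsv(path, ("symbol", "name"))
    records: list[EntityRecord] = []
    seen: set[str] = set()
    for row in rows:
        symbol = row["symbol"]
        if not symbol:
            raise OntologyFormatError(f"{path}: row with empty symbol: {row}")
        if symbol in seen:
            if on_duplicate == "reject":
                raise OntologyFormatError(f"{path}: duplicate symbol {symbol!r}")
            logger.warning("duplicate gene symbol %s: keeping first", symbol)
            continue
        seen.add(symbol)
        synonyms = _split_multi(row.get("aliases", ""))
        if row["name"]:
            synonyms = (row["name"],) + synonyms
        records.append(
            EntityRecord(
                entity_id=f"gene:{symbol}",
                category="gene",
                canonical_name=symbol,
                synonyms=synonyms,
            )
        )
    return records


def load_cytobands(path: str | Path) -> list[EntityRecord]:
    """Read a cytoband TSV (label, chrom, start, end) into positional entities.

    Arm-only labels ("17q") are accepted; a non-positive interval is a
    validation error. Cytobands have no parents.
    """
    rows = _read_tsv(path, ("label", "chrom", "start", "end"))
    records = []
    for row in rows:
        try:
            start, end = int(row["start"]), int(row["end"])
        except ValueError as exc:
            raise OntologyFormatError(f"{path}: non-integer coordinates: {row}") from exc
        if start >= end:
            raise OntologyFormatError(
                f"{path}: band {row['label']!r} has start {start} >= end {end}"
            )
        records.append(
            EntityRecord(
                entity_id=f"cytoband:{row['label']}",
                category="cytoband",
                canonical_name=row["label"],
            )
        )
    validate_records(records)
    return records


def write_records_jsonl(records: Iterable[EntityRecord], path: str | Path) -> None:
    """Serialize records to JSON Lines (one record per line)."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(
                json.dumps(
                    {
                        "entity_id": rec.entity_id,
                        "category": rec.category,
                        "canonical_name": rec.canonical_name,
                        "synonyms": list(rec.synonyms),
                        "parent_ids": list(rec.parent_ids),
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_records_jsonl(path: str | Path) -> list[EntityRecord]:
    """Read records serialized by :func:`write_records_jsonl`."""
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            d = json.loads(line)
            records.append(
                EntityRecord(
                    entity_id=d["entity_id"],
                    category=d["category"],
                    canonical_name=d["canonical_name"],
                    synonyms=tuple(d.get("synonyms", ())),
                    parent_ids=tuple(d.get("parent_ids", ())),
                )
            )
    validate_records(records)
    return records
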