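"""Knowledge-graph assembly and export.

The graph holds exactly what the text and the ontologies assert — no
inferred edges. Three edge types are kept distinct:

* ``relation`` — one edge per (subject entity, object entity) combination of
  each fully linked triple, carrying the predicate label, source PMID and
  an evidence snippet assembled from the triple's contexts;
* ``pair`` — high-recall proximity evidence (a scored entity pair in one
  abstract) with its total score; never merged into relation edges, since
  pair-only evidence is a weaker inference than an explicit predicate;
* ``parent-of`` — ontology hierarchy edges (parental cell line → derived
  line, and any other loaded parent links).

The in-memory store is a :class:`networkx.MultiDiGraph`; exports are
GraphML or a nodes.csv/edges.csv pair, both round-trippable.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .ontology_ingest import EntityRecord, HierarchyGraph
from .relation_scoring import PairScore
from .triple_ingest import LinkedTriple, evidence_snippet


class GraphBuildError(ValueError):
    """Raised on referential breakage while assembling the graph."""


def build_graph(
    triples: Iterable[LinkedTriple],
    scores: Iterable[PairScore] = (),
    hierarchy: HierarchyGraph | None = None,
    records: Iterable[EntityRecord] = (),
    score_threshold: float = 0.0,
) -> nx.MultiDiGraph:
    """Assemble the knowledge graph from one pipeline run.

    Nodes are created only for entities that appear in at least one fully
    linked triple or pair score, plus hierarchy neighbours of such
    entities. Pair scores below ``score_threshold`` are dropped (default 0
    keeps all). An edge endpoint with no category information is a build
    error.
    """
    meta: dict[str, tuple[str, str]] = {}
    for rec in records:
        meta[rec.entity_id] = (rec.category, rec.canonical_name)

    g = nx.MultiDiGraph()

    def add_node(eid: str) -> None:
        if g.has_node(eid):
            return
        if eid not in meta:
            raise GraphBuildError(f"edge endpoint {eid!r} has no entity record")
        category, name = meta[eid]
        g.add_node(eid, category=category, name=name)

    for t in triples:
        if not t.is_linked or t.self_referential:
            continue
        for s, o in t.entity_pairs():
            add_node(s)
            add_node(o)
            g.add_edge(
                s,
                o,
                type="relation",
                predicate=t.predicate_label,
                pmid=t.raw.pmid,
                evidence=evidence_snippet(t.raw),
            )
    for sc in scores:
        if sc.total < score_threshold:
            continue
        add_node(sc.e1)
        add_node(sc.e2)
        g.add_edge(sc.e1, sc.e2, type="pair", pmid=sc.pmid, score=float(sc.total))
    if hierarchy is not None:
        seeds = set(g.nodes)
        for parent, child in sorted(hierarchy.edges):
            if parent in seeds or child in seeds:
                add_node(parent)
                add_node(child)
                g.add_edge(parent, child, type="parent-of", label="parent-of")
    return g


def validate_graph(g: nx.MultiDiGraph) -> None:
    """Assert the graph's evidence invariants (every relation edge carries a
    PMID and non-empty snippet; all endpoints are typed nodes)."""
    for u, v, data in g.edges(data=True):
        for node in (u, v):
            if "category" not in g.nodes[node]:
                raise GraphBuildError(f"untyped node {node!r}")
        if data.get("type") == "relation":
            if not data.get("pmid") or not data.get("evidence"):
                raise GraphBuildError(f"relation edge {u}->{v} lacks evidence")


def export_graph(g: nx.MultiDiGraph, fmt: str, out: str | Path) -> list[Path]:
    """Write the graph as ``graphml`` (one file) or ``edge_csv``
    (``<out>/nodes.csv`` + ``<out>/edges.csv``). Returns written paths."""
    out = Path(out)
    if fmt == "graphml":
        nx.write_graphml(g, str(out), named_key_ids=True)
        return [out]
    if fmt == "edge_csv":
        out.mkdir(parents=True, exist_ok=True)
        nodes_path, edges_path = out / "nodes.csv", out / "edges.csv"
        with open(nodes_path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "category", "name"])
            for n, data in sorted(g.nodes(data=True)):
                w.writerow([n, data.get("category", ""), data.get("name", "")])
        with open(edges_path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["source", "target", "type", "predicate", "pmid", "score", "evidence"])
            rows = [
                (
                    u,
                    v,
                    d.get("type", ""),
                    d.get("predicate", ""),
                    d.get("pmid", ""),
                    d.get("score", ""),
                    d.get("evidence", ""),
                )
                for u, v, d in g.edges(data=True)
            ]
            w.writerows(sorted(rows, key=lambda r: tuple(str(x) for x in r)))
        return [nodes_path, edges_path]
    raise ValueError(f"unknown export format {fmt!r}; use 'graphml' or 'edge_csv'")


def import_graphml(path: str | Path) -> nx.MultiDiGraph:
    """Read a GraphML export back into a MultiDiGraph."""
    g = nx.read_graphml(str(path), force_multigraph=True)
    return nx.MultiDiGraph(g)


def query_neighbors(
    g: nx.MultiDiGraph,
    anchor: str,
    edge_types: set[str] | None = None,
) -> list[tuple[str, list[dict]]]:
    """Neighbours of ``anchor`` with all connecting edge payloads.

    Both edge directions are followed (a cell line that is the *object* of
    an EXPRESSES triple still lists the gene). Each payload dict gains a
    ``direction`` key ('out' | 'in'). Output is sorted by neighbour id and
    payload content; an unknown anchor raises ``KeyError``.
    """
    if anchor not in g:
        raise KeyError(f"anchor {anchor!r} not in graph")
    payloads: dict[str, list[dict]] = {}
    for _, v, data in g.out_edges(anchor, data=True):
        if edge_types is None or data.get("type") in edge_types:
            payloads.setdefault(v, []).append({**data, "direction": "out"})
    for u, _, data in g.in_edges(anchor, data=True):
        if edge_types is None or data.get("type") in edge_types:
            payloads.setdefault(u, []).append({**data, "direction": "in"})
    out = []
    for neighbor in sorted(payloads):
        plist = sorted(payloads[neighbor], key=lambda d: sorted(d.items(), key=str))
        out.append((neighbor, plist))
    return out


def relation_edge_pmids(g: nx.MultiDiGraph) -> set[str]:
    """All PMIDs backing relation edges (provenance scan)."""
    return {d["pmid"] for _, _, d in g.edges(data=True) if d.get("type") == "relation"}


def graphs_equal(a: nx.MultiDiGraph, b: nx.MultiDiGraph) -> bool:
    """Node/edge/attribute equality up to edge ordering (round-trip check).

    GraphML stringifies attribute values per its type system, so values are
    compared after string conversion.
    """

    def node_sig(g: nx.MultiDiGraph):
        return sorted((n, sorted((k, str(v)) for k, v in d.items())) for n, d in g.nodes(data=True))

    def edge_sig(g: nx.MultiDiGraph):
        return sorted((u, v, sorted((k, str(w)) for k, w in d.items())) for u, v, d in g.edges(data=True))

    return node_sig(a) == node_sig(b) and edge_sig(a) == edge_sig(b)
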