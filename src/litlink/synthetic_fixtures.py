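"""Seeded synthetic fixtures: toy ontologies, abstracts with planted
mentions, and triples — so every pipeline stage is testable offline.

The generator emulates the statistical structure the proximity score
exploits: association strength is encoded as co-mention *frequency* and
token *distance*. Each planted cell-line–gene pair has a strength class:

* ``high``   — 3 co-mentions per abstract at token distance 3;
* ``medium`` — 2 co-mentions per abstract at token distance 10;
* ``low``    — 1 co-mention per abstract at token distance 35;

(within the documented bands high ≤ 5, medium ≤ 15, low ≥ 30). Entity
morphology mimics the real nomenclatures — uppercase alphanumeric gene
symbols, hyphen/digit cell-line names, disease terms with singular/plural
variants that exercise the lemma matching tier — and filler tokens are
drawn from a closed pool disjoint from every dictionary form, so gold
mention sets are exact and spurious matches are impossible by
construction. Identical specs (including the seed) produce byte-identical
files.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

from .ontology_ingest import EntityRecord, validate_records
from .text_normalization import lemmatize_token

# strength class -> (co-mention events per abstract, token distance)
STRENGTH_PARAMS = {"high": (3, 3), "medium": (2, 10), "low": (1, 35)}

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic study corpus."""

    seed: int = 0
    n_genes: int = 15
    n_cell_lines: int = 5
    n_diseases: int = 4
    n_abstracts: int = 50
    planted_pairs: tuple[tuple[str, str, str], ...] | None = None
    # (cell_line_id, gene_id, strength); None -> high/medium/low per anchor
    triple_rate: float = 0.25
    vocab: int = 60

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_cell_lines", "n_diseases", "n_abstracts", "vocab"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.triple_rate <= 1.0:
            raise ValueError("triple_rate must be in [0, 1]")
        if self.planted_pairs is not None:
            for _cl, _g, strength in self.planted_pairs:
                if strength not in STRENGTH_PARAMS:
                    raise ValueError(f"unknown strength {strength!r}")


@dataclass
class CorpusFixture:
    """In-memory view of one generated corpus plus its gold data."""

    spec: FixtureSpec
    records: list[EntityRecord]
    abstracts: dict[str, str]  # pmid -> text
    gold_mentions: dict[str, list[tuple[int, int, str, str]]]
    # pmid -> [(token_start, token_end, entity_id, surface)]
    gold_pairs: list[tuple[str, str, str]]  # (pmid, gene_id, cell_line_id)
    triple_rows: list[dict] = field(default_factory=list)
    planted_pairs: tuple[tuple[str, str, str], ...] = ()

    @property
    def pmids(self) -> list[str]:
        return sorted(self.abstracts)


def _syllables(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(_CONSONANTS) + rng.choice(_VOWELS) for _ in range(n))


def generate_ontologies(spec: FixtureSpec) -> list[EntityRecord]:
    """Deterministically generate gene, cell-line and disease records.

    Gene symbols are uppercase alphanumerics with a lowercase full name and
    one alias; cell-line names carry hyphens and digits with spaced /
    unhyphenated synonyms and a two-level parentage tree (roots plus
    derived lines); disease terms alternate between singular canonical
    names with plural synonyms and plural-only canonical names (the latter
    are matchable from singular text only through the lemma tier).
    """
    rng = random.Random(f"{spec.seed}:ontologies")
    records: list[EntityRecord] = []

    symbols: set[str] = set()
    for i in range(spec.n_genes):
        sym = f"{_syllables(rng, 1).upper()}{rng.choice('BDKLMNPRST')}{i}"
        while sym in symbols:
            sym = f"{_syllables(rng, 1).upper()}{rng.choice('BDKLMNPRST')}{i}"
        symbols.add(sym)
        records.append(
            EntityRecord(
                entity_id=f"gene:{sym}",
                category="gene",
                canonical_name=sym,
                synonyms=(f"{_syllables(rng, 2)} factor {i}", f"{sym}L"),
            )
        )

    n_roots = max(1, spec.n_cell_lines // 3 + 1)
    cl_names: set[str] = set()
    for i in range(spec.n_cell_lines):
        name = f"{_syllables(rng, 1).upper()}{rng.choice('BCDFG')}-{100 + i}"
        while name in cl_names:
            name = f"{_syllables(rng, 1).upper()}{rng.choice('BCDFG')}-{100 + i}"
        cl_names.add(name)
        parent: tuple[str, ...] = ()
        if i >= n_roots:
            parent = (f"cell_line:SYNCL_{i % n_roots:04d}",)
        records.append(
            EntityRecord(
                entity_id=f"cell_line:SYNCL_{i:04d}",
                category="cell_line",
                canonical_name=name,
                synonyms=(name.replace("-", ""), name.replace("-", " ")),
                parent_ids=parent,
            )
        )

    for i in range(spec.n_diseases):
        stem = _syllables(rng, 2) + "oma"
        if i % 2 == 0:
            canonical, synonyms = stem, (stem + "s",)
        else:  # plural-only canonical: singular text matches via lemma tier
            canonical, synonyms = stem + "s", ()
        records.append(
            EntityRecord(
                entity_id=f"SYND:{i:04d}",
                category="disease",
                canonical_name=canonical,
                synonyms=synonyms,
            )
        )
    validate_records(records)
    return records


def _filler_pool(spec: FixtureSpec, records: Sequence[EntityRecord]) -> list[str]:
    """Closed filler vocabulary, disjoint (case- and lemma-wise) from every
    token of every dictionary form."""
    forbidden: set[str] = set()
    for rec in records:
        for form in (rec.canonical_name, *rec.synonyms):
            for tok in form.split():
                forbidden.add(tok.casefold())
                forbidden.add(lemmatize_token(tok))
    rng = random.Random(f"{spec.seed}:filler")
    pool: list[str] = []
    seen: set[str] = set()
    while len(pool) < spec.vocab:
        w = _syllables(rng, rng.choice((2, 3)))
        if w in seen or w in forbidden or lemmatize_token(w) in forbidden:
            continue
        seen.add(w)
        pool.append(w)
    return pool


def default_planted_pairs(spec: FixtureSpec, records: Sequence[EntityRecord]) -> tuple:
    """One high, one medium and one low partner gene per cell-line anchor."""
    genes = [r.entity_id for r in records if r.category == "gene"]
    cell_lines = [r.entity_id for r in records if r.category == "cell_line"]
    pairs = []
    for i, cl in enumerate(cell_lines):
        for j, strength in enumerate(("high", "medium", "low")):
            pairs.append((cl, genes[(3 * i + j) % len(genes)], strength))
    return tuple(pairs)


def generate_corpus(
    spec: FixtureSpec, records: Sequence[EntityRecord] | None = None
) -> CorpusFixture:
    """Generate the abstract corpus, gold mentions/pairs and triples.

    Each abstract is assigned one cell-line anchor (round-robin) and plants
    the co-mention events of every planted pair of that anchor, with filler
    tokens enforcing the strength-class distances, plus one disease mention
    (always planted in singular surface form). A ``triple_rate`` fraction
    of co-mention events is additionally emitted as a bracketed-context
    triple for the same PMID.
    """
    if records is None:
        records = generate_ontologies(spec)
    by_id = {r.entity_id: r for r in records}
    planted = spec.planted_pairs or default_planted_pairs(spec, records)
    for cl, gene, _ in planted:
        for eid, cat in ((cl, "cell_line"), (gene, "gene")):
            if by_id.get(eid) is None or by_id[eid].category != cat:
                raise ValueError(f"planted pair references unknown {cat} {eid!r}")
    anchors = sorted({cl for cl, _, _ in planted})
    by_anchor = {a: [(g, s) for cl, g, s in planted if cl == a] for a in anchors}
    diseases = [r.entity_id for r in records if r.category == "disease"]
    pool = _filler_pool(spec, records)
    rng = random.Random(f"{spec.seed}:corpus")

    abstracts: dict[str, str] = {}
    gold_mentions: dict[str, list[tuple[int, int, str, str]]] = {}
    gold_pairs: list[tuple[str, str, str]] = []
    triple_rows: list[dict] = []

    for j in range(spec.n_abstracts):
        pmid = f"SYNPMID{j:05d}"
        anchor = anchors[j % len(anchors)]
        anchor_surface = by_id[anchor].canonical_name
        tokens: list[str] = []
        spans: list[tuple[int, int, str, str]] = []

        def filler(k: int) -> None:
            tokens.extend(rng.choice(pool) for _ in range(k))

        def plant(eid: str, surface: str) -> int:
            start = len(tokens)
            tokens.append(surface)
            spans.append((start, start + 1, eid, surface))
            return start

        filler(3)
        event_index = 0
        for gene, strength in by_anchor[anchor]:
            n_events, distance = STRENGTH_PARAMS[strength]
            gene_surface = by_id[gene].canonical_name
            for _ in range(n_events):
                filler(2)
                plant(anchor, anchor_surface)
                filler(distance - 1)
                plant(gene, gene_surface)
                if rng.random() < spec.triple_rate:
                    triple_rows.append(
                        {
                            "pmid": pmid,
                            "sentence_index": event_index,
                            "subject_head": gene_surface,
                            "subject_context": f"the gene {gene_surface}",
                            "predicate_head": "ASSOCIATES_WITH",
                            "predicate_context": "is associated with",
                            "object_head": anchor_surface,
                            "object_context": f"the {anchor_surface} cell line",
                        }
                    )
                event_index += 1
                # isolate events: the nearest anchor mention of any planted
                # gene must be its own event's anchor, so planted distances
                # stay exact
                filler(12)
            gold_pairs.append((pmid, gene, anchor))
        if diseases:
            filler(2)
            d = diseases[j % len(diseases)]
            canonical = by_id[d].canonical_name
            singular = canonical[:-1] if canonical.endswith("s") and not by_id[d].synonyms else canonical
            plant(d, singular)
        filler(3)

        abstracts[pmid] = " ".join(tokens)
        gold_mentions[pmid] = spans

    return CorpusFixture(
        spec=spec,
        records=list(records),
        abstracts=abstracts,
        gold_mentions=gold_mentions,
        gold_pairs=gold_pairs,
        triple_rows=triple_rows,
        planted_pairs=tuple(planted),
    )


def write_fixture_files(fixture: CorpusFixture, outdir: str | Path) -> dict[str, Path]:
    """Write the fixture in the exact dialects the other modules consume.

    Emits genes.tsv, cell_lines.tsv, diseases.obo, abstracts.jsonl,
    gold_mentions.jsonl, gold_pairs.jsonl and triples.tsv; returns the
    paths keyed by role.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    genes = [r for r in fixture.records if r.category == "gene"]
    paths["genes"] = outdir / "genes.tsv"
    with open(paths["genes"], "w", encoding="utf-8") as fh:
        fh.write("symbol\tname\taliases\n")
        for r in genes:
            name = r.synonyms[0] if r.synonyms else r.canonical_name
            aliases = "|".join(r.synonyms[1:])
            fh.write(f"{r.canonical_name}\t{name}\t{aliases}\n")

    cell_lines = [r for r in fixture.records if r.category == "cell_line"]
    paths["cell_lines"] = outdir / "cell_lines.tsv"
    with open(paths["cell_lines"], "w", encoding="utf-8") as fh:
        fh.write("accession\tname\tsynonyms\tparent_accession\n")
        for r in cell_lines:
            acc = r.entity_id.split(":", 1)[1]
            parent = r.parent_ids[0].split(":", 1)[1] if r.parent_ids else ""
            fh.write(f"{acc}\t{r.canonical_name}\t{'|'.join(r.synonyms)}\t{parent}\n")

    diseases = [r for r in fixture.records if r.category == "disease"]
    paths["diseases"] = outdir / "diseases.obo"
    with open(paths["diseases"], "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-diseases\n")
        for r in diseases:
            fh.write(f"\n[Term]\nid: {r.entity_id}\nname: {r.canonical_name}\n")
            for s in r.synonyms:
                fh.write(f'synonym: "{s}" EXACT []\n')

    paths["abstracts"] = outdir / "abstracts.jsonl"
    with open(paths["abstracts"], "w", encoding="utf-8") as fh:
        for pmid in fixture.pmids:
            fh.write(json.dumps({"pmid": pmid, "text": fixture.abstracts[pmid]}) + "\n")

    paths["gold_mentions"] = outdir / "gold_mentions.jsonl"
    with open(paths["gold_mentions"], "w", encoding="utf-8") as fh:
        for pmid in fixture.pmids:
            fh.write(
                json.dumps({"pmid": pmid, "spans": fixture.gold_mentions[pmid]}) + "\n"
            )

    paths["gold_pairs"] = outdir / "gold_pairs.jsonl"
    with open(paths["gold_pairs"], "w", encoding="utf-8") as fh:
        for pmid, gene, cl in fixture.gold_pairs:
            fh.write(json.dumps({"pmid": pmid, "gene_id": gene, "cell_line_id": cl}) + "\n")

    paths["triples"] = outdir / "triples.tsv"
    cols = (
        "pmid",
        "sentence_index",
        "subject_head",
        "subject_context",
        "predicate_head",
        "predicate_context",
        "object_head",
        "object_context",
    )
    with open(paths["triples"], "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in fixture.triple_rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
    return paths


def with_seed(spec: FixtureSpec, seed: int) -> FixtureSpec:
    """The same study conditions under a different seed."""
    return replace(spec, seed=seed)
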