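"""Shared fixtures: a tiny worked-example dictionary, a cell-line registry
with a parental hierarchy, and a full synthetic corpus run once per session."""

from __future__ import annotations

import pytest

from litlink.entity_dictionary import build_dictionary, find_mentions
from litlink.ontology_ingest import EntityRecord, load_cell_line_registry
from litlink.relation_scoring import MentionIndex, score_corpus
from litlink.synthetic_fixtures import FixtureSpec, generate_corpus
from litlink.text_normalization import tokenize
from litlink.triple_ingest import RawTriple, link_triples

# The extractor-output sentence used throughout as the worked example.
EXAMPLE_SENTENCE = (
    "A small-cell lung cancer cell line (NCI-H209) expresses an aberrant "
    "underphosphorylated form of the retinoblastoma protein RB1."
)
EXAMPLE_TRIPLE = (
    "(RB1 [the retinoblastoma protein RB1]; "
    "EXPRESSES [expresses an aberrant underphosphorylated form]; "
    "NCI-H209 [small-cell lung cancer cell line (NCI-H209)])"
)


@pytest.fixture(scope="session")
def example_records() -> list[EntityRecord]:
    """Minimal records for the worked example: one gene, one cell line."""
    return [
        EntityRecord(
            entity_id="gene:RB1",
            category="gene",
            canonical_name="RB1",
            synonyms=("RB transcriptional corepressor 1",),
        ),
        EntityRecord(
            entity_id="cell_line:CVCL_1247",
            category="cell_line",
            canonical_name="NCI-H209",
            synonyms=("NCI H209", "H209"),
        ),
    ]


@pytest.fixture(scope="session")
def example_dictionary(example_records):
    return build_dictionary(example_records)


@pytest.fixture
def hela_registry_tsv(tmp_path):
    """Registry dump with a parental line and three daughter lines."""
    path = tmp_path / "cell_lines.tsv"
    path.write_text(
        "accession\tname\tsynonyms\tparent_accession\n"
        "CVCL_0030\tHeLa\tHela|He La\t\n"
        "CVCL_0058\tHeLa 229\tHeLa229\tCVCL_0030\n"
        "CVCL_1276\tHeLa S3\tHeLaS3\tCVCL_0030\n"
        "CVCL_0459\tHeLa Kyoto\t\tCVCL_0030\n"
    )
    return path


@pytest.fixture
def hela_records(hela_registry_tsv):
    return load_cell_line_registry(hela_registry_tsv)


@pytest.fixture(scope="session")
def corpus_spec() -> FixtureSpec:
    """The study conditions: 50 abstracts, 5 anchors, planted strengths."""
    return FixtureSpec(seed=1)


@pytest.fixture(scope="session")
def corpus_fixture(corpus_spec):
    return generate_corpus(corpus_spec)


@pytest.fixture(scope="session")
def corpus_dictionary(corpus_fixture):
    return build_dictionary(corpus_fixture.records)


@pytest.fixture(scope="session")
def corpus_mentions(corpus_fixture, corpus_dictionary):
    """pmid -> mention list over the whole synthetic corpus."""
    return {
        pmid: find_mentions(tokenize(corpus_fixture.abstracts[pmid]), corpus_dictionary)
        for pmid in corpus_fixture.pmids
    }


@pytest.fixture(scope="session")
def corpus_indexes(corpus_mentions):
    return [MentionIndex.from_mentions(pmid, ms) for pmid, ms in sorted(corpus_mentions.items())]


@pytest.fixture(scope="session")
def corpus_linked_triples(corpus_fixture, corpus_dictionary):
    raws = [RawTriple(**row) for row in corpus_fixture.triple_rows]
    linked, quarantined = link_triples(raws, corpus_dictionary)
    assert not quarantined
    return linked


@pytest.fixture(scope="session")
def corpus_scores(corpus_indexes, corpus_dictionary, corpus_linked_triples):
    return score_corpus(corpus_indexes, corpus_dictionary.categories, corpus_linked_triples)
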