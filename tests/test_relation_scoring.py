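"""Proximity-score formula, triple bonuses, rankings, corpus statistics."""

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from litlink.relation_scoring import (
    MentionIndex,
    PairScore,
    apply_triple_bonus,
    canonical_pair,
    corpus_statistics,
    proximity_score,
    proximity_score_bruteforce,
    rank_abstracts,
    rank_entities_for_anchor,
    score_abstract,
    score_corpus,
)
from litlink.triple_ingest import RawTriple, LinkedTriple


def mk_index(pmid="p1", **positions):
    return MentionIndex(pmid=pmid, positions={k: tuple(v) for k, v in positions.items()})


def mk_triple(pmid, subj, obj, predicate="ASSOCIATES_WITH"):
    raw = RawTriple(pmid, 0, subj, f"ctx {subj}", predicate, predicate.lower(), obj, f"ctx {obj}")
    return LinkedTriple(
        raw=raw,
        subject_entities=frozenset({subj}),
        object_entities=frozenset({obj}),
        predicate_label=predicate,
    )


class TestProximityScore:
    def test_adjacent_mentions_contribute_exactly_one(self):
        """|Δ|=1 ⇒ 1/log2(2) = 1.0, analytically forced."""
        idx = mk_index(a=[5], b=[6])
        assert proximity_score(idx, "a", "b") == pytest.approx(1.0, abs=0)

    def test_distance_three_contributes_exactly_half(self):
        """|Δ|=3 ⇒ 1/log2(4) = 0.5, analytically forced."""
        idx = mk_index(a=[0], b=[3])
        assert proximity_score(idx, "a", "b") == pytest.approx(0.5, abs=0)

    def test_multi_mention_sum_matches_hand_computation(self):
        idx = mk_index(a=[2, 10], b=[4, 20])
        expected = sum(
            1.0 / math.log2(abs(p1 - p2) + 1) for p1 in (2, 10) for p2 in (4, 20)
        )
        assert proximity_score(idx, "a", "b") == pytest.approx(expected, rel=1e-15)

    def test_symmetry(self):
        idx = mk_index(a=[1, 7, 30], b=[2, 15])
        assert proximity_score(idx, "a", "b") == proximity_score(idx, "b", "a")

    def test_monotone_decay_with_distance(self):
        scores = [proximity_score(mk_index(a=[0], b=[d]), "a", "b") for d in range(1, 40)]
        assert all(s1 > s2 for s1, s2 in zip(scores, scores[1:]))

    def test_zero_distance_uses_cap(self):
        idx = mk_index(a=[4], b=[4])
        assert proximity_score(idx, "a", "b") == 2.0
        assert proximity_score(idx, "a", "b", zero_distance_cap=5.0) == 5.0

    def test_absent_entity_is_contract_violation(self):
        idx = mk_index(a=[1])
        with pytest.raises(KeyError):
            proximity_score(idx, "a", "missing")
        with pytest.raises(ValueError):
            proximity_score(idx, "a", "a")

    def test_oracle_equivalence_on_seeded_random_indexes(self):
        """Vectorized score equals the brute-force double loop, 1000 draws."""
        rng = random.Random(20240316)
        worst = 0.0
        for _ in range(1000):
            n1, n2 = rng.randint(1, 12), rng.randint(1, 12)
            idx = mk_index(
                a=sorted(rng.randrange(500) for _ in range(n1)),
                b=sorted(rng.randrange(500) for _ in range(n2)),
            )
            fast = proximity_score(idx, "a", "b")
            slow = proximity_score_bruteforce(idx, "a", "b")
            worst = max(worst, abs(fast - slow) / max(abs(slow), 1e-300))
        assert worst < 1e-12

    @given(
        p1=st.lists(st.integers(0, 300), min_size=1, max_size=8),
        p2=st.lists(st.integers(0, 300), min_size=1, max_size=8),
    )
    @settings(max_examples=150, deadline=None)
    def test_nonnegative_and_symmetric_property(self, p1, p2):
        idx = mk_index(a=sorted(p1), b=sorted(p2))
        s = proximity_score(idx, "a", "b")
        assert s >= 0.0
        assert s == proximity_score(idx, "b", "a")


class TestTripleBonus:
    @pytest.fixture
    def base_score(self):
        return PairScore(pmid="p1", e1="a", e2="b", proximity_score=1.5)

    def test_no_matching_triples_leaves_total_unchanged(self, base_score):
        updated = apply_triple_bonus(base_score, [mk_triple("p1", "a", "z")])
        assert updated.triple_bonus == 0
        assert updated.total == base_score.proximity_score

    def test_one_matching_triple_adds_one(self, base_score):
        updated = apply_triple_bonus(base_score, [mk_triple("p1", "a", "b")])
        assert updated.triple_bonus == 1
        assert updated.total == pytest.approx(2.5)

    def test_three_matching_triples_across_orientations(self, base_score):
        triples = [
            mk_triple("p1", "a", "b"),
            mk_triple("p1", "b", "a"),
            mk_triple("p1", "a", "b", predicate="INHIBITS"),
        ]
        updated = apply_triple_bonus(base_score, triples)
        assert updated.triple_bonus == 3
        assert updated.total == pytest.approx(4.5)
        assert len([e for e in updated.evidence if e["kind"] == "triple"]) == 3

    def test_unlinked_triples_never_count(self, base_score):
        raw = RawTriple("p1", 0, "a", "a", "IS", "IS", "zzz", "zzz")
        unlinked = LinkedTriple(raw, frozenset({"a"}), frozenset(), "IS")
        assert apply_triple_bonus(base_score, [unlinked]).triple_bonus == 0


class TestScoreAbstract:
    CATS = {"cl": "cell_line", "g1": "gene", "g2": "gene"}

    def test_cross_category_pairs_only(self):
        idx = mk_index(cl=[0], g1=[1], g2=[5])
        scores = score_abstract(idx, self.CATS)
        pairs = {(s.e1, s.e2) for s in scores}
        assert pairs == {canonical_pair("cl", "g1"), canonical_pair("cl", "g2")}

    def test_total_is_proximity_plus_bonus(self):
        idx = mk_index(cl=[0], g1=[1])
        scores = score_abstract(idx, self.CATS, [mk_triple("p1", "g1", "cl")])
        (s,) = scores
        assert s.proximity_score == pytest.approx(1.0)
        assert s.triple_bonus == 1
        assert s.total == pytest.approx(2.0)

    def test_triples_from_other_abstracts_ignored(self):
        idx = mk_index(cl=[0], g1=[1])
        (s,) = score_abstract(idx, self.CATS, [mk_triple("OTHER", "g1", "cl")])
        assert s.triple_bonus == 0


class TestRankings:
    def test_triple_backed_abstract_outranks_higher_proximity(self):
        """A (2.0 proximity + 1 bonus) ranks above B (2.5, no bonus)."""
        scores = [
            PairScore("A", "a", "b", proximity_score=2.0, triple_bonus=1),
            PairScore("B", "a", "b", proximity_score=2.5),
        ]
        assert rank_abstracts(scores, "a", "b") == [("A", 3.0), ("B", 2.5)]

    def test_singleton(self):
        scores = [PairScore("A", "a", "b", 1.0)]
        assert rank_abstracts(scores, "b", "a") == [("A", 1.0)]

    def test_tie_break_by_pmid_stable(self):
        scores = [
            PairScore("B", "a", "b", 1.0),
            PairScore("A", "a", "b", 1.0),
        ]
        for _ in range(3):
            assert rank_abstracts(scores, "a", "b") == [("A", 1.0), ("B", 1.0)]

    def test_anchor_aggregation_sums_per_abstract_totals(self):
        cats = {"cl": "cell_line", "geneA": "gene", "geneB": "gene"}
        scores = [
            PairScore("p1", "cl", "geneA", 1.0),
            PairScore("p2", "cl", "geneA", 2.0),
            PairScore("p3", "cl", "geneB", 2.5),
        ]
        agg = rank_entities_for_anchor(scores, "cl", cats, "gene")
        assert [(p, s) for p, s, _ in agg.ranked] == [("geneA", 3.0), ("geneB", 2.5)]
        assert agg.ranked[0][2] == ("p2", "p1")  # evidence pmids by per-abstract total

    def test_category_filter_excluding_all_partners(self):
        cats = {"cl": "cell_line", "geneA": "gene"}
        scores = [PairScore("p1", "cl", "geneA", 1.0)]
        assert rank_entities_for_anchor(scores, "cl", cats, "disease").ranked == ()

    def test_anchor_with_no_scores_gives_empty_ranking(self):
        assert rank_entities_for_anchor([], "cl", {}, "gene").ranked == ()

    def test_aggregate_additivity_over_corpus(self, corpus_scores, corpus_dictionary):
        """Aggregate score equals the exact sum of per-abstract totals."""
        anchor = next(
            e for e, c in sorted(corpus_dictionary.categories.items()) if c == "cell_line"
        )
        agg = rank_entities_for_anchor(corpus_scores, anchor, corpus_dictionary.categories, "gene")
        for partner, total, pmids in agg.ranked:
            c1, c2 = canonical_pair(anchor, partner)
            manual = sum(s.total for s in corpus_scores if (s.e1, s.e2) == (c1, c2))
            assert total == pytest.approx(manual, rel=1e-12)
            assert len(pmids) == sum(1 for s in corpus_scores if (s.e1, s.e2) == (c1, c2))


class TestCorpusStatistics:
    def test_empty_corpus_all_zeros(self):
        stats = corpus_statistics([], [], {})
        assert stats.as_dict() == {
            "n_abstracts": 0,
            "total_entity_matches": 0,
            "unique_entity_matches": 0,
            "unique_cell_lines": 0,
            "abstracts_per_cell_line": 0.0,
            "linked_entities_per_cell_line": 0.0,
        }

    def test_hand_enumerated_five_abstract_fixture(self):
        """Five abstracts, hand-counted mentions; statistics match exactly.

        Mention counts per abstract (hand enumeration):
          p1: cl1 x2, g1 x1, g2 x1            -> 4
          p2: cl1 x1, g1 x2                    -> 3
          p3: cl2 x1, g2 x1, d1 x3             -> 5
          p4: cl2 x2, cl1 x1                   -> 3
          p5: d1 x1, g1 x1                     -> 2
        total 17 matches; 5 unique entities (cl1, cl2, g1, g2, d1);
        2 unique cell lines; cl1 in 3 abstracts, cl2 in 2 -> 5/2 = 2.5.
        """
        cats = {"cl1": "cell_line", "cl2": "cell_line", "g1": "gene", "g2": "gene", "d1": "disease"}
        indexes = [
            mk_index("p1", cl1=[0, 9], g1=[3], g2=[6]),
            mk_index("p2", cl1=[0], g1=[2, 8]),
            mk_index("p3", cl2=[0], g2=[4], d1=[6, 7, 8]),
            mk_index("p4", cl2=[0, 5], cl1=[9]),
            mk_index("p5", d1=[1], g1=[4]),
        ]
        scores = score_corpus(indexes, cats)
        stats = corpus_statistics(indexes, scores, cats)
        assert stats.n_abstracts == 5
        assert stats.total_entity_matches == 17
        assert stats.unique_entity_matches == 5
        assert stats.unique_cell_lines == 2
        assert stats.abstracts_per_cell_line == pytest.approx(2.5)
        # partners per cell line (hand enumeration of cross-category pairs):
        # cl1: g1, g2 (p1), g1 (p2), cl2? same category -> no, d1? never co-mentioned
        #      -> {g1, g2}; cl2: g2, d1 (p3) -> {g2, d1}; mean = (2 + 2)/2 = 2
        assert stats.linked_entities_per_cell_line == pytest.approx(2.0)

    def test_abstracts_per_cell_line_definition(self, corpus_indexes, corpus_scores, corpus_dictionary):
        cats = corpus_dictionary.categories
        stats = corpus_statistics(corpus_indexes, corpus_scores, cats)
        cls = {e for idx in corpus_indexes for e in idx.positions if cats[e] == "cell_line"}
        manual = sum(
            sum(1 for idx in corpus_indexes if c in idx.positions) for c in cls
        ) / len(cls)
        assert stats.abstracts_per_cell_line == pytest.approx(manual)
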