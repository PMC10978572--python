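"""The categorical entity dictionary and dictionary-based mention matching.

Each entity surface form is indexed in up to three tiers:

* **exact** — byte-exact strings, reserved for gene symbols and cell-line
  canonical names. Case is load-bearing there ("STEP" the gene must not
  match "step" the word), so these forms get no case or lemma expansion.
* **case** — casefolded, token-normalized strings: all synonyms of every
  category plus the canonical names of disease/anatomy/cytoband entities.
* **lemma** — the same strings as one-lemma-per-token keys, so inflectional
  variants ("glioma"/"gliomas") unify.

Matching scans every token n-gram of the input up to a length bound and
tests each tier; a full dictionary form must match a contiguous n-gram
(high-precision full-form matching — a single shared token is not enough).
Overlapping candidates are resolved longest-first, then leftmost, then by
tier priority exact > case > lemma, so output mentions are pairwise
non-overlapping and deterministic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .ontology_ingest import EntityRecord
from .text_normalization import TokenizedText, lemmatize_token, tokenize

logger = logging.getLogger(__name__)

DEFAULT_MAX_LEN = 8

_TIER_PRIORITY = {"exact": 0, "case": 1, "lemma": 2}


@dataclass
class EntityDictionary:
    """Three-tier surface-form index over a collection of entity records."""

    exact_entries: dict[str, set[str]] = field(default_factory=dict)
    case_entries: dict[str, set[str]] = field(default_factory=dict)
    lemma_entries: dict[str, set[str]] = field(default_factory=dict)
    categories: dict[str, str] = field(default_factory=dict)
    canonical_names: dict[str, str] = field(default_factory=dict)
    max_form_tokens: int = 1

    def __len__(self) -> int:
        return len(self.categories)


@dataclass(frozen=True)
class EntityMention:
    """One linked mention: entity, matching tier, token span, raw surface."""

    entity_id: str
    category: str
    matched_form: str  # exact | case | lemma
    token_start: int
    token_end: int  # half-open
    surface: str

    def __post_init__(self) -> None:
        if self.token_start >= self.token_end:
            raise ValueError("empty token span")


def case_key(form: str) -> str:
    """Token-normalized casefolded key for the case tier."""
    return " ".join(t.casefold() for t in tokenize(form).tokens)


def lemma_key(form: str) -> str:
    """Token-normalized lemma key for the lemma tier."""
    return " ".join(lemmatize_token(t) for t in tokenize(form).tokens)


def _add(index: dict[str, set[str]], key: str, entity_id: str) -> None:
    if key:
        index.setdefault(key, set()).add(entity_id)


def build_dictionary(records: Iterable[EntityRecord]) -> EntityDictionary:
    """Build the categorical dictionary from validated entity records.

    Gene and cell-line canonical names are stored byte-exact only; every
    synonym (all categories) and the canonical names of the remaining
    categories are expanded into case and lemma entries. Ambiguous strings
    simply map to multiple entity ids.
    """
    d = EntityDictionary()
    n = 0
    for rec in records:
        n += 1
        d.categories[rec.entity_id] = rec.category
        d.canonical_names[rec.entity_id] = rec.canonical_name
        forms_for_expansion = list(rec.synonyms)
        if rec.category in ("gene", "cell_line"):
            _add(d.exact_entries, rec.canonical_name, rec.entity_id)
        else:
            forms_for_expansion.append(rec.canonical_name)
        for form in forms_for_expansion:
            _add(d.case_entries, case_key(form), rec.entity_id)
            _add(d.lemma_entries, lemma_key(form), rec.entity_id)
        for form in [rec.canonical_name, *rec.synonyms]:
            d.max_form_tokens = max(d.max_form_tokens, len(tokenize(form).tokens))
    if n == 0:
        logger.warning("building dictionary from an empty record collection")
    return d


def find_mentions(
    text: TokenizedText,
    dictionary: EntityDictionary,
    max_len: int = DEFAULT_MAX_LEN,
) -> list[EntityMention]:
    """Scan all token n-grams of ``text`` (lengths 1..max_len) against the
    dictionary and return non-overlapping mentions.

    For each n-gram the raw surface is tried against the exact tier, the
    casefolded token key against the case tier, and the lemma key against
    the lemma tier. Overlaps are resolved longest-match-first, ties by
    leftmost start, then by tier priority exact > case > lemma; all entity
    ids of a winning span are reported (ambiguity is preserved).
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    n = len(text.tokens)
    # candidates: (start, end) -> {entity_id: best tier}
    candidates: dict[tuple[int, int], dict[str, str]] = {}
    folded = [t.casefold() for t in text.tokens]
    lemmas = [lemmatize_token(t) for t in text.tokens]
    for start in range(n):
        for end in range(start + 1, min(start + max_len, n) + 1):
            surface = text.surface(start, end)
            hits: dict[str, str] = {}
            for eid in dictionary.exact_entries.get(surface, ()):
                hits[eid] = "exact"
            ck = " ".join(folded[start:end])
            for eid in dictionary.case_entries.get(ck, ()):
                hits.setdefault(eid, "case")
            lk = " ".join(lemmas[start:end])
            for eid in dictionary.lemma_entries.get(lk, ()):
                hits.setdefault(eid, "lemma")
            if hits:
                candidates[(start, end)] = hits

    def span_rank(item: tuple[tuple[int, int], dict[str, str]]) -> tuple[int, int, int]:
        (start, end), hits = item
        best_tier = min(_TIER_PRIORITY[t] for t in hits.values())
        return (-(end - start), start, best_tier)

    taken = [False] * n
    mentions: list[EntityMention] = []
    for (start, end), hits in sorted(candidates.items(), key=span_rank):
        if any(taken[start:end]):
            continue
        for i in range(start, end):
            taken[i] = True
        surface = text.surface(start, end)
        for eid in sorted(hits):
            mentions.append(
                EntityMention(
                    entity_id=eid,
                    category=dictionary.categories[eid],
                    matched_form=hits[eid],
                    token_start=start,
                    token_end=end,
                    surface=surface,
                )
            )
    mentions.sort(key=lambda m: (m.token_start, m.token_end, m.entity_id))
    return mentions


def match_text(
    raw_text: str, dictionary: EntityDictionary, max_len: int = DEFAULT_MAX_LEN
) -> list[EntityMention]:
    """Tokenize ``raw_text`` and find its dictionary mentions."""
    return find_mentions(tokenize(raw_text), dictionary, max_len=max_len)


def write_dictionary_jsonl(dictionary: EntityDictionary, path: str | Path) -> None:
    """Persist the dictionary as tier-tagged JSON Lines entries."""
    with open(path, "w", encoding="utf-8") as fh:
        meta = {
            "tier": "_meta",
            "categories": dictionary.categories,
            "canonical_names": dictionary.canonical_names,
            "max_form_tokens": dictionary.max_form_tokens,
        }
        fh.write(json.dumps(meta, ensure_ascii=False, sort_keys=True) + "\n")
        for tier, index in (
            ("exact", dictionary.exact_entries),
            ("case", dictionary.case_entries),
            ("lemma", dictionary.lemma_entries),
        ):
            for surface in sorted(index):
                fh.write(
                    json.dumps(
                        {"tier": tier, "surface": surface, "entity_ids": sorted(index[surface])},
                        ensure_ascii=False,
                        sort_keys=True,
                    )
                    + "\n"
                )


def read_dictionary_jsonl(path: str | Path) -> EntityDictionary:
    """Load a dictionary persisted by :func:`write_dictionary_jsonl`."""
    d = EntityDictionary()
    tiers = {"exact": d.exact_entries, "case": d.case_entries, "lemma": d.lemma_entries}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            entry = json.loads(line)
            if entry["tier"] == "_meta":
                d.categories.update(entry["categories"])
                d.canonical_names.update(entry["canonical_names"])
                d.max_form_tokens = entry["max_form_tokens"]
            else:
                tiers[entry["tier"]][entry["surface"]] = set(entry["entity_ids"])
    return d


def planted_mention_metrics(
    gold_spans: Sequence[tuple[int, int, str]],
    mentions: Sequence[EntityMention],
) -> tuple[float, float]:
    """Precision and recall of mention spans against gold (start, end, id)."""
    gold = {(s, e, eid) for s, e, eid in gold_spans}
    pred = {(m.token_start, m.token_end, m.entity_id) for m in mentions}
    if not pred and not gold:
        return 1.0, 1.0
    tp = len(gold & pred)
    precision = tp / len(pred) if pred else 0.0
    recall = tp / len(gold) if gold else 0.0
    return precision, recall
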