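# Methods

`litlink` implements a literature information-extraction pipeline for
cancer cell-line research: dictionary-based entity linking of abstract
text against biomedical ontologies, ingestion of open-information-extraction
(OpenIE) triples, a token-distance pair-relationship score, corpus-level
ranked gene–cell-line association lists with per-abstract evidence, a
knowledge graph, and an entity-pair evaluation harness. This note records
the model, its assumptions, the parameters that matter, and the design
choices made where the design was genuinely open.

## Entity model and dictionary matching

Entities come from five sources, normalized to uniform records
(`entity_id`, category, canonical name, synonyms, parent links): disease
and anatomy ontologies in OBO format, a cell-line registry dump, a gene
nomenclature table, and a cytoband table. Entity ids are namespaced by
category (`gene:TP53`, `cell_line:CVCL_0030`) so identical surface strings
from different sources never collide. Parent links (ontology `is_a`,
parental cell-line accessions) form a directed acyclic hierarchy; cycles
and (by default) dangling parents are rejected at load time. Obsolete
ontology terms are excluded by default — the dictionary is tuned for
precision, and deprecated labels are a known source of spurious matches.

Each surface form is indexed in up to three tiers:

* **exact** (byte-exact): gene symbols and cell-line canonical names only.
  Case is semantic for these ("STEP" the phosphatase gene vs "step" the
  word), so they receive no case or lemma expansion. Gene *aliases* and
  cell-line *synonyms* are expanded normally: only canonical names carry
  the exactness guarantee. This is revisitable, but treating aliases
  case-sensitively would cost substantial recall for historic symbols.
* **case** (Unicode casefold, token-normalized): all synonyms of all
  categories, plus canonical names of disease/anatomy/cytoband entities.
  Casefolding rather than lowercasing keeps Greek letters in gene and
  protein names well-behaved.
* **lemma** (one lowercase lemma per token): the same strings again, so
  inflectional variants unify ("glioma" ↔ "gliomas").

Matching scans every token n-gram up to `max_len` = 8 tokens (bounding the
scan cost; longer than any fixture synonym with margin) and requires the
*full* dictionary form to match a contiguous n-gram. A single shared token
is never enough — full-form contiguous matching is the stricter reading of
token-overlap matching and favours precision. Overlapping candidates are
resolved longest-match-first, ties by leftmost start, then by tier priority
exact > case > lemma; output mentions are therefore pairwise
non-overlapping and deterministic. Ambiguous strings map to multiple
entity ids and all are reported.

## Tokenization and lemmatization

Token positions are the coordinate system for everything downstream, so
the tokenizer is a pinned deterministic rule system rather than a
replaceable model: maximal runs of word characters joined by internal
hyphens stay single tokens ("MDA-MB-453", "NCI-H209", "9p21"), and every
other non-space character is a punctuation token. Punctuation tokens are
counted in positions (a mention's position is a token index in the full
token sequence, punctuation included). The lemmatizer is likewise a small
rule system: an exception table for irregular biomedical plurals
("analyses" → "analysis") plus conservative suffix stripping (`-ies` →
`-y`; `-es` after sibilants; otherwise final `-s` unless `-ss`/`-us`/`-is`).
Both carry a name/version in `text_normalization.CONFIG`; identical input
always yields byte-identical output. The trade-off is deliberate:
reproducibility over linguistic coverage, and the golden tokenization
tests freeze the behaviour the scores depend on.

## Pair-relationship score

The per-abstract relationship score between entities e1 and e2 is

    R(D, e1, e2) = Σ_{p1 ∈ P(e1)} Σ_{p2 ∈ P(e2)}  1 / log2(|p1 − p2| + 1)

where P(e) is the set of token start positions of e's mentions in abstract
D. Adjacent mentions (distance 1) contribute exactly 1/log2(2) = 1.0;
distance 3 contributes 1/log2(4) = 0.5; strength decays slowly with
distance, which is the point — it is a high-recall complement that catches
long-distance relationships a sentence-level triple extractor cannot.
Numerical choices:

* **Position of a multi-token mention** is its start token index — one
  scalar per mention, and the difference against a span midpoint is at
  most a few tokens, far inside the score's decay scale.
* **Coincident positions** (distance 0, possible only when overlapping
  mentions of *distinct* entities survive resolution, e.g. an ambiguous
  string reported for two entities) are undefined under the formula; they
  contribute a flat cap (default 2.0) instead, preserving "closer is
  stronger" without an infinity.
* **Unordered pairs**: the symmetric double sum is computed once per
  unordered pair. Running it over ordered pairs would double every score
  uniformly and change no ranking, so the cheaper convention is used. The
  summation order is canonicalized so R(e1,e2) and R(e2,e1) are
  bit-identical.
* **Scope** is strictly within-abstract; no cross-document distances.
* Each linked triple connecting the pair in the same abstract adds a flat
  **bonus of +1** (one per triple, not per orientation) — an explicit
  subject–predicate–object extraction is a definitive semantic connection
  and should outrank pure proximity. A triple with multiple entities on a
  side contributes one relation per subject-entity × object-entity
  combination, and the bonus is counted per triple per pair.

All cross-category pairs are scored; the portal-style cell-line → gene
view is a downstream filter, not a restriction of the computation.
Corpus-level association lists sum per-abstract totals per pair; all
rankings break ties by identifier (then PMID) so output is reproducible
run-to-run.

## Triple ingestion

Triples arrive in the bracketed-context dialect
(`subject [context]; PREDICATE [context]; object [context]`), as TSV
(5-column bracket dialect or 8-column explicit) or JSON Lines. The
extractor that produces them is deliberately pluggable — the pipeline is
extractor-agnostic and no parsing model is embedded here. Malformed
records are collected into a per-record error report, never silently
dropped, and triples citing a PMID outside the corpus are quarantined.
Linking runs mention detection over head *and* context of each side, since
the context is part of the argument text and typically carries the
resolvable name. Predicates stay open-vocabulary; normalization is
display-only (uppercased head).

## Knowledge graph

The graph contains only what the text and ontologies assert: relation
edges (one per subject-entity × object-entity combination of each fully
linked, non-self-referential triple, carrying predicate, PMID and an
evidence snippet), pair edges (scored co-mentions, kept as a distinct edge
type because predicate-free proximity evidence is a weaker inference), and
parent-of hierarchy edges. No edges are inferred from the graph itself.
Nodes exist only for entities with at least one edge; hierarchy edges are
included when either endpoint is already evidenced, which extends cell-line
parentage to every loaded ontology's parent links. Exports are GraphML or
nodes/edges CSV, both round-trippable (GraphML stringifies attribute
values, so round-trip equality is checked after string conversion).

## Evaluation harness

Benchmarks with gene and cell-line NER spans but no gene–cell-line
relation annotations are adapted by assuming that co-annotation in the
same abstract implies a relationship: gold pairs are the per-document
Cartesian product of unique gene ids × unique cell-line ids. The
assumption can introduce false positive gold pairs, so the report includes
per-document TP/FP/FN for auditing. Metrics are micro-averaged
precision/recall/F1 over document-level pairs (macro available); an empty
gold set with an empty prediction set scores 1.0 by configurable
convention. Pipeline scores convert to predictions by strict thresholding
of the per-abstract total (default threshold 0, i.e. every scored
co-mention — consistent with surfacing all candidate relations for expert
triage); a sweep mode covers threshold sensitivity.

## Synthetic study corpus

The fixture generator emulates exactly the statistical structure the score
exploits — association strength encoded as co-mention frequency and token
distance — and nothing else. Strength classes map to planted geometry:
high = 3 co-mention events per abstract at token distance 3, medium = 2 at
distance 10, low = 1 at distance 35 (within the documented bands ≤5, ≤15,
≥30). Events are separated by ≥12 filler tokens so each planted gene's
nearest anchor mention is its own event's anchor and planted distances are
exact. Entity morphology mimics the real nomenclatures (uppercase
alphanumeric gene symbols, hyphen/digit cell-line names with a two-level
parentage tree, disease terms whose singular/plural variants exercise the
lemma tier, including plural-only canonical names reachable from singular
text only through lemmas). Filler tokens are drawn from a closed lowercase
pool checked to be disjoint — casefold- and lemma-wise — from every
dictionary form, so gold mention sets are exact and precision/recall on
planted corpora is a meaningful 1.0 rather than an approximation. A
`triple_rate` fraction (default 0.25) of planted events is also emitted as
bracketed triples. Identical specs (seed included) produce byte-identical
outputs.

The default corpus — 50 abstracts, 5 cell-line anchors each with one high,
one medium and one low partner gene, 15 genes, 4 diseases — is the study
condition used by the test suite and `scripts/acceptance.py`. These sizes
keep a full pipeline run around a second while giving every anchor all
three strength classes, so rank-recovery statistics (Spearman between
planted strength and recovered rank) are well-defined.

What passing on this corpus does **not** show: robustness to real
abstracts' ambiguity (abbreviations, nested coordination, entities the
dictionary lacks), extractor noise in real triples, or calibration of the
score's magnitude against human relevance judgments. The generator plants
verbatim surface forms with clean filler, so mention precision/recall = 1.0
is a correctness check of the matcher and bookkeeping, not an NER accuracy
claim.

## Known limitations

* The lemmatizer handles plural/singular and simple 3rd-person forms only;
  derivational variants ("metastatic" vs "metastasis") do not unify.
* Exact-tier matching compares the raw character slice, so unusual
  whitespace inside a multi-token canonical name (double spaces, newlines)
  defeats an exact match; the case tier, which is token-normalized, still
  fires for synonyms.
* Real resource dumps (full registry flat files, complete nomenclature
  exports) need thin conversion to the documented TSV dialects; the OBO
  reader handles standard OBO 1.2/1.4.
* Adapted gold pairs inherit the co-annotation assumption; F1 against them
  mixes extraction quality with the assumption's validity.
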