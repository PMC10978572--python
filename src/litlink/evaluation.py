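"""Entity-pair evaluation harness.

Relation benchmarks rarely annotate gene–cell-line relationships directly,
but span-level NER annotations for both types are available. The harness
therefore adapts span annotations into document-level relationship pairs:
whenever a gene and a cell line are both annotated in the same abstract,
that document is annotated with a relationship pair for the two — the
Cartesian product of its unique gene ids and unique cell-line ids. This
matches the system's goal (surface *all* potential relations for an expert
to triage) but can introduce spurious gold pairs, so per-document
diagnostics are reported for auditing.

Scoring is standard entity-pair precision/recall/F1, micro-averaged over
documents by default (macro available). Predictions can come from any
source; :func:`evaluate_pipeline` converts this package's pair scores into
predictions by thresholding the per-abstract total.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .relation_scoring import PairScore

logger = logging.getLogger(__name__)

_PAIR_CATEGORIES = {"gene", "cell_line"}


@dataclass(frozen=True)
class GoldAnnotation:
    """Span-level entity annotations of one document."""

    doc_id: str
    entity_spans: tuple[tuple[int, int, str, str], ...]
    # each: (char_start, char_end, category, normalized_id)


@dataclass(frozen=True)
class PairPrediction:
    """One document-level gene–cell-line relationship pair."""

    doc_id: str
    gene_id: str
    cell_line_id: str


def read_pubtator(path: str | Path) -> list[GoldAnnotation]:
    """Parse PubTator-style annotations (``pmid|t|``/``pmid|a|`` text lines,
    tab-separated annotation lines). Categories other than gene/cell line
    are kept in the spans with their own label; pair adaptation ignores
    them with a logged count."""
    spans: dict[str, list[tuple[int, int, str, str]]] = defaultdict(list)
    doc_order: list[str] = []
    type_map = {"gene": "gene", "cellline": "cell_line", "cell_line": "cell_line"}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if "|t|" in line or "|a|" in line:
                doc_id = line.split("|", 1)[0]
                if doc_id not in spans:
                    doc_order.append(doc_id)
                    spans[doc_id] = []
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                continue
            doc_id, start, end, _text, etype, norm_id = parts[:6]
            if doc_id not in spans:
                doc_order.append(doc_id)
            category = type_map.get(etype.casefold(), etype.casefold())
            spans[doc_id].append((int(start), int(end), category, norm_id))
    return [GoldAnnotation(doc_id=d, entity_spans=tuple(spans[d])) for d in doc_order]


def read_gold_jsonl(path: str | Path) -> list[GoldAnnotation]:
    """Read the JSON Lines equivalent: one object per document with
    ``doc_id`` and ``entity_spans`` [[start, end, category, id], ...]."""
    import json

    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            d = json.loads(line)
            out.append(
                GoldAnnotation(
                    doc_id=str(d["doc_id"]),
                    entity_spans=tuple(tuple(s) for s in d["entity_spans"]),
                )
            )
    return out


def adapt_to_pairs(gold: Iterable[GoldAnnotation]) -> set[PairPrediction]:
    """Document-level gene × cell-line Cartesian product of the annotations.

    Per document: every unique annotated gene id paired with every unique
    annotated cell-line id. Other categories are ignored (counted in the
    log). Duplicate spans of the same entity collapse to one id.
    """
    pairs: set[PairPrediction] = set()
    ignored = 0
    for doc in gold:
        genes: set[str] = set()
        cell_lines: set[str] = set()
        for _s, _e, category, norm_id in doc.entity_spans:
            if category == "gene":
                genes.add(norm_id)
            elif category == "cell_line":
                cell_lines.add(norm_id)
            else:
                ignored += 1
        pairs.update(
            PairPrediction(doc.doc_id, g, c) for g in sorted(genes) for c in sorted(cell_lines)
        )
    if ignored:
        logger.info("adapt_to_pairs ignored %d non-gene/cell-line spans", ignored)
    return pairs


def entity_pair_f1(
    gold_pairs: Iterable[PairPrediction],
    predicted_pairs: Iterable[PairPrediction],
    average: str = "micro",
    empty_sets_are_perfect: bool = True,
) -> tuple[float, float, float]:
    """Precision, recall and F1 of predicted vs gold document-level pairs.

    Micro-averaging pools true positives over all documents (``macro``
    averages per-document F1 instead). The degenerate case of an empty gold
    *and* empty prediction set scores 1.0 by default (0.0 if
    ``empty_sets_are_perfect`` is false).
    """
    gold, pred = set(gold_pairs), set(predicted_pairs)
    if not gold and not pred:
        val = 1.0 if empty_sets_are_perfect else 0.0
        return val, val, val
    if average == "micro":
        tp = len(gold & pred)
        precision = tp / len(pred) if pred else 0.0
        recall = tp / len(gold) if gold else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        return precision, recall, f1
    if average == "macro":
        docs = {p.doc_id for p in gold | pred}
        scores = [
            entity_pair_f1(
                {p for p in gold if p.doc_id == d},
                {p for p in pred if p.doc_id == d},
                average="micro",
                empty_sets_are_perfect=empty_sets_are_perfect,
            )
            for d in sorted(docs)
        ]
        n = len(scores)
        return (
            sum(s[0] for s in scores) / n,
            sum(s[1] for s in scores) / n,
            sum(s[2] for s in scores) / n,
        )
    raise ValueError("average must be 'micro' or 'macro'")


def predictions_from_scores(
    scores: Iterable[PairScore],
    categories: Mapping[str, str],
    threshold: float = 0.0,
) -> set[PairPrediction]:
    """Convert pipeline pair scores into document-level pair predictions.

    A gene–cell-line pair is predicted for a document when its total score
    strictly exceeds ``threshold`` (default 0: every scored co-mention)."""
    out: set[PairPrediction] = set()
    for s in scores:
        cats = {categories.get(s.e1), categories.get(s.e2)}
        if cats != _PAIR_CATEGORIES or s.total <= threshold:
            continue
        gene, cl = (s.e1, s.e2) if categories.get(s.e1) == "gene" else (s.e2, s.e1)
        out.add(PairPrediction(doc_id=s.pmid, gene_id=gene, cell_line_id=cl))
    return out


@dataclass
class EvaluationReport:
    """Corpus metrics plus per-document diagnostics."""

    precision: float
    recall: float
    f1: float
    threshold: float
    n_gold_pairs: int
    n_predicted_pairs: int
    per_document: list[dict] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "threshold": self.threshold,
            "n_gold_pairs": self.n_gold_pairs,
            "n_predicted_pairs": self.n_predicted_pairs,
            "per_document": self.per_document,
        }


def evaluate_pipeline(
    scores: Sequence[PairScore],
    gold: Sequence[GoldAnnotation],
    categories: Mapping[str, str],
    threshold: float = 0.0,
    average: str = "micro",
) -> EvaluationReport:
    """Score the pipeline's output against adapted gold annotations.

    Documents present in the predictions but absent from the gold are
    scored against an empty gold set (and logged); the report carries
    per-document TP/FP/FN so spurious adapted pairs can be audited.
    """
    gold_pairs = adapt_to_pairs(gold)
    pred_pairs = predictions_from_scores(scores, categories, threshold)
    gold_docs = {g.doc_id for g in gold}
    stray = {p.doc_id for p in pred_pairs} - gold_docs
    if stray:
        logger.warning("%d predicted doc(s) absent from gold; scored against empty gold", len(stray))
    p, r, f1 = entity_pair_f1(gold_pairs, pred_pairs, average=average)
    per_doc = []
    for d in sorted(gold_docs | stray):
        gd = {x for x in gold_pairs if x.doc_id == d}
        pd = {x for x in pred_pairs if x.doc_id == d}
        per_doc.append(
            {
                "doc_id": d,
                "tp": len(gd & pd),
                "fp": len(pd - gd),
                "fn": len(gd - pd),
                "in_gold": d in gold_docs,
            }
        )
    return EvaluationReport(
        precision=p,
        recall=r,
        f1=f1,
        threshold=threshold,
        n_gold_pairs=len(gold_pairs),
        n_predicted_pairs=len(pred_pairs),
        per_document=per_doc,
    )


def threshold_sweep(
    scores: Sequence[PairScore],
    gold: Sequence[GoldAnnotation],
    categories: Mapping[str, str],
    thresholds: Sequence[float],
) -> list[EvaluationReport]:
    """Evaluate over a grid of score thresholds (predicted-pair count is
    non-increasing in the threshold)."""
    return [evaluate_pipeline(scores, gold, categories, t) for t in thresholds]
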