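"""Deterministic tokenization, case normalization and lemmatization.

Token positions are the coordinate system for every downstream quantity:
dictionary matching, mention positions and the pair proximity score all
count in tokens produced here. The tokenizer and lemmatizer are therefore
pinned, pure-Python rule systems — no model downloads, byte-identical
output for identical input — and their names/versions are declared in
:data:`CONFIG` so a processed corpus records exactly how it was segmented.

Three text forms are produced for both dictionary entries and input text:

* ``unprocessed`` — the string exactly as given (gene symbols and cell-line
  canonical names are matched in this form only, because case carries
  meaning there: "STEP" the gene is not "step" the word);
* ``case_normalized`` — Unicode casefold (robust for Greek letters in gene
  names);
* ``lemma_tokens`` — one lowercased lemma per token, so plural/singular
  variants of disease and anatomy terms ("gliomas" / "glioma") unify.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

CONFIG = {
    "tokenizer.name": "litlink-hyphen-word",
    "tokenizer.version": "1.0",
    "lemmatizer.name": "litlink-rule-lemma",
    "lemmatizer.version": "1.0",
}

# Word characters (letters, digits, underscore) optionally joined by internal
# hyphens, so biomedical surface forms like "MDA-MB-453" or "NCI-H209" stay
# single tokens; any other non-space character is its own punctuation token.
_TOKEN_RE = re.compile(r"\w+(?:-\w+)*|[^\w\s]", re.UNICODE)


@dataclass(frozen=True)
class TokenizedText:
    """A text with its token strings and their character spans.

    Spans are 0-based half-open offsets into ``raw``; ``raw[start:end]``
    reproduces each token exactly.
    """

    raw: str
    tokens: tuple[str, ...]
    token_char_spans: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.token_char_spans):
            raise ValueError("tokens and spans must be parallel")

    def __len__(self) -> int:
        return len(self.tokens)

    def surface(self, start: int, end: int) -> str:
        """Raw text under the half-open token span [start, end)."""
        if not 0 <= start < end <= len(self.tokens):
            raise IndexError(f"token span [{start}, {end}) out of range")
        return self.raw[self.token_char_spans[start][0] : self.token_char_spans[end - 1][1]]


@dataclass(frozen=True)
class NormalizedForms:
    """The three matching forms of one string."""

    unprocessed: str
    case_normalized: str
    lemma_tokens: tuple[str, ...] = field(default_factory=tuple)


def tokenize(text: str) -> TokenizedText:
    """Segment ``text`` deterministically into tokens with character spans.

    Hyphenated identifiers are kept whole; punctuation is split off. Empty
    input yields an empty token list.
    """
    tokens: list[str] = []
    spans: list[tuple[int, int]] = []
    for m in _TOKEN_RE.finditer(text):
        tokens.append(m.group(0))
        spans.append((m.start(), m.end()))
    return TokenizedText(raw=text, tokens=tuple(tokens), token_char_spans=tuple(spans))


# Irregular plurals that the suffix rules below would mangle.
_LEMMA_EXCEPTIONS = {
    "analyses": "analysis",
    "hypotheses": "hypothesis",
    "metastases": "metastasis",
    "prognoses": "prognosis",
    "diagnoses": "diagnosis",
    "mice": "mouse",
    "men": "man",
    "women": "woman",
    "feet": "foot",
    "teeth": "tooth",
}

_SIBILANT_ES = ("sses", "zzes", "ches", "shes", "xes")


def lemmatize_token(token: str) -> str:
    """Lowercased lemma of one token (plural → singular, 3rd-person → base).

    Purely rule-based: an exception table for common irregular biomedical
    plurals, then conservative suffix stripping. Non-alphabetic tokens are
    returned casefolded but otherwise untouched.
    """
    w = token.casefold()
    if w in _LEMMA_EXCEPTIONS:
        return _LEMMA_EXCEPTIONS[w]
    if not w.isalpha():
        return w
    if w.endswith("ies") and len(w) > 4:
        return w[:-3] + "y"
    if w.endswith(_SIBILANT_ES):
        return w[:-2]
    if w.endswith("s") and not w.endswith(("ss", "us", "is")) and len(w) > 3:
        return w[:-1]
    return w


def case_normalize(text: str) -> str:
    """Unicode casefold of ``text`` (the case-normalized form)."""
    return text.casefold()


def normalize(text: str) -> NormalizedForms:
    """Return the unprocessed, case-normalized and lemmatized forms."""
    toks = tokenize(text)
    return NormalizedForms(
        unprocessed=text,
        case_normalized=case_normalize(text),
        lemma_tokens=tuple(lemmatize_token(t) for t in toks.tokens),
    )
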