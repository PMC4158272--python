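"""Bag-of-words and n-gram preprocessing of titles and abstracts.

The pipeline applies, in order: punctuation removal, lowercasing, stop-word
removal, Porter stemming, and short-token removal (tokens shorter than
``min_token_length`` characters are dropped; the length test runs on the
*stemmed* token). N-grams are built from the unstemmed, lowercased,
punctuation-stripped word stream with stop words kept, joined by underscores;
title and abstract are windowed as separate streams so no n-gram spans the
boundary between them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from ._porter import porter_stem
from .corpus_io import Document, TermList
from .errors import ValidationError

# Standard English stop-word list (SMART-derived subset). Used when no
# project-specific list is supplied.
DEFAULT_STOP_WORDS = TermList(
    name="default_english",
    terms=tuple(
        """a about above after again against all am an and any are as at be because
        been before being below between both but by can cannot could did do does
        doing down during each few for from further had has have having he her here
        hers herself him himself his how i if in into is it its itself just me more
        most my myself no nor not now of off on once only or other our ours
        ourselves out over own same she should so some such than that the their
        theirs them themselves then there these they this those through to too
        under until up upon very was we were what when where which while who whom
        why will with would you your yours yourself yourselves""".split()
    ),
)

# Where the printed worked-example stems differ from classic Porter output.
# The source platform's closed stemmer prints "discover" and "large"; Porter
# yields "discoveri" and "larg". Keys are printed forms, values Porter forms.
PRINTED_STEM_VARIANTS: dict[str, str] = {
    "discover": "discoveri",
    "large": "larg",
}

_NON_ALNUM = re.compile(r"[^a-z0-9]+")


@dataclass(frozen=True)
class PipelineConfig:
    """Preprocessing configuration.

    Parameters
    ----------
    stop_words
        Terms removed from the BoW stream (kept in n-grams).
    min_token_length
        Tokens shorter than this (after stemming) are removed; default 4,
        i.e. tokens of length <= 3 are dropped.
    stemmer
        ``"porter"`` (default) or ``"none"``.
    use_ngrams
        Whether :func:`tokenize_document` also emits n-gram tokens.
    ngram_orders
        N-gram window sizes, each >= 2; default bigrams and trigrams.
    """

    stop_words: TermList = DEFAULT_STOP_WORDS
    min_token_length: int = 4
    stemmer: str = "porter"
    use_ngrams: bool = False
    ngram_orders: tuple[int, ...] = (2, 3)

    def __post_init__(self) -> None:
        if self.min_token_length < 1:
            raise ValidationError("min_token_length must be >= 1")
        if self.stemmer not in ("porter", "none"):
            raise ValidationError(f"unknown stemmer {self.stemmer!r}")
        if any(n < 2 for n in self.ngram_orders):
            raise ValidationError("ngram orders must each be >= 2")

    def stem(self, token: str) -> str:
        return porter_stem(token) if self.stemmer == "porter" else token

    def to_dict(self) -> dict:
        return {
            "stop_words": list(self.stop_words.terms),
            "min_token_length": self.min_token_length,
            "stemmer": self.stemmer,
            "use_ngrams": self.use_ngrams,
            "ngram_orders": list(self.ngram_orders),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            stop_words=TermList(name="config", terms=tuple(d["stop_words"])),
            min_token_length=int(d["min_token_length"]),
            stemmer=d["stemmer"],
            use_ngrams=bool(d["use_ngrams"]),
            ngram_orders=tuple(int(n) for n in d["ngram_orders"]),
        )


@dataclass(frozen=True)
class TokenizedDocument:
    """Processed token view of one document."""

    doc_id: str
    bow_tokens: tuple[str, ...]
    ngram_tokens: tuple[str, ...] = ()


def clean_and_split(text: str) -> list[str]:
    """Lowercase, replace every non-alphanumeric character by a space, split.

    Hyphens, underscores and all punctuation therefore split words; order is
    preserved; an empty text yields an empty list.
    """
    if not text:
        return []
    return _NON_ALNUM.sub(" ", text.lower()).split()


def _bow_stream(words: Iterable[str], config: PipelineConfig) -> list[str]:
    stop = config.stop_words.as_set()
    out = []
    for w in words:
        if w in stop:
            continue
        s = config.stem(w)
        if len(s) >= config.min_token_length:
            out.append(s)
    return out


def tokenize_bow(doc: Document, config: PipelineConfig | None = None) -> TokenizedDocument:
    """BoW-tokenize a document: title stream then abstract stream.

    Duplicates are retained (presence/absence collapsing happens at
    vectorization); first-occurrence order is preserved.
    """
    config = config or PipelineConfig()
    tokens = _bow_stream(clean_and_split(doc.title), config)
    tokens += _bow_stream(clean_and_split(doc.abstract), config)
    return TokenizedDocument(doc_id=doc.doc_id, bow_tokens=tuple(tokens))


def tokenize_ngrams(
    doc: Document, order: int, config: PipelineConfig | None = None
) -> list[str]:
    """Underscore-joined n-grams of adjacent words, stop words kept, no stemming.

    A stream of L words yields max(0, L - order + 1) n-grams; title and
    abstract are windowed separately.
    """
    if order < 2:
        raise ValidationError(f"n-gram order must be >= 2, got {order}")
    grams: list[str] = []
    for stream in (clean_and_split(doc.title), clean_and_split(doc.abstract)):
        for i in range(len(stream) - order + 1):
            grams.append("_".join(stream[i : i + order]))
    return grams


def tokenize_document(doc: Document, config: PipelineConfig | None = None) -> TokenizedDocument:
    """Full tokenization: BoW tokens plus n-grams when the config enables them."""
    config = config or PipelineConfig()
    tok = tokenize_bow(doc, config)
    if not config.use_ngrams:
        return tok
    grams: list[str] = []
    for order in sorted(config.ngram_orders):
        grams.extend(tokenize_ngrams(doc, order, config))
    return TokenizedDocument(
        doc_id=tok.doc_id, bow_tokens=tok.bow_tokens, ngram_tokens=tuple(grams)
    )


def tokenize_corpus(
    docs: Sequence[Document], config: PipelineConfig | None = None
) -> list[TokenizedDocument]:
    config = config or PipelineConfig()
    return [tokenize_document(d, config) for d in docs]
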