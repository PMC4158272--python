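"""Synthetic two-class corpora for end-to-end testing without downloads.

The generator emulates the structure of a curated medicinal-chemistry corpus
against a random bibliographic background: two document classes share a large
common vocabulary with Zipf-distributed word frequencies, and each class
additionally owns a small set of class-specific terms (the synthetic analogue
of class-enriched words like "compound" or "surgery") that appear only in its
own documents and are over-sampled by ``discriminative_boost``. Titles and
abstracts are separate word streams with Poisson lengths; stop words from a
small fixed list are interleaved at ``stopword_rate``; every content word is a
pronounceable ASCII string of >= 4 characters so it survives the preprocessing
filters.

What this does *not* emulate: real word co-occurrence and syntax, burstiness
(words are drawn i.i.d. within a document), document-length/label
correlations, journal or date metadata. Tests passing on this generator show
the pipeline's statistical machinery works, not that real corpora are this
separable.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus_io import Document
from .errors import ValidationError

SYNTH_STOP_WORDS = ("the", "of", "and", "in", "with", "for", "from", "this")

_CONSONANTS = "bcdfghjklmnprstvz"
_VOWELS = "aeiou"


def _word_pool(n: int, forbidden: frozenset[str]) -> list[str]:
    """First ``n`` pronounceable CVCV(CV) words not colliding with stop lists."""
    syllables = [c + v for c in _CONSONANTS for v in _VOWELS]
    words = []
    for combo in itertools.product(syllables, repeat=2):
        w = "".join(combo)
        if w not in forbidden:
            words.append(w)
            if len(words) == n:
                return words
    for combo in itertools.product(syllables, repeat=3):
        w = "".join(combo)
        if w not in forbidden:
            words.append(w)
            if len(words) == n:
                return words
    raise ValidationError(f"cannot generate {n} distinct synthetic words")


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults are the package's standard study conditions.

    2,000 documents per class, a 2,000-term shared vocabulary, 30 class-specific
    terms per class boosted 5x, Zipf exponent 1.1, 12-word titles and 150-word
    abstracts on average, one stop word per four tokens.
    """

    n_pos: int = 2000
    n_neg: int = 2000
    vocab_size_shared: int = 2000
    vocab_size_pos_only: int = 30
    vocab_size_neg_only: int = 30
    zipf_exponent: float = 1.1
    title_length_mean: float = 12.0
    abstract_length_mean: float = 150.0
    discriminative_boost: float = 5.0
    stopword_rate: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValidationError("need at least one document per class")
        if self.vocab_size_shared + min(self.vocab_size_pos_only, self.vocab_size_neg_only) < 10:
            raise ValidationError("combined vocabulary must have >= 10 terms")
        if self.zipf_exponent <= 0:
            raise ValidationError("zipf_exponent must be > 0")
        if self.title_length_mean <= 0 or self.abstract_length_mean <= 0:
            raise ValidationError("length means must be > 0")
        if self.discriminative_boost < 1:
            raise ValidationError("discriminative_boost must be >= 1")
        if not 0 <= self.stopword_rate < 1:
            raise ValidationError("stopword_rate must be in [0, 1)")


@dataclass
class SynthCorpus:
    """Generated labeled documents plus the ground truth that produced them."""

    documents: list[Document]
    pos_terms: list[str]
    neg_terms: list[str]
    shared_terms: list[str]
    token_probs: dict[str, dict[str, float]]  # class ("pos"/"neg") -> term -> prob
    config: SynthConfig

    def ground_truth_dict(self) -> dict:
        return {
            "pos_terms": self.pos_terms,
            "neg_terms": self.neg_terms,
            "shared_terms": self.shared_terms,
            "token_probs": self.token_probs,
            "config": self.config.__dict__,
        }

    def save_ground_truth(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.ground_truth_dict()), encoding="utf-8")


def _class_distribution(
    shared: list[str], own: list[str], exponent: float, boost: float
) -> tuple[list[str], np.ndarray]:
    """Zipf weights over shared + class-specific terms.

    Class-specific terms are interleaved at evenly spaced ranks through the
    frequency spectrum (so some are common, some rare), then boosted.
    """
    v = len(shared) + len(own)
    c = len(own)
    if c == 0:
        positions: set[int] = set()
    elif v >= 2 * c:
        # interior evenly spaced ranks: some class terms common, some rare
        positions = set(
            np.floor(np.linspace(v / (c + 1), v * c / (c + 1), c)).astype(int) - 1
        )
    else:
        positions = set(np.floor(np.linspace(0, v - 1, c)).astype(int))
    assert len(positions) == c
    terms: list[str] = []
    shared_iter = iter(shared)
    own_iter = iter(own)
    for rank0 in range(v):
        terms.append(next(own_iter) if rank0 in positions else next(shared_iter))
    weights = 1.0 / np.arange(1, len(terms) + 1, dtype=float) ** exponent
    own_set = set(own)
    boost_mask = np.array([t in own_set for t in terms])
    weights[boost_mask] *= boost
    return terms, weights / weights.sum()


def generate_corpus(config: SynthConfig) -> SynthCorpus:
    """Draw a labeled corpus; deterministic for a fixed config (incl. seed)."""
    rng = np.random.default_rng(config.seed)
    n_words = (
        config.vocab_size_shared + config.vocab_size_pos_only + config.vocab_size_neg_only
    )
    pool = _word_pool(n_words, frozenset(SYNTH_STOP_WORDS))
    shared = pool[: config.vocab_size_shared]
    pos_terms = pool[config.vocab_size_shared : config.vocab_size_shared + config.vocab_size_pos_only]
    neg_terms = pool[config.vocab_size_shared + config.vocab_size_pos_only :]

    dists = {
        "pos": _class_distribution(
            shared, pos_terms, config.zipf_exponent, config.discriminative_boost
        ),
        "neg": _class_distribution(
            shared, neg_terms, config.zipf_exponent, config.discriminative_boost
        ),
    }

    documents: list[Document] = []
    counter = 0
    for cls, label, n_docs in (("pos", 1, config.n_pos), ("neg", 0, config.n_neg)):
        terms, probs = dists[cls]
        terms_arr = np.asarray(terms, dtype=object)
        title_lens = np.maximum(rng.poisson(config.title_length_mean, n_docs), 3)
        abstract_lens = rng.poisson(config.abstract_length_mean, n_docs)
        total = int(title_lens.sum() + abstract_lens.sum())
        is_stop = rng.random(total) < config.stopword_rate
        content = rng.choice(terms_arr, size=total, p=probs)
        stops = rng.choice(np.asarray(SYNTH_STOP_WORDS, dtype=object), size=total)
        tokens = np.where(is_stop, stops, content)
        pos = 0
        for i in range(n_docs):
            counter += 1
            lt, la = int(title_lens[i]), int(abstract_lens[i])
            title = " ".join(tokens[pos : pos + lt])
            abstract = " ".join(tokens[pos + lt : pos + lt + la])
            pos += lt + la
            documents.append(
                Document(
                    doc_id=f"synth{counter:06d}",
                    title=title,
                    abstract=abstract,
                    label=label,
                )
            )
    token_probs = {
        cls: dict(zip(dists[cls][0], dists[cls][1].tolist())) for cls in ("pos", "neg")
    }
    return SynthCorpus(
        documents=documents,
        pos_terms=list(pos_terms),
        neg_terms=list(neg_terms),
        shared_terms=list(shared),
        token_probs=token_probs,
        config=config,
    )


def expected_term_stats(corpus: SynthCorpus) -> pd.DataFrame:
    """Analytic expected per-class document frequencies for every term.

    Uses the Poisson thinning identity: with mean content length
    lambda = (title_mean + abstract_mean) * (1 - stopword_rate) and per-token
    probability p, P(term present in a document) = 1 - exp(-lambda * p).
    (The 3-word title floor makes this an approximation with negligible bias
    at the default title mean.)
    """
    cfg = corpus.config
    lam = (cfg.title_length_mean + cfg.abstract_length_mean) * (1 - cfg.stopword_rate)
    all_terms = corpus.shared_terms + corpus.pos_terms + corpus.neg_terms
    rows = []
    for term in all_terms:
        p_pos = corpus.token_probs["pos"].get(term, 0.0)
        p_neg = corpus.token_probs["neg"].get(term, 0.0)
        rows.append(
            {
                "term": term,
                "p_token_pos": p_pos,
                "p_token_neg": p_neg,
                "expected_doc_freq_pos": cfg.n_pos * (1 - np.exp(-lam * p_pos)),
                "expected_doc_freq_neg": cfg.n_neg * (1 - np.exp(-lam * p_neg)),
            }
        )
    return pd.DataFrame(rows)
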