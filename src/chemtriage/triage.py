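"""Downstream triage use cases built on the classifier.

Four workflows: (1) ranking a stream of new documents by corpus-likeness
score; (2) keyword-filtered curation with cost accounting — filter a
retrieved set by topic keywords, keep classifier positives, and report the
pay-per-view money not spent on discarded articles; (3) single-document alert
scoring (the feed-bot hook); (4) dictionary-gated relevance classification —
pre-filter a pool by requiring a minimum count of domain-dictionary words,
train a small NB model on a balanced labeled seed set, and rank the gated
pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus_io import Document, TermList
from .errors import ValidationError
from .evaluate import rank_order
from .models import NBModel, train_nb
from .preprocess import PipelineConfig, clean_and_split, tokenize_corpus
from .vectorize import build_vocabulary, vectorize


@dataclass
class TriageResult:
    """Ranked scored documents with pass/fail flags and run provenance."""

    documents: list[Document]  # descending score, ties by doc_id
    passed: list[bool]  # score >= threshold, aligned to documents
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.documents)


@dataclass(frozen=True)
class CostEstimate:
    """Curation cost avoided by discarding classifier-negative articles."""

    n_before: int
    n_after: int
    cost_per_article: float = 30.0

    def __post_init__(self) -> None:
        if self.n_after > self.n_before:
            raise ValidationError("n_after cannot exceed n_before")

    @property
    def saving(self) -> float:
        return (self.n_before - self.n_after) * self.cost_per_article


def _score_documents(model, docs: Sequence[Document], config: PipelineConfig):
    tokenized = tokenize_corpus(docs, config)
    matrix = vectorize(tokenized, model.vocabulary)
    return model.decision_scores(matrix)


def rank_documents(
    model,
    docs: Sequence[Document],
    config: PipelineConfig | None = None,
    threshold: float | None = None,
) -> TriageResult:
    """Preprocess, vectorize, score and rank documents (descending score)."""
    config = config or model.pipeline or PipelineConfig()
    if not docs:
        return TriageResult(documents=[], passed=[], provenance={"n_input": 0})
    scores = _score_documents(model, docs, config)
    cut = model.threshold if threshold is None else threshold
    order = rank_order(scores, [d.doc_id for d in docs])
    ranked = [docs[i].with_score(scores[i]) for i in order]
    passed = [scores[i] >= cut for i in order]
    return TriageResult(
        documents=ranked,
        passed=passed,
        provenance={
            "model_type": model.model_type,
            "threshold": cut,
            "n_input": len(docs),
        },
    )


def keyword_filter(
    docs: Sequence[Document],
    keywords: TermList,
    match_mode: str = "word",
) -> list[Document]:
    """Keep documents whose title or abstract contains >= 1 keyword.

    ``word`` mode (default) matches case-insensitive whole words after
    punctuation stripping (multi-word keywords match as adjacent word
    sequences); ``substring`` mode matches raw lowercase substrings, so
    "malaria" then also hits "antimalarial". Input order is preserved.
    """
    if len(keywords) == 0:
        raise ValidationError("keyword list is empty")
    if match_mode not in ("word", "substring"):
        raise ValidationError(f"unknown match_mode {match_mode!r}")
    kept = []
    if match_mode == "substring":
        for d in docs:
            text = f"{d.title} {d.abstract}".lower()
            if any(k in text for k in keywords.terms):
                kept.append(d)
        return kept
    key_seqs = [tuple(clean_and_split(k)) for k in keywords.terms]
    for d in docs:
        words = clean_and_split(d.title) + clean_and_split(d.abstract)
        wset = set(words)
        hit = False
        for seq in key_seqs:
            if len(seq) == 1:
                hit = seq[0] in wset
            else:
                hit = any(
                    tuple(words[i : i + len(seq)]) == seq
                    for i in range(len(words) - len(seq) + 1)
                )
            if hit:
                break
        if hit:
            kept.append(d)
    return kept


def classify_and_reduce(
    docs: Sequence[Document],
    model,
    keywords: TermList,
    config: PipelineConfig | None = None,
    cost_per_article: float = 30.0,
    threshold: float | None = None,
    match_mode: str = "word",
) -> tuple[list[Document], CostEstimate]:
    """Keyword-filter, then keep classifier positives; account the saving.

    ``n_before`` is the keyword-matched count (the set a curator would
    otherwise buy and read); ``n_after`` the classifier-positive subset.
    """
    matched = keyword_filter(docs, keywords, match_mode)
    result = rank_documents(model, matched, config, threshold)
    kept = [d for d, ok in zip(result.documents, result.passed) if ok]
    return kept, CostEstimate(
        n_before=len(matched), n_after=len(kept), cost_per_article=cost_per_article
    )


def dictionary_gate(
    docs: Sequence[Document],
    dictionary: TermList,
    min_count: int = 5,
    config: PipelineConfig | None = None,
    count_mode: str = "occurrences",
) -> list[Document]:
    """Keep documents with >= min_count dictionary-word hits in title+abstract.

    Counting is over token occurrences by default (``count_mode="types"``
    counts distinct dictionary terms instead). Matching is on the
    punctuation-stripped lowercase word stream; when the config stems, both
    the stream and the dictionary entries are stemmed, so inflected variants
    of a dictionary word count.
    """
    if len(dictionary) == 0:
        raise ValidationError("gating dictionary is empty")
    if min_count < 1:
        raise ValidationError("min_count must be >= 1")
    if count_mode not in ("occurrences", "types"):
        raise ValidationError(f"unknown count_mode {count_mode!r}")
    config = config or PipelineConfig()
    entries = {config.stem(t) for t in dictionary.terms}
    kept = []
    for d in docs:
        words = clean_and_split(d.title) + clean_and_split(d.abstract)
        hits = [w for w in (config.stem(w) for w in words) if w in entries]
        count = len(set(hits)) if count_mode == "types" else len(hits)
        if count >= min_count:
            kept.append(d)
    return kept


def _balance_classes(docs: Sequence[Document], seed: int) -> list[Document]:
    rng = np.random.default_rng(seed)
    pos = [d for d in docs if d.label == 1]
    neg = [d for d in docs if d.label == 0]
    n = min(len(pos), len(neg))
    pos_idx = sorted(rng.choice(len(pos), size=n, replace=False).tolist())
    neg_idx = sorted(rng.choice(len(neg), size=n, replace=False).tolist())
    return [pos[i] for i in pos_idx] + [neg[i] for i in neg_idx]


def gated_classifier_workflow(
    seed_docs: Sequence[Document],
    pool: Sequence[Document],
    dictionary: TermList,
    min_count: int = 5,
    config: PipelineConfig | None = None,
    seed: int = 0,
    min_doc_freq: int = 1,
) -> TriageResult:
    """Dictionary-gate a pool, train NB on a balanced labeled seed set, rank.

    The majority class of the seed set is downsampled (seeded) so both classes
    contribute equally, then an NB model is trained on the balanced seed and
    the gated pool is scored and ranked.
    """
    config = config or PipelineConfig()
    labels = {d.label for d in seed_docs}
    if labels != {0, 1}:
        raise ValidationError("seed set must contain both classes")
    balanced = _balance_classes(seed_docs, seed)
    tokenized = tokenize_corpus(balanced, config)
    vocab = build_vocabulary(
        tokenized, min_doc_freq=min_doc_freq, include_ngrams=config.use_ngrams
    )
    matrix = vectorize(tokenized, vocab, labels=[d.label for d in balanced])
    model = train_nb(matrix, pipeline=config)
    gated = dictionary_gate(pool, dictionary, min_count, config)
    result = rank_documents(model, gated, config)
    result.provenance.update(
        {
            "gate_min_count": min_count,
            "n_pool": len(pool),
            "n_gated": len(gated),
            "n_train": len(balanced),
            "seed": seed,
        }
    )
    return result


def score_feed_item(
    model,
    doc: Document,
    keyword: str,
    config: PipelineConfig | None = None,
) -> tuple[bool, float, int]:
    """Alert-feed hook: does the doc mention the keyword, and is it corpus-like?

    Returns (matched, score, predicted_class). Matching is whole-word over
    title or abstract, consistent with :func:`keyword_filter`.
    """
    matched = bool(
        keyword_filter([doc], TermList(name="feed", terms=(keyword.lower(),)))
    )
    config = config or model.pipeline or PipelineConfig()
    score = float(_score_documents(model, [doc], config)[0])
    return matched, score, int(score >= model.threshold)
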