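"""Vocabulary construction and binary document-term matrices.

A document is encoded as a binary presence/absence vector over a fixed term
vocabulary — the text analogue of a dictionary-based chemical fingerprint.
BoW terms and n-grams live in one vocabulary, each feature tagged with its
namespace (``bow`` or ``ngram``), so the n-gram configuration is a strict
superset of the plain BoW one. Term order is first occurrence across the
document stream, never lexicographic, so worked examples reproduce
bit-for-bit. Tokens absent from the vocabulary are silently ignored at
encoding time (new literature always contains unseen terms).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .errors import ValidationError
from .preprocess import TokenizedDocument


@dataclass
class Vocabulary:
    terms: list[str]
    index: dict[str, int]
    doc_freq: np.ndarray  # training document frequency per term
    namespaces: list[str]  # "bow" | "ngram", aligned to terms

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.index

    @classmethod
    def from_terms(
        cls, terms: Sequence[str], doc_freq: Sequence[int] | None = None
    ) -> "Vocabulary":
        """Build a vocabulary from an explicit ordered term list."""
        terms = list(terms)
        if len(set(terms)) != len(terms):
            raise ValidationError("vocabulary terms must be unique")
        df = np.zeros(len(terms), dtype=np.int64) if doc_freq is None else np.asarray(
            doc_freq, dtype=np.int64
        )
        return cls(
            terms=terms,
            index={t: i for i, t in enumerate(terms)},
            doc_freq=df,
            namespaces=["ngram" if "_" in t else "bow" for t in terms],
        )

    def to_dict(self) -> dict:
        return {
            "terms": self.terms,
            "doc_freq": self.doc_freq.tolist(),
            "namespaces": self.namespaces,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Vocabulary":
        return cls(
            terms=list(d["terms"]),
            index={t: i for i, t in enumerate(d["terms"])},
            doc_freq=np.asarray(d["doc_freq"], dtype=np.int64),
            namespaces=list(d["namespaces"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


@dataclass
class DocTermMatrix:
    """Sparse binary presence matrix: rows = documents, columns = terms."""

    doc_ids: list[str]
    vocabulary: Vocabulary
    bits: sp.csr_matrix
    labels: np.ndarray | None = None  # aligned 0/1 ints

    @property
    def n_docs(self) -> int:
        return self.bits.shape[0]

    def subset(self, row_indices: np.ndarray) -> "DocTermMatrix":
        idx = np.asarray(row_indices)
        return DocTermMatrix(
            doc_ids=[self.doc_ids[i] for i in idx],
            vocabulary=self.vocabulary,
            bits=self.bits[idx],
            labels=None if self.labels is None else self.labels[idx],
        )


def build_vocabulary(
    tokenized_docs: Sequence[TokenizedDocument],
    min_doc_freq: int = 1,
    include_ngrams: bool = False,
) -> Vocabulary:
    """Union of tokens over all documents, ordered by first occurrence.

    Terms seen in fewer than ``min_doc_freq`` documents are dropped (the
    default of 1 keeps everything, matching a no-cutoff training setup).
    """
    if not tokenized_docs:
        raise ValidationError("cannot build a vocabulary from an empty collection")
    order: list[str] = []
    namespaces: dict[str, str] = {}
    df: dict[str, int] = {}
    for tdoc in tokenized_docs:
        seen: set[str] = set()
        streams = [("bow", tdoc.bow_tokens)]
        if include_ngrams:
            streams.append(("ngram", tdoc.ngram_tokens))
        for ns, tokens in streams:
            for t in tokens:
                if t in seen:
                    continue
                seen.add(t)
                if t in df:
                    df[t] += 1
                else:
                    df[t] = 1
                    order.append(t)
                    namespaces[t] = ns
    kept = [t for t in order if df[t] >= min_doc_freq]
    return Vocabulary(
        terms=kept,
        index={t: i for i, t in enumerate(kept)},
        doc_freq=np.array([df[t] for t in kept], dtype=np.int64),
        namespaces=[namespaces[t] for t in kept],
    )


def vectorize(
    tokenized_docs: Sequence[TokenizedDocument],
    vocabulary: Vocabulary,
    labels: Sequence[int] | None = None,
) -> DocTermMatrix:
    """Encode documents as binary rows over the vocabulary (input order kept)."""
    if len(vocabulary) == 0:
        raise ValidationError("vocabulary is empty; nothing to encode")
    indptr = [0]
    indices: list[int] = []
    index = vocabulary.index
    for tdoc in tokenized_docs:
        cols = {
            index[t]
            for t in (*tdoc.bow_tokens, *tdoc.ngram_tokens)
            if t in index
        }
        indices.extend(sorted(cols))
        indptr.append(len(indices))
    bits = sp.csr_matrix(
        (
            np.ones(len(indices), dtype=np.int8),
            np.array(indices, dtype=np.int64),
            np.array(indptr, dtype=np.int64),
        ),
        shape=(len(tokenized_docs), len(vocabulary)),
    )
    lab = None
    if labels is not None:
        lab = np.asarray(labels, dtype=np.int64)
        if lab.shape[0] != len(tokenized_docs):
            raise ValidationError("labels length does not match document count")
    return DocTermMatrix(
        doc_ids=[t.doc_id for t in tokenized_docs],
        vocabulary=vocabulary,
        bits=bits,
        labels=lab,
    )


def save_mtx(matrix: DocTermMatrix, path: str | Path) -> None:
    """Export as Matrix Market (text) with a doc_id sidecar and vocabulary JSON.

    Writes ``<path>`` (MTX), ``<path>.doc_ids.txt`` (one id per row) and
    ``<path>.vocab.json``.
    """
    path = Path(path)
    from scipy.io import mmwrite

    mmwrite(str(path), matrix.bits.tocoo(), field="integer")
    Path(f"{path}.doc_ids.txt").write_text(
        "\n".join(matrix.doc_ids) + "\n", encoding="utf-8"
    )
    matrix.vocabulary.save(f"{path}.vocab.json")


def load_mtx(path: str | Path) -> DocTermMatrix:
    """Read a matrix written by :func:`save_mtx` (labels are not stored)."""
    from scipy.io import mmread

    path = Path(path)
    bits = sp.csr_matrix(mmread(str(path)), dtype=np.int8)
    doc_ids = Path(f"{path}.doc_ids.txt").read_text(encoding="utf-8").splitlines()
    vocab = Vocabulary.load(f"{path}.vocab.json")
    if bits.shape != (len(doc_ids), len(vocab)):
        raise ValidationError(
            f"{path}: matrix shape {bits.shape} does not match sidecars "
            f"({len(doc_ids)} docs, {len(vocab)} terms)"
        )
    return DocTermMatrix(doc_ids=doc_ids, vocabulary=vocab, bits=bits)


def bit_string(matrix: DocTermMatrix, row: int) -> str:
    """Row as a '0'/'1' string in vocabulary order (worked-example display)."""
    dense = np.asarray(matrix.bits[row].todense()).ravel()
    return "".join("1" if b else "0" for b in dense)
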