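"""Reading and writing document collections, term lists and scores.

Documents are title+abstract records keyed by an identifier (typically a
PubMed ID). Three on-disk formats are supported: a strict TSV dialect, JSON
lines, and PubMed/MEDLINE XML (``PubmedArticleSet``). Term lists (stop words,
keyword sets, gating dictionaries) are plain text, one term per line, with
``#`` comment lines allowed.

The TSV dialect is deliberately strict — UTF-8, a fixed header, and no
embedded tabs or newlines inside fields — so corpus files stay trivially
diffable. JSONL is the lossless interchange format for text containing
arbitrary characters.
"""

from __future__ import annotations

import json
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

_TSV_FIELDS = ("doc_id", "title", "abstract", "label", "score")


@dataclass(frozen=True)
class Document:
    """One triage unit: identifier, title, abstract, optional label and score.

    ``label`` is 1 for the positive ("corpus-like") class, 0 for background.
    ``score`` is a classifier output attached after scoring.
    """

    doc_id: str
    title: str
    abstract: str = ""
    label: int | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValidationError("Document doc_id must be non-empty")
        if not self.title:
            raise ValidationError(f"Document {self.doc_id!r}: title must be non-empty")
        if self.label is not None and self.label not in (0, 1):
            raise ValidationError(
                f"Document {self.doc_id!r}: label must be 0 or 1, got {self.label!r}"
            )

    def with_score(self, score: float) -> "Document":
        return replace(self, score=float(score))


@dataclass(frozen=True)
class TermList:
    """Named ordered set of lowercase terms (stop words, keywords, dictionary)."""

    name: str
    terms: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(set(self.terms)) != len(self.terms):
            raise ValidationError(f"TermList {self.name!r} contains duplicate terms")
        for t in self.terms:
            if not t:
                raise ValidationError(f"TermList {self.name!r} contains an empty term")

    def __contains__(self, term: str) -> bool:
        return term in set(self.terms)

    def __len__(self) -> int:
        return len(self.terms)

    def as_set(self) -> frozenset[str]:
        return frozenset(self.terms)


def _check_unique_ids(docs: Sequence[Document]) -> None:
    seen: set[str] = set()
    for d in docs:
        if d.doc_id in seen:
            raise ValidationError(f"duplicate doc_id {d.doc_id!r} in collection")
        seen.add(d.doc_id)


def read_documents(path: str | Path, format: str) -> list[Document]:
    """Read an ordered document collection.

    Parameters
    ----------
    path
        Input file.
    format
        One of ``tsv``, ``jsonl``, ``medline_xml``.
    """
    path = Path(path)
    if format == "tsv":
        docs = _read_tsv(path)
    elif format == "jsonl":
        docs = _read_jsonl(path)
    elif format == "medline_xml":
        docs = _read_medline_xml(path)
    else:
        raise ValidationError(f"unknown corpus format {format!r}")
    _check_unique_ids(docs)
    return docs


def _parse_label(raw: str | None):
    if raw is None or raw == "":
        return None
    if raw not in ("0", "1"):
        raise ParseError(f"label must be 0 or 1, got {raw!r}")
    return int(raw)


def _read_tsv(path: Path) -> list[Document]:
    with open(path, encoding="utf-8", newline="") as fh:
        # split on \n only: unicode line separators may legitimately occur
        # inside fields and must not break records
        lines = fh.read().split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    if not lines:
        return []
    header = lines[0].split("\t")
    if tuple(header) not in [_TSV_FIELDS[:n] for n in (3, 4, 5)]:
        raise ParseError(
            f"{path}: bad TSV header {header!r}; expected doc_id/title/abstract"
            "[/label][/score]"
        )
    docs = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        cells = line.split("\t")
        if len(cells) != len(header):
            raise ParseError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(cells)}"
            )
        rec = dict(zip(header, cells))
        score = rec.get("score")
        docs.append(
            Document(
                doc_id=rec["doc_id"],
                title=rec["title"],
                abstract=rec.get("abstract", ""),
                label=_parse_label(rec.get("label")),
                score=float(score) if score not in (None, "") else None,
            )
        )
    return docs


def _read_jsonl(path: Path) -> list[Document]:
    docs = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            label = rec.get("label")
            docs.append(
                Document(
                    doc_id=str(rec["doc_id"]),
                    title=rec["title"],
                    abstract=rec.get("abstract") or "",
                    label=int(label) if label is not None else None,
                    score=rec.get("score"),
                )
            )
    return docs


def _read_medline_xml(path: Path) -> list[Document]:
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        line, col = exc.position
        raise ParseError(
            f"{path}: malformed XML at line {line}, offset {col}: {exc}"
        ) from exc
    docs = []
    for article in tree.getroot().iter("PubmedArticle"):
        citation = article.find("MedlineCitation")
        if citation is None:
            continue
        pmid_el = citation.find("PMID")
        pmid = (pmid_el.text or "").strip() if pmid_el is not None else ""
        art = citation.find("Article")
        title_el = art.find("ArticleTitle") if art is not None else None
        title = "".join(title_el.itertext()).strip() if title_el is not None else ""
        if not pmid or not title:
            logger.warning(
                "skipping PubmedArticle with missing %s",
                "PMID" if not pmid else f"title (PMID {pmid})",
            )
            continue
        abstract_parts = []
        if art is not None:
            for ab in art.iterfind("Abstract/AbstractText"):
                text = "".join(ab.itertext()).strip()
                if text:
                    abstract_parts.append(text)
        docs.append(Document(doc_id=pmid, title=title, abstract=" ".join(abstract_parts)))
    return docs


def read_term_list(path: str | Path, name: str | None = None) -> TermList:
    """Read a plain-text term list: one term per line, ``#`` comments allowed.

    Lines are trimmed and lowercased; blanks and comments dropped; duplicates
    removed keeping the first occurrence. An empty resulting list is an error.
    """
    path = Path(path)
    terms: list[str] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            term = line.strip().lower()
            if not term or term.startswith("#"):
                continue
            if term not in seen:
                seen.add(term)
                terms.append(term)
    if not terms:
        raise ValidationError(f"{path}: term list is empty after filtering")
    return TermList(name=name or path.stem, terms=tuple(terms))


def _require_scores(docs: Sequence[Document]) -> None:
    for d in docs:
        if d.score is None:
            raise ValidationError(f"document {d.doc_id!r} has no score")


def write_documents(docs: Sequence[Document], path: str | Path, format: str) -> None:
    """Write documents as TSV or JSONL; round-trips with :func:`read_documents`."""
    path = Path(path)
    if format == "tsv":
        _write_tsv(docs, path)
    elif format == "jsonl":
        _write_jsonl(docs, path)
    else:
        raise ValidationError(f"unknown output format {format!r}")


def write_scored_documents(docs: Sequence[Document], path: str | Path, format: str) -> None:
    """Write a scored collection; every document must carry a score."""
    _require_scores(docs)
    write_documents(docs, path, format)


def _write_tsv(docs: Sequence[Document], path: Path) -> None:
    has_label = any(d.label is not None for d in docs)
    has_score = any(d.score is not None for d in docs)
    n_cols = 3 + has_label + has_score
    if has_score and not has_label:
        # score column position is fixed after label; emit empty label column
        has_label = True
        n_cols = 5
    header = _TSV_FIELDS[:n_cols]
    lines = ["\t".join(header)]
    for d in docs:
        cells = [d.doc_id, d.title, d.abstract]
        if has_label:
            cells.append("" if d.label is None else str(d.label))
        if has_score:
            cells.append("" if d.score is None else repr(float(d.score)))
        for name, cell in zip(header, cells):
            if "\t" in cell or "\n" in cell or "\r" in cell:
                raise ValidationError(
                    f"document {d.doc_id!r}: field {name!r} contains a tab or "
                    "newline; use jsonl for such content"
                )
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _write_jsonl(docs: Sequence[Document], path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            rec: dict = {"doc_id": d.doc_id, "title": d.title, "abstract": d.abstract}
            if d.label is not None:
                rec["label"] = d.label
            if d.score is not None:
                rec["score"] = d.score
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
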