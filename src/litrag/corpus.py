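"""Document and chunk data model, corpus ingestion, and the recursive character chunker.

The retrieval corpus is organised at two levels: each paper's abstract is kept
whole as a single *abstract-level* chunk (abstract retrieval operates on whole
abstracts), while the full text is segmented into overlapping *fulltext-level*
chunks by a recursive character splitter (default 500 characters with a
100-character overlap).  Chunks are exact slices of their source text, so the
source can always be reconstructed from the chunk spans.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Document",
    "Chunk",
    "CorpusIndex",
    "CorpusError",
    "DEFAULT_SEPARATORS",
    "load_corpus",
    "chunk_corpus",
    "split_spans",
    "save_chunks",
    "load_chunks",
]

#: Separator hierarchy for the recursive splitter, coarsest first.  The final
#: empty string is the character-level fallback, so every run is splittable.
DEFAULT_SEPARATORS: tuple[str, ...] = ("\n\n", "\n", ". ", "! ", "? ", " ", "")

ABSTRACT = "abstract"
FULLTEXT = "fulltext"

_MD_MARKS = re.compile(r"[#*_`>]+")


class CorpusError(ValueError):
    """Raised for malformed corpora: duplicate ids, bad records, invalid config."""


@dataclass(frozen=True)
class Document:
    """A research paper with its retrievable text and bibliographic metadata."""

    doc_id: str
    title: str
    abstract: str = ""
    full_text: str = ""
    year: int | None = None
    keywords: tuple[str, ...] = ()
    cited_doc_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise CorpusError("document requires a non-empty doc_id")
        if not self.title:
            raise CorpusError(f"document {self.doc_id!r} requires a non-empty title")
        if not self.abstract and not self.full_text:
            raise CorpusError(
                f"document {self.doc_id!r} has neither abstract nor full text"
            )

    def to_record(self) -> dict:
        return {
            "doc_id": self.doc_id,
            "title": self.title,
            "abstract": self.abstract,
            "full_text": self.full_text,
            "year": self.year,
            "keywords": list(self.keywords),
            "cited_doc_ids": list(self.cited_doc_ids),
        }

    @classmethod
    def from_record(cls, rec: dict) -> "Document":
        return cls(
            doc_id=str(rec["doc_id"]),
            title=str(rec.get("title", "")),
            abstract=str(rec.get("abstract", "") or ""),
            full_text=str(rec.get("full_text", "") or ""),
            year=rec.get("year"),
            keywords=tuple(rec.get("keywords", ()) or ()),
            cited_doc_ids=tuple(rec.get("cited_doc_ids", ()) or ()),
        )


@dataclass(frozen=True)
class Chunk:
    """An addressable fragment of one document at one retrieval level.

    ``text`` always equals the slice ``source[char_start:char_end]`` of the
    level's source text (abstract or full text), which keeps every chunk
    traceable to an exact span of the paper it came from.
    """

    chunk_id: str
    doc_id: str
    level: str  # "abstract" | "fulltext"
    text: str
    char_start: int
    char_end: int

    def __post_init__(self) -> None:
        if self.level not in (ABSTRACT, FULLTEXT):
            raise CorpusError(f"unknown chunk level {self.level!r}")
        if not (0 <= self.char_start < self.char_end):
            raise CorpusError(f"invalid span for chunk {self.chunk_id!r}")
        if len(self.text) != self.char_end - self.char_start:
            raise CorpusError(f"text/span length mismatch for chunk {self.chunk_id!r}")

    def to_record(self) -> dict:
        return {
            "chunk_id": self.chunk_id,
            "doc_id": self.doc_id,
            "level": self.level,
            "text": self.text,
            "char_start": self.char_start,
            "char_end": self.char_end,
        }


@dataclass
class CorpusIndex:
    """In-memory corpus: documents plus (after chunking) their chunks by level."""

    documents: dict[str, Document] = field(default_factory=dict)
    chunks: dict[str, Chunk] = field(default_factory=dict)
    by_level: dict[str, list[str]] = field(
        default_factory=lambda: {ABSTRACT: [], FULLTEXT: []}
    )

    def add_document(self, doc: Document) -> None:
        if doc.doc_id in self.documents:
            raise CorpusError(f"duplicate doc_id: {doc.doc_id!r}")
        self.documents[doc.doc_id] = doc

    def add_chunk(self, chunk: Chunk) -> None:
        if chunk.doc_id not in self.documents:
            raise CorpusError(
                f"chunk {chunk.chunk_id!r} references unknown doc_id {chunk.doc_id!r}"
            )
        if chunk.chunk_id in self.chunks:
            raise CorpusError(f"duplicate chunk_id: {chunk.chunk_id!r}")
        self.chunks[chunk.chunk_id] = chunk
        self.by_level[chunk.level].append(chunk.chunk_id)

    def chunk_ids(self, level: str) -> list[str]:
        return list(self.by_level.get(level, ()))

    @property
    def is_chunked(self) -> bool:
        return bool(self.chunks)


def _strip_markdown(text: str) -> str:
    """Markdown is ingested as plain text: formatting marks are dropped."""
    return _MD_MARKS.sub("", text)


def load_corpus(records_path: str | Path, texts_dir: str | Path | None = None) -> CorpusIndex:
    """Load a corpus from a JSON Lines metadata file and optional text directory.

    Each line of ``records_path`` is one JSON object with the ``Document``
    fields.  When ``texts_dir`` is given, a file ``<doc_id>.md`` (or ``.txt``)
    found there supplies the document's full text, stripped of markdown marks.

    Raises :class:`CorpusError` on duplicate ids or unparseable records.
    """
    records_path = Path(records_path)
    if not records_path.exists():
        raise CorpusError(f"records file not found: {records_path}")
    index = CorpusIndex()
    texts_dir = Path(texts_dir) if texts_dir is not None else None
    with records_path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(
                    f"{records_path}:{lineno}: unparseable record ({exc})"
                ) from exc
            full_text = str(rec.get("full_text", "") or "")
            if texts_dir is not None:
                for suffix in (".md", ".txt"):
                    candidate = texts_dir / f"{rec.get('doc_id', '')}{suffix}"
                    if candidate.exists():
                        full_text = _strip_markdown(
                            candidate.read_text(encoding="utf-8")
                        )
                        break
            rec = dict(rec, full_text=full_text)
            index.add_document(Document.from_record(rec))
    return index


# ---------------------------------------------------------------------------
# Recursive character splitting
# ---------------------------------------------------------------------------


def _piece_boundaries(
    text: str, start: int, end: int, separators: Sequence[str], chunk_size: int
) -> list[int]:
    """Return interior break positions partitioning ``text[start:end]`` into
    pieces of at most ``chunk_size`` characters.

    Descends the separator hierarchy: the first separator that actually occurs
    splits the span (the separator stays attached to the preceding piece so
    that concatenating pieces reconstructs the text); oversized pieces recurse
    with the remaining separators.  The empty-string separator cuts every
    ``chunk_size`` characters, so the recursion always terminates with pieces
    no longer than ``chunk_size``.
    """
    if end - start <= chunk_size:
        return []
    for si, sep in enumerate(separators):
        if sep == "":
            return list(range(start + chunk_size, end, chunk_size))
        cuts = []
        pos = start
        while True:
            hit = text.find(sep, pos, end)
            if hit == -1:
                break
            cut = hit + len(sep)
            if start < cut < end:
                cuts.append(cut)
            pos = cut
        if not cuts:
            continue
        boundaries: list[int] = []
        prev = start
        for cut in cuts + [end]:
            if cut - prev > chunk_size:
                boundaries.extend(
                    _piece_boundaries(text, prev, cut, separators[si + 1 :], chunk_size)
                )
            if cut != end:
                boundaries.append(cut)
            prev = cut
        return boundaries
    return []


def split_spans(
    text: str,
    chunk_size: int = 500,
    overlap: int = 100,
    separators: Sequence[str] = DEFAULT_SEPARATORS,
) -> list[tuple[int, int]]:
    """Split ``text`` into overlapping chunk spans by recursive descent.

    Splits preferentially at coarse separators (paragraph, line, sentence end)
    to preserve sentence integrity, falling back to finer ones only when a
    piece still exceeds ``chunk_size``.  Where a split occurs, the next chunk
    restarts ``overlap`` characters before the previous chunk's end, so
    consecutive chunks share exactly that much context.

    Returns a list of ``(char_start, char_end)`` spans covering ``[0, len(text))``.
    """
    if not 0 <= overlap < chunk_size:
        raise CorpusError(
            f"overlap ({overlap}) must be non-negative and smaller than "
            f"chunk_size ({chunk_size})"
        )
    if not separators or separators[-1] != "":
        raise CorpusError("separators must be non-empty and end with ''")
    n = len(text)
    if n == 0:
        return []
    if n <= chunk_size:
        return [(0, n)]
    boundaries = sorted(set(_piece_boundaries(text, 0, n, list(separators), chunk_size)))
    spans: list[tuple[int, int]] = []
    start = 0
    prev_end = 0
    while True:
        limit = start + chunk_size
        if n <= limit:
            spans.append((start, n))
            break
        # largest piece boundary that fits and makes progress
        fitting = [b for b in boundaries if prev_end < b <= limit]
        end = max(fitting) if fitting else limit
        spans.append((start, end))
        prev_end = end
        start = max(0, end - overlap)
    return spans


def chunk_corpus(
    index: CorpusIndex,
    chunk_size: int = 500,
    overlap: int = 100,
    separators: Sequence[str] = DEFAULT_SEPARATORS,
) -> CorpusIndex:
    """Populate ``index`` with abstract- and fulltext-level chunks.

    Each non-empty abstract becomes exactly one abstract-level chunk regardless
    of its length; each non-empty full text is split into fulltext-level chunks
    of at most ``chunk_size`` characters with ``overlap``-character carry-over.
    Chunk ids are ``<doc_id>:<level>:<ordinal>`` so they are stable across runs.
    """
    if index.chunks:
        raise CorpusError("corpus is already chunked")
    for doc_id in sorted(index.documents):
        doc = index.documents[doc_id]
        if doc.abstract:
            index.add_chunk(
                Chunk(
                    chunk_id=f"{doc_id}:{ABSTRACT}:0",
                    doc_id=doc_id,
                    level=ABSTRACT,
                    text=doc.abstract,
                    char_start=0,
                    char_end=len(doc.abstract),
                )
            )
        if doc.full_text:
            for i, (s, e) in enumerate(
                split_spans(doc.full_text, chunk_size, overlap, separators)
            ):
                index.add_chunk(
                    Chunk(
                        chunk_id=f"{doc_id}:{FULLTEXT}:{i}",
                        doc_id=doc_id,
                        level=FULLTEXT,
                        text=doc.full_text[s:e],
                        char_start=s,
                        char_end=e,
                    )
                )
    return index


def save_chunks(index: CorpusIndex, path: str | Path) -> None:
    """Serialize the chunk store as JSON Lines for inspection and re-loading."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for chunk_id in sorted(index.chunks):
            fh.write(json.dumps(index.chunks[chunk_id].to_record()) + "\n")


def load_chunks(index: CorpusIndex, path: str | Path) -> CorpusIndex:
    """Re-load a serialized chunk store into an unchunked ``index``."""
    if index.chunks:
        raise CorpusError("corpus is already chunked")
    chunks = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                chunks.append(Chunk(**json.loads(line)))
    # insert in (doc, level, ordinal) order so by_level ordering is canonical
    for chunk in sorted(chunks, key=lambda c: c.chunk_id):
        index.add_chunk(chunk)
    return index
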