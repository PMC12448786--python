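"""Backend contracts for the two model-dependent capabilities, with deterministic mocks.

The pipeline never talks to an embedding model or an LLM directly: it goes
through :class:`EmbeddingBackend` (dense vectors + cosine similarity) and
:class:`LLMBackend` (pre-retrieval reasoning, relevance judging, drafting,
support scoring, deep final generation, answer grading).  The shipped
implementations are :class:`MockEmbedding` (hashed character 3-gram vectors)
and :class:`MockLLM` (rule-based behaviour driven by a synonym thesaurus and a
table of planted facts).  Both are fully deterministic and seed-free, so the
whole pipeline is reproducible and testable offline; live adapters can be
plugged in behind the same contracts.
"""

from __future__ import annotations

import logging
import re
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Protocol, Sequence, runtime_checkable

import numpy as np

__all__ = [
    "BackendError",
    "EmbeddingBackend",
    "LLMBackend",
    "MockEmbedding",
    "MockLLM",
    "PreretrievalBundle",
    "KeywordGroup",
    "cosine_similarity",
    "top_k_by_similarity",
    "content_words",
]

log = logging.getLogger("litrag")

_WORD = re.compile(r"[A-Za-z0-9][A-Za-z0-9\-']*")

#: Function words excluded from content-word overlap computations.
STOPWORDS = frozenset(
    """a an and are as at be but by for from has have if in into is it its of on
    or that the their this to was were what when which who will with does do did
    how why where can may most used using against than then these those
    """.split()
)


class BackendError(RuntimeError):
    """Typed failure raised by a backend capability."""


def content_words(text: str) -> list[str]:
    """Lower-cased alphanumeric words of ``text`` minus function words."""
    return [w for w in (m.group(0).lower() for m in _WORD.finditer(text)) if w not in STOPWORDS]


# ---------------------------------------------------------------------------
# Pre-retrieval bundle (produced by the LLM backend, consumed by retrieval)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KeywordGroup:
    """A head term with its synonyms; any member matching counts as a group hit."""

    head_term: str
    synonyms: tuple[str, ...] = ()


@dataclass(frozen=True)
class PreretrievalBundle:
    """Keywords with synonym groups plus a virtual answer for one question.

    The virtual answer is a hypothesized answer used purely as an additional
    retrieval query (hypothetical-document expansion); it is never shown to the
    user nor merged into the final answer.
    """

    question: str
    keyword_groups: tuple[KeywordGroup, ...]
    virtual_answer: str

    def __post_init__(self) -> None:
        if not self.keyword_groups and not self.virtual_answer:
            raise ValueError("bundle must carry keyword groups or a virtual answer")

    def to_record(self) -> dict:
        return {
            "question": self.question,
            "keyword_groups": [
                {"head_term": g.head_term, "synonyms": list(g.synonyms)}
                for g in self.keyword_groups
            ],
            "virtual_answer": self.virtual_answer,
        }

    @classmethod
    def from_record(cls, rec: dict) -> "PreretrievalBundle":
        return cls(
            question=rec["question"],
            keyword_groups=tuple(
                KeywordGroup(g["head_term"], tuple(g.get("synonyms", ())))
                for g in rec.get("keyword_groups", ())
            ),
            virtual_answer=rec.get("virtual_answer", ""),
        )


# ---------------------------------------------------------------------------
# Contracts
# ---------------------------------------------------------------------------


@runtime_checkable
class EmbeddingBackend(Protocol):
    """Dense text embedding: same text always maps to the same vector."""

    dimension: int

    def embed(self, texts: Sequence[str]) -> np.ndarray:  # (len(texts), dimension)
        ...


@runtime_checkable
class LLMBackend(Protocol):
    """The reasoning/judging capabilities the pipeline delegates to an LLM."""

    def preretrieve(self, question: str) -> PreretrievalBundle: ...

    def judge_relevance(self, question: str, chunk_text: str) -> tuple[bool, str]: ...

    def draft_answer(self, question: str, chunk_texts: Sequence[str]) -> str: ...

    def score_support(self, question: str, draft_answer: str, chunk_text: str) -> int: ...

    def deep_answer(self, question: str, ranked_chunk_texts: Sequence[str]) -> str: ...

    def direct_answer(self, question: str) -> str: ...

    def grade_answer(self, question: str, answer: str, gold_answer: str) -> int: ...


# ---------------------------------------------------------------------------
# Vector utilities
# ---------------------------------------------------------------------------


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity in [-1, 1]; zero-norm inputs are defined to score 0."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise BackendError(f"dimension mismatch: {a.shape} vs {b.shape}")
    na = float(np.linalg.norm(a))
    nb = float(np.linalg.norm(b))
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def top_k_by_similarity(
    query_vector: np.ndarray,
    candidates: dict[str, np.ndarray],
    k: int,
) -> list[tuple[str, float]]:
    """Rank ``candidates`` (id -> vector) by cosine similarity to the query.

    Returns at most ``k`` pairs sorted by descending similarity, ties broken
    lexicographically by id so rankings are deterministic.  An empty candidate
    set yields an empty result with a warning rather than an error.
    """
    if k < 1:
        raise BackendError(f"k must be >= 1, got {k}")
    if not candidates:
        log.warning("top_k_by_similarity: empty candidate set")
        return []
    scored = [
        (cid, cosine_similarity(query_vector, vec)) for cid, vec in candidates.items()
    ]
    scored.sort(key=lambda p: (-p[1], p[0]))
    return scored[:k]


# ---------------------------------------------------------------------------
# Mock embedding: hashed character 3-gram term-frequency vectors
# ---------------------------------------------------------------------------


class MockEmbedding:
    """Character 3-gram term-frequency vectors hashed into a fixed dimension.

    The text is lower-cased and whitespace-collapsed; every character 3-gram
    increments one of ``dimension`` buckets chosen by CRC-32 of the gram, and
    the vector is length-normalized.  Deterministic and seed-free: identical
    strings embed identically (cosine 1.0), and texts whose 3-gram sets are
    disjoint (and collision-free under the hash) score 0.0.
    """

    def __init__(self, dimension: int = 256):
        if dimension < 1:
            raise BackendError("embedding dimension must be positive")
        self.dimension = dimension

    @staticmethod
    def _normalize(text: str) -> str:
        return " ".join(text.lower().split())

    def _grams(self, text: str) -> list[str]:
        text = self._normalize(text)
        if len(text) < 3:
            return [text] if text else []
        return [text[i : i + 3] for i in range(len(text) - 2)]

    def bucket(self, gram: str) -> int:
        return zlib.crc32(gram.encode("utf-8")) % self.dimension

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        out = np.zeros((len(texts), self.dimension), dtype=np.float64)
        for i, text in enumerate(texts):
            for gram in self._grams(text):
                out[i, self.bucket(gram)] += 1.0
            norm = np.linalg.norm(out[i])
            if norm > 0:
                out[i] /= norm
        return out

    def embed_one(self, text: str) -> np.ndarray:
        return self.embed([text])[0]


# ---------------------------------------------------------------------------
# Mock LLM: rule-based behaviour driven by a thesaurus and planted facts
# ---------------------------------------------------------------------------


def _dedup_case_insensitive(terms: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for term in terms:
        term = term.strip()
        if not term:
            continue
        key = term.lower()
        if key not in seen:
            seen.add(key)
            out.append(term)
    return out


_SENTENCE_SPLIT = re.compile(r"(?<=[.!?])\s+")


@dataclass
class MockLLM:
    """Deterministic stand-in for the LLM backend, driven by fixture knowledge.

    ``thesaurus`` maps a term to its synonym list; ``question_facts`` maps a
    normalized question to the fact tokens whose presence marks a chunk as
    gold evidence for that question.  The rules are intentionally transparent:

    * ``preretrieve`` extracts thesaurus-known terms and capitalized words as
      keywords, attaches thesaurus synonyms, and emits a virtual answer that
      concatenates the question with all keywords and synonyms.
    * ``judge_relevance`` is true iff the chunk contains any of the question's
      fact tokens.
    * ``draft_answer`` / ``deep_answer`` return the sentences of the supplied
      chunks that contain a fact token (first sentence of the top chunk if
      none do).
    * ``score_support`` is the rounded percentage of draft content words
      present in the chunk.
    * ``grade_answer`` maps content-word overlap with the gold answer onto a
      5-point grade.
    """

    thesaurus: dict[str, list[str]] = field(default_factory=dict)
    question_facts: dict[str, list[str]] = field(default_factory=dict)

    @staticmethod
    def _norm_question(question: str) -> str:
        return " ".join(question.lower().split())

    def _facts_for(self, question: str) -> list[str]:
        return self.question_facts.get(self._norm_question(question), [])

    # -- pre-retrieval ------------------------------------------------------

    def preretrieve(self, question: str) -> PreretrievalBundle:
        q = question.strip()
        if not q:
            raise BackendError("empty question")
        heads: list[str] = []
        q_lower = q.lower()
        # thesaurus-known multi-word terms found anywhere in the question
        for term in sorted(self.thesaurus):
            if term.lower() in q_lower:
                heads.append(term)
        # capitalized words (skipping the leading word of the question)
        words = _WORD.findall(q)
        for word in words[1:]:
            if word[:1].isupper():
                heads.append(word)
        heads = _dedup_case_insensitive(heads)
        if not heads:
            raise BackendError("no key terms extracted; nothing to hypothesize from")
        groups = tuple(
            KeywordGroup(
                head_term=h,
                synonyms=tuple(
                    s
                    for s in _dedup_case_insensitive(self.thesaurus.get(h, []))
                    if s.lower() != h.lower()
                ),
            )
            for h in heads
        )
        expansion = [t for g in groups for t in (g.head_term, *g.synonyms)]
        virtual = " ".join([q, *expansion]).strip()
        return PreretrievalBundle(
            question=q, keyword_groups=groups, virtual_answer=virtual
        )

    # -- progressive generation --------------------------------------------

    def judge_relevance(self, question: str, chunk_text: str) -> tuple[bool, str]:
        for token in self._facts_for(question):
            if token.lower() in chunk_text.lower():
                return True, f"chunk states the fact {token!r}"
        return False, "chunk does not state a fact required by the question"

    def _fact_sentences(self, question: str, chunk_texts: Sequence[str]) -> str:
        facts = [t.lower() for t in self._facts_for(question)]
        picked: list[str] = []
        for text in chunk_texts:
            for sentence in _SENTENCE_SPLIT.split(text):
                if any(tok in sentence.lower() for tok in facts):
                    sentence = sentence.strip()
                    if sentence and sentence not in picked:
                        picked.append(sentence)
        if not picked and chunk_texts:
            first = _SENTENCE_SPLIT.split(chunk_texts[0])[0].strip()
            picked = [first] if first else [chunk_texts[0][:100]]
        return " ".join(picked)

    def draft_answer(self, question: str, chunk_texts: Sequence[str]) -> str:
        if not chunk_texts:
            raise BackendError("draft_answer requires at least one chunk")
        return self._fact_sentences(question, chunk_texts)

    def score_support(self, question: str, draft_answer: str, chunk_text: str) -> int:
        words = content_words(draft_answer)
        if not words:
            return 0
        chunk_words = set(content_words(chunk_text))
        hit = sum(1 for w in words if w in chunk_words)
        return round(100 * hit / len(words))

    def deep_answer(self, question: str, ranked_chunk_texts: Sequence[str]) -> str:
        if not ranked_chunk_texts:
            raise BackendError("deep_answer requires at least one chunk")
        return self._fact_sentences(question, ranked_chunk_texts)

    def direct_answer(self, question: str) -> str:
        # no retrieved context: the mock has nothing grounded to say
        return "No supporting evidence was retrieved; unable to substantiate a claim."

    # -- judging ------------------------------------------------------------

    def grade_answer(self, question: str, answer: str, gold_answer: str) -> int:
        gold = content_words(gold_answer)
        if not gold:
            return 1
        got = set(content_words(answer))
        overlap = sum(1 for w in gold if w in got) / len(gold)
        for grade, floor in ((5, 0.8), (4, 0.6), (3, 0.4), (2, 0.2)):
            if overlap >= floor:
                return grade
        return 1
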