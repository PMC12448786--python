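"""Phase 2: multilevel, multigranularity retrieval with weighted rank fusion.

Five strategies probe the corpus from different angles:

* ``question_abstract`` / ``virtual_abstract`` — embedding similarity of the
  question / virtual answer against whole abstracts;
* ``question_fulltext`` / ``virtual_fulltext`` — the same against fulltext
  chunks;
* ``keyword`` — synonym-expanded keyword-group coverage over fulltext chunks.

All hits are fused into one ranking by a weighted normalization score

    S_i = w_S * S_sim,i / S_sim,max  +  w_M * M_i / M_max  +  w_R * R_i / R_max

where ``S_sim,i`` is the chunk's best raw score over the strategies that hit
it, ``M_i`` the number of distinct strategies that hit it, and ``R_i`` the
number of candidate chunks sharing its document.  The default weights are
(5, 3, 1): similarity dominates, strategy diversity helps, intradocument
repetition breaks near-ties.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .backends import EmbeddingBackend, PreretrievalBundle, top_k_by_similarity
from .corpus import ABSTRACT, FULLTEXT, CorpusIndex

__all__ = [
    "STRATEGIES",
    "StrategyHit",
    "RetrievalCandidate",
    "AggregatorWeights",
    "CorpusVectors",
    "retrieve_all",
    "keyword_match_score",
    "aggregate",
    "save_candidates",
]

log = logging.getLogger("litrag")

STRATEGIES = (
    "question_abstract",
    "virtual_abstract",
    "question_fulltext",
    "virtual_fulltext",
    "keyword",
)

#: Keyword hits are unbounded in principle; cap the emitted list to bound the
#: candidate pool (best-scoring chunks kept, ties broken by chunk id).
DEFAULT_KEYWORD_CAP = 50


@dataclass(frozen=True)
class StrategyHit:
    """One chunk retrieved by one strategy, with its within-strategy rank."""

    chunk_id: str
    strategy: str
    raw_score: float
    rank_within_strategy: int

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not 0.0 <= self.raw_score <= 1.0:
            raise ValueError(f"raw_score out of [0, 1]: {self.raw_score}")


@dataclass(frozen=True)
class RetrievalCandidate:
    """A deduplicated chunk with its fusion components and fused score."""

    chunk_id: str
    doc_id: str
    s_sim: float
    m: int
    r: int
    fused_score: float
    contributing_strategies: frozenset[str]

    def to_record(self) -> dict:
        return {
            "chunk_id": self.chunk_id,
            "doc_id": self.doc_id,
            "s_sim": self.s_sim,
            "m": self.m,
            "r": self.r,
            "fused_score": self.fused_score,
            "contributing_strategies": sorted(self.contributing_strategies),
        }


@dataclass(frozen=True)
class AggregatorWeights:
    """Weights of the three fusion factors; defaults follow the (5, 3, 1) setting."""

    w_s: float = 5.0
    w_m: float = 3.0
    w_r: float = 1.0

    def __post_init__(self) -> None:
        if min(self.w_s, self.w_m, self.w_r) < 0:
            raise ValueError("aggregator weights must be non-negative")
        if self.w_s == self.w_m == self.w_r == 0:
            raise ValueError("aggregator weights must not all be zero")


class CorpusVectors:
    """Embeddings of every chunk at each level, computed once per corpus."""

    def __init__(self, index: CorpusIndex, emb: EmbeddingBackend):
        self.index = index
        self.emb = emb
        self._vectors: dict[str, dict[str, np.ndarray]] = {}
        for level in (ABSTRACT, FULLTEXT):
            ids = sorted(index.chunk_ids(level))
            if ids:
                mat = emb.embed([index.chunks[cid].text for cid in ids])
                self._vectors[level] = {cid: mat[i] for i, cid in enumerate(ids)}
            else:
                self._vectors[level] = {}

    def level(self, level: str) -> dict[str, np.ndarray]:
        return self._vectors[level]


def _clamp_score(sim: float, chunk_id: str) -> float:
    if sim < 0.0:
        log.debug("clamping negative similarity %.4f for %s", sim, chunk_id)
        return 0.0
    return min(sim, 1.0)


def keyword_match_score(chunk_text: str, keyword_groups: Sequence) -> float:
    """Fraction of keyword groups matched in ``chunk_text``.

    A group matches iff its head term or any synonym occurs case-insensitively
    on word boundaries.  Empty text scores 0.
    """
    if not keyword_groups:
        raise ValueError("keyword_match_score requires at least one group")
    if not chunk_text:
        return 0.0
    lowered = chunk_text.lower()
    matched = 0
    for group in keyword_groups:
        for term in (group.head_term, *group.synonyms):
            term = term.strip().lower()
            if term and re.search(
                r"(?<!\w)" + re.escape(term) + r"(?!\w)", lowered
            ):
                matched += 1
                break
    return matched / len(keyword_groups)


def retrieve_all(
    bundle: PreretrievalBundle,
    index: CorpusIndex,
    emb: EmbeddingBackend,
    k_per_strategy: int = 10,
    keyword_cap: int = DEFAULT_KEYWORD_CAP,
    vectors: CorpusVectors | None = None,
) -> list[StrategyHit]:
    """Run all five retrieval strategies and return the union of their hits.

    Embedding strategies return the top ``k_per_strategy`` chunks at their
    level; the keyword strategy returns every fulltext chunk with positive
    keyword-group coverage, capped at ``keyword_cap`` by score.  Strategies
    without a query (empty virtual answer, no keyword groups) are skipped.
    Negative similarities are clamped to 0 so raw scores live in [0, 1].
    """
    if not index.is_chunked:
        raise ValueError("corpus index has no chunks; run chunk_corpus first")
    if vectors is None:
        vectors = CorpusVectors(index, emb)

    hits: list[StrategyHit] = []

    embedding_strategies = [
        ("question_abstract", bundle.question, ABSTRACT),
        ("virtual_abstract", bundle.virtual_answer, ABSTRACT),
        ("question_fulltext", bundle.question, FULLTEXT),
        ("virtual_fulltext", bundle.virtual_answer, FULLTEXT),
    ]
    for strategy, query, level in embedding_strategies:
        if not query.strip():
            log.info("strategy %s skipped: empty query", strategy)
            continue
        pool = vectors.level(level)
        if not pool:
            log.info("strategy %s skipped: no %s chunks", strategy, level)
            continue
        qvec = emb.embed([query])[0]
        for rank, (cid, sim) in enumerate(
            top_k_by_similarity(qvec, pool, k_per_strategy), start=1
        ):
            hits.append(StrategyHit(cid, strategy, _clamp_score(sim, cid), rank))

    if bundle.keyword_groups:
        scored = []
        for cid in index.chunk_ids(FULLTEXT):
            score = keyword_match_score(index.chunks[cid].text, bundle.keyword_groups)
            if score > 0.0:
                scored.append((cid, score))
        scored.sort(key=lambda p: (-p[1], p[0]))
        for rank, (cid, score) in enumerate(scored[:keyword_cap], start=1):
            hits.append(StrategyHit(cid, "keyword", score, rank))
    else:
        log.info("strategy keyword skipped: no keyword groups")

    return hits


def aggregate(
    hits: Sequence[StrategyHit],
    index: CorpusIndex,
    weights: AggregatorWeights = AggregatorWeights(),
) -> list[RetrievalCandidate]:
    """Fuse strategy hits into one ranked candidate list.

    Candidates are deduplicated by chunk id; ``s_sim`` is the best raw score
    over the chunk's hits, ``m`` the number of distinct strategies that hit
    it, ``r`` the number of candidate chunks (self included) sharing its
    document.  Each factor is normalized by its maximum over the pool (a zero
    maximum contributes 0) and weighted.  Output is sorted by fused score
    descending, ties broken by chunk id.
    """
    if not hits:
        log.warning("aggregate: empty hit list")
        return []

    by_chunk: dict[str, list[StrategyHit]] = {}
    for hit in hits:
        by_chunk.setdefault(hit.chunk_id, []).append(hit)

    doc_of = {cid: index.chunks[cid].doc_id for cid in by_chunk}
    per_doc: dict[str, int] = {}
    for doc_id in doc_of.values():
        per_doc[doc_id] = per_doc.get(doc_id, 0) + 1

    s_sim = {cid: max(h.raw_score for h in hs) for cid, hs in by_chunk.items()}
    m = {cid: len({h.strategy for h in hs}) for cid, hs in by_chunk.items()}
    r = {cid: per_doc[doc_of[cid]] for cid in by_chunk}

    s_max = max(s_sim.values())
    m_max = max(m.values())
    r_max = max(r.values())

    def term(value: float, vmax: float, weight: float) -> float:
        return weight * value / vmax if vmax > 0 else 0.0

    candidates = [
        RetrievalCandidate(
            chunk_id=cid,
            doc_id=doc_of[cid],
            s_sim=s_sim[cid],
            m=m[cid],
            r=r[cid],
            fused_score=(
                term(s_sim[cid], s_max, weights.w_s)
                + term(m[cid], m_max, weights.w_m)
                + term(r[cid], r_max, weights.w_r)
            ),
            contributing_strategies=frozenset(h.strategy for h in by_chunk[cid]),
        )
        for cid in by_chunk
    ]
    candidates.sort(key=lambda c: (-c.fused_score, c.chunk_id))
    return candidates


def save_candidates(candidates: Sequence[RetrievalCandidate], path: str | Path) -> None:
    """Serialize a ranked candidate list as JSON Lines with all score components."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for cand in candidates:
            fh.write(json.dumps(cand.to_record()) + "\n")
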