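"""End-to-end question answering: pre-retrieval -> fusion retrieval -> progressive generation."""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .backends import EmbeddingBackend, LLMBackend
from .corpus import CorpusIndex
from .generation import (
    DEFAULT_EXAMINATION_CAP,
    DEFAULT_TARGET,
    AnswerRecord,
    run_generation,
)
from .preretrieval import run_preretrieval
from .retrieval import (
    DEFAULT_KEYWORD_CAP,
    AggregatorWeights,
    CorpusVectors,
    RetrievalCandidate,
    aggregate,
    retrieve_all,
)

__all__ = ["PipelineParams", "answer_question", "retrieve_candidates"]

log = logging.getLogger("litrag")


@dataclass(frozen=True)
class PipelineParams:
    """Tunable knobs of the QA pipeline, at their standard settings."""

    k_per_strategy: int = 10
    keyword_cap: int = DEFAULT_KEYWORD_CAP
    weights: AggregatorWeights = AggregatorWeights()
    target: int = DEFAULT_TARGET
    examination_cap: int = DEFAULT_EXAMINATION_CAP


def retrieve_candidates(
    question: str,
    index: CorpusIndex,
    emb: EmbeddingBackend,
    llm: LLMBackend,
    params: PipelineParams = PipelineParams(),
    vectors: CorpusVectors | None = None,
) -> list[RetrievalCandidate]:
    """Phases 1-2: expand the question, run all strategies, fuse into one ranking."""
    bundle = run_preretrieval(question, llm)
    hits = retrieve_all(
        bundle, index, emb, params.k_per_strategy, params.keyword_cap, vectors
    )
    return aggregate(hits, index, params.weights)


def answer_question(
    question: str,
    index: CorpusIndex,
    emb: EmbeddingBackend,
    llm: LLMBackend,
    params: PipelineParams = PipelineParams(),
    vectors: CorpusVectors | None = None,
) -> AnswerRecord:
    """Run the full pipeline for one question and return the answer record."""
    candidates = retrieve_candidates(question, index, emb, llm, params, vectors)
    if not candidates:
        raise ValueError(f"retrieval produced no candidates for {question!r}")
    return run_generation(
        candidates, question, index, llm, params.target, params.examination_cap
    )
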