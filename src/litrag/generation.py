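"""Phases 3-4: progressive reasoning-based generation.

The ranked candidates from retrieval are refined in four steps:

1. **Relevance check** — candidates are examined in fused-score order; the
   backend judges each until a target number (default 5) are accepted.  If the
   examination budget runs out with some but fewer than the target accepted,
   only those are used (*partial*); with none accepted, the top 5 by fused
   score are used regardless (*fallback_top5*).
2. **Answer construction** — a draft answer is generated from the selected
   chunks.
3. **Self-reflective evaluation** — each selected chunk receives a 0-100
   support score for the draft (100 = maximal support, 0 = irrelevant or
   contradictory).
4. **Deep thinking** — chunks with positive support, in descending score
   order, feed the final deep-reasoning generation pass.  The draft itself is
   not forwarded; its only role is to anchor the support scoring.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .backends import LLMBackend
from .corpus import CorpusIndex
from .retrieval import RetrievalCandidate

__all__ = [
    "RelevanceVerdict",
    "SupportScore",
    "AnswerRecord",
    "relevance_check",
    "construct_draft",
    "self_reflect",
    "deep_answer",
    "run_generation",
    "DEFAULT_TARGET",
    "DEFAULT_EXAMINATION_CAP",
]

log = logging.getLogger("litrag")

DEFAULT_TARGET = 5
#: Bound on how many ranked candidates the relevance check may examine.
DEFAULT_EXAMINATION_CAP = 30

RELEVANT_FOUND = "relevant_found"
PARTIAL = "partial"
FALLBACK_TOP5 = "fallback_top5"


@dataclass(frozen=True)
class RelevanceVerdict:
    chunk_id: str
    relevant: bool
    rationale: str
    position_examined: int


@dataclass(frozen=True)
class SupportScore:
    chunk_id: str
    score: int

    def __post_init__(self) -> None:
        if not 0 <= self.score <= 100:
            raise ValueError(f"support score out of [0, 100]: {self.score}")


@dataclass(frozen=True)
class AnswerRecord:
    """Final answer with its full evidence trail."""

    question: str
    draft_answer: str
    final_answer: str
    evidence: tuple[tuple[str, SupportScore], ...]
    selection_mode: str

    def evidence_doc_ids(self, index: CorpusIndex) -> set[str]:
        """Unique source documents of the evidence chunks."""
        return {index.chunks[cid].doc_id for cid, _ in self.evidence}

    def to_record(self, index: CorpusIndex | None = None) -> dict:
        rec = {
            "question": self.question,
            "draft_answer": self.draft_answer,
            "final_answer": self.final_answer,
            "selection_mode": self.selection_mode,
            "evidence": [
                {"chunk_id": cid, "support_score": ss.score}
                for cid, ss in self.evidence
            ],
        }
        if index is not None:
            for ev in rec["evidence"]:
                chunk = index.chunks[ev["chunk_id"]]
                ev.update(
                    doc_id=chunk.doc_id,
                    level=chunk.level,
                    char_start=chunk.char_start,
                    char_end=chunk.char_end,
                )
        return rec


def relevance_check(
    candidates: Sequence[RetrievalCandidate],
    question: str,
    index: CorpusIndex,
    llm: LLMBackend,
    target: int = DEFAULT_TARGET,
    examination_cap: int = DEFAULT_EXAMINATION_CAP,
) -> tuple[list[RetrievalCandidate], list[RelevanceVerdict], str]:
    """Sequentially judge ranked candidates until ``target`` are accepted.

    Returns the selected candidates (in rank order), the verdict trail, and
    the selection mode: ``relevant_found`` when the target was reached,
    ``partial`` when 1..target-1 were accepted before the budget ran out, and
    ``fallback_top5`` (top ``target`` by fused score, regardless of verdicts)
    when none were.
    """
    if not candidates:
        raise ValueError("relevance_check requires a non-empty candidate list")
    if target < 1:
        raise ValueError("target must be >= 1")
    selected: list[RetrievalCandidate] = []
    verdicts: list[RelevanceVerdict] = []
    for position, cand in enumerate(candidates[:examination_cap], start=1):
        relevant, rationale = llm.judge_relevance(
            question, index.chunks[cand.chunk_id].text
        )
        verdicts.append(RelevanceVerdict(cand.chunk_id, relevant, rationale, position))
        if relevant:
            selected.append(cand)
            if len(selected) == target:
                log.info("relevance_check: target reached after %d examinations", position)
                return selected, verdicts, RELEVANT_FOUND
    if selected:
        log.info(
            "relevance_check: %d/%d relevant after %d examinations (partial)",
            len(selected), target, len(verdicts),
        )
        return selected, verdicts, PARTIAL
    log.info("relevance_check: none relevant; falling back to top-%d by score", target)
    return list(candidates[:target]), verdicts, FALLBACK_TOP5


def construct_draft(
    question: str,
    selected: Sequence[RetrievalCandidate],
    index: CorpusIndex,
    llm: LLMBackend,
) -> str:
    """Generate the initial draft answer from the selected chunks (in fused-score order)."""
    if not selected:
        raise ValueError("construct_draft requires at least one selected chunk")
    texts = [index.chunks[c.chunk_id].text for c in selected]
    log.debug("construct_draft over chunks %s", [c.chunk_id for c in selected])
    draft = llm.draft_answer(question, texts)
    if not draft:
        raise ValueError("backend produced an empty draft")
    return draft


def self_reflect(
    question: str,
    draft: str,
    selected: Sequence[RetrievalCandidate],
    index: CorpusIndex,
    llm: LLMBackend,
) -> list[SupportScore]:
    """Score each selected chunk's support for the draft on the 0-100 scale.

    Out-of-range backend values are clamped and logged; unparseable values are
    treated as 0 with a warning.
    """
    if not draft:
        raise ValueError("self_reflect requires a non-empty draft")
    scores: list[SupportScore] = []
    for cand in selected:
        raw = llm.score_support(question, draft, index.chunks[cand.chunk_id].text)
        try:
            value = int(raw)
        except (TypeError, ValueError):
            log.warning("unparseable support score %r for %s; using 0", raw, cand.chunk_id)
            value = 0
        if not 0 <= value <= 100:
            log.warning("clamping support score %d for %s", value, cand.chunk_id)
            value = min(100, max(0, value))
        scores.append(SupportScore(cand.chunk_id, value))
    return scores


def deep_answer(
    question: str,
    draft: str,
    scored: Sequence[tuple[RetrievalCandidate, SupportScore]],
    index: CorpusIndex,
    llm: LLMBackend,
    selection_mode: str,
) -> AnswerRecord:
    """Run the deep-thinking final generation over the best-supported chunks.

    Chunks with positive support are forwarded in descending score order
    (ties by chunk id); if every score is 0, all chunks are forwarded in the
    incoming fused-score order instead.
    """
    if not scored:
        raise ValueError("deep_answer requires at least one scored chunk")
    positive = [(c, s) for c, s in scored if s.score > 0]
    if positive:
        ordered = sorted(positive, key=lambda p: (-p[1].score, p[0].chunk_id))
    else:
        ordered = list(scored)
    final = llm.deep_answer(
        question, [index.chunks[c.chunk_id].text for c, _ in ordered]
    )
    return AnswerRecord(
        question=question,
        draft_answer=draft,
        final_answer=final,
        evidence=tuple((c.chunk_id, s) for c, s in ordered),
        selection_mode=selection_mode,
    )


def run_generation(
    candidates: Sequence[RetrievalCandidate],
    question: str,
    index: CorpusIndex,
    llm: LLMBackend,
    target: int = DEFAULT_TARGET,
    examination_cap: int = DEFAULT_EXAMINATION_CAP,
) -> AnswerRecord:
    """Run all four generation phases and return the answer record."""
    selected, verdicts, mode = relevance_check(
        candidates, question, index, llm, target, examination_cap
    )
    draft = construct_draft(question, selected, index, llm)
    scores = self_reflect(question, draft, selected, index, llm)
    return deep_answer(
        question, draft, list(zip(selected, scores)), index, llm, mode
    )


def save_answer(record: AnswerRecord, index: CorpusIndex, path: str | Path) -> None:
    """Write the machine-readable answer (with evidence provenance) as JSON."""
    Path(path).write_text(
        json.dumps(record.to_record(index), indent=2), encoding="utf-8"
    )
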