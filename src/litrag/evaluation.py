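"""Measurement protocol: document-retrieval precision/recall/F1, judge-based
answer scoring on a 5-point scale reported as a percentage, ablation runners,
and the per-strategy recall decomposition.

*Retrieved documents* for precision/recall/F1 are defined as the unique source
documents of the chunks selected for final generation — the evidence the
answer actually used — and that definition is recorded in every results file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .backends import EmbeddingBackend, LLMBackend, top_k_by_similarity
from .corpus import ABSTRACT, FULLTEXT, CorpusIndex
from .generation import run_generation
from .pipeline import PipelineParams, answer_question, retrieve_candidates
from .preretrieval import run_preretrieval
from .retrieval import (
    CorpusVectors,
    RetrievalCandidate,
    keyword_match_score,
    retrieve_all,
)

__all__ = [
    "ABLATION_MODES",
    "GoldQARecord",
    "EvalRecord",
    "score_retrieval",
    "score_answer",
    "run_ablation",
    "recall_decomposition",
    "load_gold_records",
    "save_results",
]

log = logging.getLogger("litrag")

ABLATION_MODES = ("full", "no_progressive", "no_integrated", "no_retrieval")

#: Flat-retrieval pool size for the no_integrated ablation.
FLAT_TOP_K = 50

RETRIEVED_DOCS_DEFINITION = (
    "unique source documents of the chunks selected for final generation"
)


@dataclass(frozen=True)
class GoldQARecord:
    """One gold QA tuple: question, reference answer, and its source papers."""

    question: str
    gold_answer: str
    gold_doc_ids: frozenset[str]
    question_type: str = ""

    def __post_init__(self) -> None:
        if not self.gold_doc_ids:
            raise ValueError(f"gold record for {self.question!r} has no gold_doc_ids")


@dataclass(frozen=True)
class EvalRecord:
    """Per-question retrieval and answer-quality metrics."""

    question: str
    retrieved_doc_ids: frozenset[str] | None
    precision: float | None
    recall: float | None
    f1: float | None
    answer_score: float
    question_type: str = ""


def load_gold_records(path: str | Path) -> list[GoldQARecord]:
    """Load gold QA records from JSON Lines."""
    records = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            records.append(
                GoldQARecord(
                    question=rec["question"],
                    gold_answer=rec["gold_answer"],
                    gold_doc_ids=frozenset(rec["gold_doc_ids"]),
                    question_type=rec.get("question_type", ""),
                )
            )
    return records


def score_retrieval(
    retrieved_doc_ids: set[str] | frozenset[str],
    gold_doc_ids: set[str] | frozenset[str],
) -> tuple[float, float, float]:
    """Document-level precision, recall and F1 with the 0/0 guard."""
    if not gold_doc_ids:
        raise ValueError("gold_doc_ids must be non-empty")
    hit = len(set(retrieved_doc_ids) & set(gold_doc_ids))
    precision = hit / len(retrieved_doc_ids) if retrieved_doc_ids else 0.0
    recall = hit / len(gold_doc_ids)
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1


def score_answer(
    question: str, final_answer: str, gold_answer: str, judge: LLMBackend
) -> float:
    """Judge the answer on the 5-point scale, reported as (grade/5) x 100."""
    if not question or not final_answer or not gold_answer:
        raise ValueError("score_answer requires non-empty texts")
    raw = judge.grade_answer(question, final_answer, gold_answer)
    try:
        grade = int(raw)
    except (TypeError, ValueError):
        log.warning("unparseable judge grade %r; scoring 0", raw)
        return 0.0
    if not 1 <= grade <= 5:
        log.warning("judge grade %d out of [1, 5]; clamping", grade)
        grade = min(5, max(1, grade))
    return grade / 5 * 100


# ---------------------------------------------------------------------------
# Ablation runners
# ---------------------------------------------------------------------------


def _flat_candidates(
    question: str, index: CorpusIndex, emb: EmbeddingBackend, vectors: CorpusVectors
) -> list[RetrievalCandidate]:
    """Flat top-k fulltext retrieval by question embedding only (no fusion)."""
    pool = vectors.level(FULLTEXT)
    qvec = emb.embed([question])[0]
    ranked = top_k_by_similarity(qvec, pool, FLAT_TOP_K)
    per_doc: dict[str, int] = {}
    for cid, _ in ranked:
        doc_id = index.chunks[cid].doc_id
        per_doc[doc_id] = per_doc.get(doc_id, 0) + 1
    return [
        RetrievalCandidate(
            chunk_id=cid,
            doc_id=index.chunks[cid].doc_id,
            s_sim=max(0.0, min(1.0, sim)),
            m=1,
            r=per_doc[index.chunks[cid].doc_id],
            fused_score=max(0.0, sim),
            contributing_strategies=frozenset({"question_fulltext"}),
        )
        for cid, sim in ranked
    ]


def _evaluate_one(
    mode: str,
    gold: GoldQARecord,
    index: CorpusIndex,
    emb: EmbeddingBackend,
    llm: LLMBackend,
    params: PipelineParams,
    vectors: CorpusVectors,
) -> EvalRecord:
    if mode == "no_retrieval":
        final = llm.direct_answer(gold.question)
        answer_score = score_answer(gold.question, final or " ", gold.gold_answer, llm)
        return EvalRecord(gold.question, None, None, None, None, answer_score,
                          gold.question_type)

    if mode == "full":
        record = answer_question(gold.question, index, emb, llm, params, vectors)
    elif mode == "no_progressive":
        candidates = retrieve_candidates(gold.question, index, emb, llm, params, vectors)
        top = candidates[: params.target]
        if not top:
            raise ValueError(f"no candidates for {gold.question!r}")
        final = llm.deep_answer(gold.question, [index.chunks[c.chunk_id].text for c in top])
        retrieved = frozenset(c.doc_id for c in top)
        answer_score = score_answer(gold.question, final or " ", gold.gold_answer, llm)
        p, r, f1 = score_retrieval(retrieved, gold.gold_doc_ids)
        return EvalRecord(gold.question, retrieved, p, r, f1, answer_score,
                          gold.question_type)
    elif mode == "no_integrated":
        candidates = _flat_candidates(gold.question, index, emb, vectors)
        if not candidates:
            raise ValueError(f"no candidates for {gold.question!r}")
        record = run_generation(
            candidates, gold.question, index, llm, params.target, params.examination_cap
        )
    else:
        raise ValueError(f"unknown ablation mode {mode!r}")

    retrieved = frozenset(record.evidence_doc_ids(index))
    p, r, f1 = score_retrieval(retrieved, gold.gold_doc_ids)
    answer_score = score_answer(
        gold.question, record.final_answer or " ", gold.gold_answer, llm
    )
    return EvalRecord(gold.question, retrieved, p, r, f1, answer_score,
                      gold.question_type)


def run_ablation(
    mode: str,
    gold: Sequence[GoldQARecord],
    index: CorpusIndex,
    emb: EmbeddingBackend,
    llm: LLMBackend,
    params: PipelineParams = PipelineParams(),
    vectors: CorpusVectors | None = None,
) -> dict:
    """Evaluate one pipeline configuration over the gold set.

    ``full`` runs the entire pipeline; ``no_progressive`` answers directly
    from the top-5 fused candidates; ``no_integrated`` replaces fusion
    retrieval with a flat top-50 by question embedding, then runs progressive
    generation; ``no_retrieval`` answers with no context (retrieval metrics
    are then not applicable and reported as None).
    """
    if mode not in ABLATION_MODES:
        raise ValueError(f"unknown ablation mode {mode!r}; choose from {ABLATION_MODES}")
    if not gold:
        raise ValueError("gold record list is empty")
    if vectors is None:
        vectors = CorpusVectors(index, emb)
    records = [
        _evaluate_one(mode, g, index, emb, llm, params, vectors) for g in gold
    ]
    with_retrieval = mode != "no_retrieval"
    summary = {
        "mode": mode,
        "n_questions": len(records),
        "retrieved_docs_definition": RETRIEVED_DOCS_DEFINITION,
        "mean_precision": (
            sum(r.precision for r in records) / len(records) if with_retrieval else None
        ),
        "mean_recall": (
            sum(r.recall for r in records) / len(records) if with_retrieval else None
        ),
        "mean_f1": (
            sum(r.f1 for r in records) / len(records) if with_retrieval else None
        ),
        "mean_answer_score": sum(r.answer_score for r in records) / len(records),
        "per_question": records,
    }
    return summary


# ---------------------------------------------------------------------------
# Per-strategy recall decomposition
# ---------------------------------------------------------------------------


def recall_decomposition(
    gold: Sequence[GoldQARecord],
    index: CorpusIndex,
    emb: EmbeddingBackend,
    llm: LLMBackend,
    params: PipelineParams = PipelineParams(),
    vectors: CorpusVectors | None = None,
) -> dict:
    """Document-level recall per granularity, per level, and cumulatively.

    Rows are the three query granularities (question-based, virtual-answer-
    based, keyword-based); columns give recall at the abstract level, the
    fulltext level, their union (multilevel), and the cumulative recall as
    granularities are added in that order.  All values are percentages.
    """
    if not gold:
        raise ValueError("gold record list is empty")
    if vectors is None:
        vectors = CorpusVectors(index, emb)

    granularities = ("question", "virtual", "keyword")
    level_docs: dict[str, dict[str, list[set[str]]]] = {
        g: {"abstract": [], "fulltext": []} for g in granularities
    }
    for g_record in gold:
        bundle = run_preretrieval(g_record.question, llm)
        hits = retrieve_all(
            bundle, index, emb, params.k_per_strategy, params.keyword_cap, vectors
        )
        docs: dict[tuple[str, str], set[str]] = {}
        for hit in hits:
            chunk = index.chunks[hit.chunk_id]
            if hit.strategy.startswith("question"):
                key = ("question", chunk.level)
            elif hit.strategy.startswith("virtual"):
                key = ("virtual", chunk.level)
            else:
                key = ("keyword", chunk.level)
            docs.setdefault(key, set()).add(chunk.doc_id)
        # keyword matching over abstracts, measured here for the table only
        # (the pipeline's keyword strategy runs at the fulltext level)
        if bundle.keyword_groups:
            kw_abs = {
                index.chunks[cid].doc_id
                for cid in index.chunk_ids(ABSTRACT)
                if keyword_match_score(index.chunks[cid].text, bundle.keyword_groups) > 0
            }
            docs[("keyword", ABSTRACT)] = kw_abs
        for granularity in granularities:
            for level in (ABSTRACT, FULLTEXT):
                level_docs[granularity][level].append(
                    docs.get((granularity, level), set())
                )

    def mean_recall(doc_sets: Sequence[set[str]]) -> float:
        total = 0.0
        for g_record, docs_ in zip(gold, doc_sets):
            total += len(docs_ & g_record.gold_doc_ids) / len(g_record.gold_doc_ids)
        return 100 * total / len(gold)

    table: dict[str, dict[str, float]] = {}
    cumulative_sets = [set() for _ in gold]
    for granularity in granularities:
        abs_sets = level_docs[granularity]["abstract"]
        ft_sets = level_docs[granularity]["fulltext"]
        multi_sets = [a | f for a, f in zip(abs_sets, ft_sets)]
        cumulative_sets = [c | m for c, m in zip(cumulative_sets, multi_sets)]
        table[granularity] = {
            "abstract": mean_recall(abs_sets),
            "fulltext": mean_recall(ft_sets),
            "multilevel": mean_recall(multi_sets),
            "cumulative": mean_recall(cumulative_sets),
        }
    return table


# ---------------------------------------------------------------------------
# Results output
# ---------------------------------------------------------------------------


def save_results(summary: dict, out_dir: str | Path, config_snapshot: dict | None = None) -> dict[str, Path]:
    """Write per-question CSV, JSON summary of means, and a config snapshot."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "question": r.question,
            "question_type": r.question_type,
            "retrieved_doc_ids": (
                ";".join(sorted(r.retrieved_doc_ids)) if r.retrieved_doc_ids else ""
            ),
            "precision": r.precision,
            "recall": r.recall,
            "f1": r.f1,
            "answer_score": r.answer_score,
        }
        for r in summary["per_question"]
    ]
    csv_path = out_dir / f"results_{summary['mode']}.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    json_path = out_dir / f"summary_{summary['mode']}.json"
    json_payload = {k: v for k, v in summary.items() if k != "per_question"}
    json_path.write_text(json.dumps(json_payload, indent=2), encoding="utf-8")
    paths = {"csv": csv_path, "json": json_path}
    if config_snapshot is not None:
        snap_path = out_dir / f"config_{summary['mode']}.json"
        snap_path.write_text(json.dumps(config_snapshot, indent=2), encoding="utf-8")
        paths["config"] = snap_path
    return paths
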