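"""Phase 1: pre-retrieval reasoning.

Before touching the corpus, the question is expanded into a
:class:`~litrag.backends.PreretrievalBundle`: key terms with synonym groups
(for flexible keyword matching) and a *virtual answer*, a hypothesized answer
used as an extra retrieval query.  The backend's raw output is repaired here —
empty terms stripped, synonyms deduplicated case-insensitively, head terms
removed from their own synonym lists, group counts bounded — so downstream
phases can rely on a validated bundle.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from .backends import BackendError, KeywordGroup, LLMBackend, PreretrievalBundle

__all__ = ["run_preretrieval", "normalize_question", "save_bundle", "load_bundle"]

log = logging.getLogger("litrag")

#: Bounds on keyword expansion, to keep keyword matching cheap.
MAX_GROUPS = 10
MAX_SYNONYMS = 10


def normalize_question(question: str) -> str:
    """Whitespace-normalize a question; the cache key for bundles."""
    return " ".join(question.split())


def _repair(bundle: PreretrievalBundle) -> PreretrievalBundle:
    groups: list[KeywordGroup] = []
    for group in bundle.keyword_groups[:MAX_GROUPS]:
        head = group.head_term.strip()
        if not head:
            continue
        seen = {head.lower()}
        synonyms: list[str] = []
        for syn in group.synonyms:
            syn = syn.strip()
            key = syn.lower()
            if syn and key not in seen:
                seen.add(key)
                synonyms.append(syn)
        groups.append(KeywordGroup(head, tuple(synonyms[:MAX_SYNONYMS])))
    return PreretrievalBundle(
        question=bundle.question,
        keyword_groups=tuple(groups),
        virtual_answer=bundle.virtual_answer.strip(),
    )


def run_preretrieval(question: str, llm: LLMBackend) -> PreretrievalBundle:
    """Derive keywords, synonym groups, and a virtual answer for ``question``.

    Falls back to a degraded bundle — the whole question as the single head
    term — when the backend yields neither keywords nor a virtual answer.
    Raises ``ValueError`` for an empty question.
    """
    question = normalize_question(question)
    if not question:
        raise ValueError("question is empty")
    try:
        bundle = _repair(llm.preretrieve(question))
        if bundle.keyword_groups or bundle.virtual_answer:
            return bundle
    except (BackendError, ValueError) as exc:
        log.warning("preretrieval backend failed (%s); degraded bundle", exc)
    log.warning("preretrieval degraded mode for question %r", question)
    return PreretrievalBundle(
        question=question,
        keyword_groups=(KeywordGroup(head_term=question),),
        virtual_answer="",
    )


def save_bundle(bundle: PreretrievalBundle, path: str | Path) -> None:
    Path(path).write_text(json.dumps(bundle.to_record(), indent=2), encoding="utf-8")


def load_bundle(path: str | Path) -> PreretrievalBundle:
    return PreretrievalBundle.from_record(
        json.loads(Path(path).read_text(encoding="utf-8"))
    )
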