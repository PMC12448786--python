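"""Dual-layer knowledge-graph construction with provenance.

Two graph layers are built from the corpus.  The *entity layer* holds typed
biomedical entities — genes, proteins, drugs, diseases — connected by relation
triplets (e1, r, e2) extracted from abstracts, with each mention normalized
against a reference vocabulary (nearest-neighbour candidate retrieval followed
by backend adjudication).  The *document layer* holds papers connected to the
research methods, datasets and research domains they use, with surface names
merged sequentially whenever their embedding similarity strictly exceeds 0.5.
Every edge carries an ``evidence_source`` — the id of the paper supporting it —
and parallel edges with distinct relations or evidence are kept separate, so
the graph stays fully traceable.  Cross-document links connect papers that
share at least one canonical entity, and citation edges follow each paper's
reference list.
"""

from __future__ import annotations

import csv
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol, Sequence, runtime_checkable

import networkx as nx
import numpy as np

from .backends import EmbeddingBackend, cosine_similarity
from .corpus import Document

__all__ = [
    "ENTITY_TYPES",
    "DOCUMENT_TYPES",
    "DEFAULT_RELATIONS",
    "Triplet",
    "VocabularyIndex",
    "MergeRegistry",
    "KnowledgeGraph",
    "MockExtractor",
    "extract_triplets",
    "normalize_entity",
    "merge_document_entity",
    "assemble_graph",
    "average_degree",
    "graph_stats",
    "export_graph",
    "import_graph",
    "load_vocabulary",
]

log = logging.getLogger("litrag")

ENTITY_LAYER = "entity"
DOCUMENT_LAYER = "document"

ENTITY_TYPES = frozenset({"gene", "protein", "drug", "disease"})
DOCUMENT_TYPES = frozenset({"paper", "method", "dataset", "research_domain"})

#: Default relation vocabulary.  The full relation-type list used upstream is
#: configuration; these defaults cover common biomedical relations plus the
#: structural document-layer and cross-document relations.
DEFAULT_RELATIONS = frozenset(
    {
        "treats",
        "inhibits",
        "promotes",
        "associated_with",
        "interacts_with",
        "uses_method",
        "uses_dataset",
        "in_domain",
        "cites",
        "shares_entity",
    }
)

#: How many nearest vocabulary candidates are offered to adjudication.
NORMALIZATION_CANDIDATES = 5

#: Two document-layer names denote the same concept iff their embedding
#: cosine similarity strictly exceeds this threshold.
MERGE_THRESHOLD = 0.5


@dataclass(frozen=True)
class Triplet:
    """A provenance-carrying assertion (e1, r, e2) at one graph layer."""

    e1: str
    e1_type: str
    r: str
    e2: str
    e2_type: str
    evidence_source: str
    layer: str

    def __post_init__(self) -> None:
        allowed = ENTITY_TYPES if self.layer == ENTITY_LAYER else DOCUMENT_TYPES
        if self.layer not in (ENTITY_LAYER, DOCUMENT_LAYER):
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.e1_type not in allowed or self.e2_type not in allowed:
            raise ValueError(
                f"entity types ({self.e1_type!r}, {self.e2_type!r}) not in the "
                f"{self.layer}-layer vocabulary"
            )
        if not self.evidence_source:
            raise ValueError("triplet requires an evidence_source")


# ---------------------------------------------------------------------------
# Reference vocabularies (term lists standing in for curated databases)
# ---------------------------------------------------------------------------


class VocabularyIndex:
    """Canonical terms with types and embeddings, for entity normalization."""

    def __init__(
        self,
        entries: Sequence[tuple[str, str, str]],
        emb: EmbeddingBackend,
    ):
        self.entries: list[tuple[str, str, str]] = []
        seen: set[tuple[str, str]] = set()
        for term, etype, source in entries:
            key = (term.lower(), etype)
            if key in seen:
                raise ValueError(f"duplicate vocabulary term {term!r} for type {etype!r}")
            seen.add(key)
            self.entries.append((term, etype, source))
        self._by_type: dict[str, list[int]] = {}
        for i, (_, etype, _) in enumerate(self.entries):
            self._by_type.setdefault(etype, []).append(i)
        if self.entries:
            self._vectors = emb.embed([term for term, _, _ in self.entries])
        else:
            self._vectors = np.zeros((0, emb.dimension))
        self._emb = emb

    def candidates(self, mention: str, etype: str, k: int) -> list[str]:
        """The ``k`` vocabulary terms of ``etype`` nearest to ``mention``."""
        idx = self._by_type.get(etype, [])
        if not idx:
            return []
        qvec = self._emb.embed([mention])[0]
        scored = [
            (self.entries[i][0], cosine_similarity(qvec, self._vectors[i]))
            for i in idx
        ]
        scored.sort(key=lambda p: (-p[1], p[0]))
        return [term for term, _ in scored[:k]]


def load_vocabulary(path: str | Path, emb: EmbeddingBackend) -> VocabularyIndex:
    """Load a vocabulary TSV (canonical_term <TAB> type <TAB> source_tag)."""
    entries = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed vocabulary line: {line!r}")
            term, etype = parts[0], parts[1]
            source = parts[2] if len(parts) > 2 else ""
            entries.append((term, etype, source))
    return VocabularyIndex(entries, emb)


# ---------------------------------------------------------------------------
# Extraction / adjudication backend contract and its mock
# ---------------------------------------------------------------------------


@runtime_checkable
class TripletExtractionBackend(Protocol):
    """LLM capabilities used by graph construction."""

    def extract_entity_triplets(
        self, text: str
    ) -> list[tuple[str, str, str, str, str]]:
        """Raw (e1, e1_type, r, e2, e2_type) tuples found in ``text``."""
        ...

    def extract_document_triplets(
        self, doc: Document
    ) -> list[tuple[str, str, str, str, str]]: ...

    def adjudicate_entity(
        self, mention: str, etype: str, candidates: Sequence[str]
    ) -> str | None:
        """Choose the candidate that standardizes ``mention``, or None."""
        ...


_SENTENCES = re.compile(r"(?<=[.!?])\s+")

#: Surface relation phrases recognized by the mock extractor.
RELATION_PHRASES = {
    "treats": "treats",
    "inhibits": "inhibits",
    "promotes": "promotes",
    "is associated with": "associated_with",
    "interacts with": "interacts_with",
}


@dataclass
class MockExtractor:
    """Rule-based extraction/adjudication stand-in driven by fixture knowledge.

    ``entity_lexicon`` maps surface mention -> entity type; entity triplets
    are emitted when a sentence contains two known mentions bridged by a
    recognized relation phrase.  ``doc_info`` maps doc_id -> the paper's
    method/dataset/domain for document-layer summarization.  Adjudication
    accepts a candidate iff it equals the mention case-insensitively or the
    thesaurus links the two; otherwise the mention is out-of-vocabulary.
    """

    entity_lexicon: dict[str, str] = field(default_factory=dict)
    doc_info: dict[str, dict[str, str]] = field(default_factory=dict)
    thesaurus: dict[str, list[str]] = field(default_factory=dict)

    def extract_entity_triplets(self, text: str) -> list[tuple[str, str, str, str, str]]:
        out = []
        for sentence in _SENTENCES.split(text):
            lowered = sentence.lower()
            for phrase, relation in RELATION_PHRASES.items():
                pos = lowered.find(f" {phrase} ")
                if pos == -1:
                    continue
                left, right = sentence[:pos], sentence[pos + len(phrase) + 2 :]
                e1 = self._last_mention(left)
                e2 = self._first_mention(right)
                if e1 and e2:
                    out.append((e1, self.entity_lexicon[e1], relation, e2, self.entity_lexicon[e2]))
        return out

    def _mention_positions(self, text: str) -> list[tuple[int, str]]:
        lowered = text.lower()
        hits = []
        for mention in self.entity_lexicon:
            pos = lowered.find(mention.lower())
            if pos != -1:
                hits.append((pos, mention))
        return sorted(hits)

    def _last_mention(self, text: str) -> str | None:
        hits = self._mention_positions(text)
        return hits[-1][1] if hits else None

    def _first_mention(self, text: str) -> str | None:
        hits = self._mention_positions(text)
        return hits[0][1] if hits else None

    def extract_document_triplets(self, doc: Document) -> list[tuple[str, str, str, str, str]]:
        info = self.doc_info.get(doc.doc_id, {})
        out = []
        for key, relation, etype in (
            ("method", "uses_method", "method"),
            ("dataset", "uses_dataset", "dataset"),
            ("domain", "in_domain", "research_domain"),
        ):
            value = info.get(key)
            if value:
                out.append((doc.doc_id, "paper", relation, value, etype))
        return out

    def adjudicate_entity(
        self, mention: str, etype: str, candidates: Sequence[str]
    ) -> str | None:
        mention_l = mention.lower()
        linked = {s.lower() for s in self.thesaurus.get(mention, [])}
        for candidate in candidates:
            cand_l = candidate.lower()
            if cand_l == mention_l or cand_l in linked:
                return candidate
            if mention_l in {s.lower() for s in self.thesaurus.get(candidate, [])}:
                return candidate
        return None


# ---------------------------------------------------------------------------
# Extraction and normalization
# ---------------------------------------------------------------------------


def extract_triplets(
    doc: Document,
    llm: TripletExtractionBackend,
    layer: str,
    relation_vocab: frozenset[str] = DEFAULT_RELATIONS,
    counters: dict[str, int] | None = None,
) -> list[Triplet]:
    """Extract schema-validated triplets from one document at one layer.

    Entity-layer extraction runs over the abstract; document-layer extraction
    summarizes the paper's method, dataset and research domain.  Raw items
    with unknown types or relations are dropped and counted in ``counters``
    (key ``"dropped"``); a wholly failed extraction yields an empty list.
    """
    if layer == ENTITY_LAYER:
        if not doc.abstract:
            raise ValueError(f"document {doc.doc_id!r} has no abstract to extract from")
        raw = llm.extract_entity_triplets(doc.abstract)
        allowed = ENTITY_TYPES
    elif layer == DOCUMENT_LAYER:
        raw = llm.extract_document_triplets(doc)
        allowed = DOCUMENT_TYPES
    else:
        raise ValueError(f"unknown layer {layer!r}")

    triplets: list[Triplet] = []
    for e1, t1, r, e2, t2 in raw:
        if t1 not in allowed or t2 not in allowed or r not in relation_vocab:
            if counters is not None:
                counters["dropped"] = counters.get("dropped", 0) + 1
            log.info("dropping out-of-schema triplet (%r, %r, %r) from %s", e1, r, e2, doc.doc_id)
            continue
        triplets.append(Triplet(e1, t1, r, e2, t2, doc.doc_id, layer))
    return triplets


def normalize_entity(
    mention: str,
    etype: str,
    vocab: VocabularyIndex,
    emb: EmbeddingBackend,
    llm: TripletExtractionBackend,
) -> str:
    """Map a surface mention to a canonical vocabulary term.

    The nearest vocabulary candidates (by embedding similarity) are offered to
    the adjudication capability; if it rejects all of them — or the vocabulary
    has no terms of this type — the mention itself becomes canonical and is
    logged as out-of-vocabulary.
    """
    candidates = vocab.candidates(mention, etype, NORMALIZATION_CANDIDATES)
    if not candidates:
        log.warning("empty vocabulary for type %r; %r passes through", etype, mention)
        return mention
    chosen = llm.adjudicate_entity(mention, etype, candidates)
    if chosen is None:
        log.info("mention %r (%s) is out-of-vocabulary; kept as canonical", mention, etype)
        return mention
    return chosen


class MergeRegistry:
    """Sequential insert-or-merge registry for document-layer entity names.

    Names are processed one at a time: a name whose embedding similarity to an
    existing canonical entry strictly exceeds the 0.5 threshold is merged into
    the most similar such entry; otherwise it is registered as a new canonical
    entry.  The outcome is order-dependent by construction, so callers should
    fix a deterministic processing order.
    """

    def __init__(self, emb: EmbeddingBackend):
        self._emb = emb
        self.canonical: list[str] = []
        self._vectors: list[np.ndarray] = []
        self.mapping: dict[str, str] = {}

    def __len__(self) -> int:
        return len(self.canonical)

    def resolve(self, name: str) -> str:
        """Insert-or-merge ``name``; returns its canonical id (idempotent)."""
        if not name:
            raise ValueError("cannot register an empty name")
        if name in self.mapping:
            return self.mapping[name]
        vec = self._emb.embed([name])[0]
        best_i, best_sim = -1, MERGE_THRESHOLD
        for i, other in enumerate(self._vectors):
            sim = cosine_similarity(vec, other)
            if sim > best_sim:
                best_i, best_sim = i, sim
        if best_i >= 0:
            canonical = self.canonical[best_i]
            log.debug("merged %r into %r (similarity %.3f)", name, canonical, best_sim)
        else:
            canonical = name
            self.canonical.append(name)
            self._vectors.append(vec)
        self.mapping[name] = canonical
        return canonical


def merge_document_entity(name: str, registry: MergeRegistry, emb: EmbeddingBackend) -> str:
    """Insert-or-merge one document-layer entity name (see :class:`MergeRegistry`)."""
    return registry.resolve(name)


# ---------------------------------------------------------------------------
# Graph assembly, statistics, export
# ---------------------------------------------------------------------------


class KnowledgeGraph:
    """Typed multigraph of canonical entities with provenance-carrying edges.

    Nodes are unique per (canonical name, type); edges are directed, labeled
    with a relation, and keyed by (relation, evidence_source) so the same
    assertion from two papers yields two parallel edges while an exact
    duplicate from one paper is stored once.
    """

    def __init__(self) -> None:
        self.graph = nx.MultiDiGraph()

    @staticmethod
    def node_key(name: str, etype: str) -> str:
        return f"{etype}::{name}"

    def add_node(self, name: str, etype: str) -> str:
        key = self.node_key(name, etype)
        if key not in self.graph:
            self.graph.add_node(key, name=name, type=etype)
        return key

    def add_edge(
        self,
        e1: str,
        e1_type: str,
        relation: str,
        e2: str,
        e2_type: str,
        evidence_source: str,
        **attrs,
    ) -> bool:
        """Add one edge; returns False if it duplicates an existing edge."""
        u = self.add_node(e1, e1_type)
        v = self.add_node(e2, e2_type)
        key = f"{relation}|{evidence_source}"
        if self.graph.has_edge(u, v, key=key):
            return False
        self.graph.add_edge(
            u, v, key=key, relation=relation, evidence_source=evidence_source, **attrs
        )
        return True

    @property
    def node_count(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def edge_count(self) -> int:
        return self.graph.number_of_edges()

    def edges(self):
        return self.graph.edges(keys=True, data=True)


def assemble_graph(
    triplets: Iterable[Triplet],
    documents: dict[str, Document] | None = None,
    counters: dict[str, int] | None = None,
) -> KnowledgeGraph:
    """Assemble the dual-layer graph from normalized triplets.

    Duplicate edges (same endpoints, relation and evidence) are skipped.
    When ``documents`` is supplied, triplets citing unknown papers are
    rejected (counted under ``"rejected"``), citation edges are added from
    each paper's reference list (restricted to in-corpus ids), and papers
    sharing at least one canonical entity are linked with a ``shares_entity``
    edge carrying the shared-entity count.
    """
    kg = KnowledgeGraph()
    entity_papers: dict[str, set[str]] = {}
    for t in triplets:
        if documents is not None and t.evidence_source not in documents:
            if counters is not None:
                counters["rejected"] = counters.get("rejected", 0) + 1
            log.warning("triplet cites unknown doc_id %r; rejected", t.evidence_source)
            continue
        kg.add_edge(t.e1, t.e1_type, t.r, t.e2, t.e2_type, t.evidence_source)
        if t.layer == ENTITY_LAYER:
            for name, etype in ((t.e1, t.e1_type), (t.e2, t.e2_type)):
                entity_papers.setdefault(kg.node_key(name, etype), set()).add(
                    t.evidence_source
                )

    if documents is not None:
        for doc_id in sorted(documents):
            for cited in documents[doc_id].cited_doc_ids:
                if cited in documents:
                    kg.add_edge(doc_id, "paper", "cites", cited, "paper", doc_id)
        # cross-document links via shared canonical entities
        shared: dict[tuple[str, str], int] = {}
        for papers in entity_papers.values():
            ordered = sorted(papers)
            for i, a in enumerate(ordered):
                for b in ordered[i + 1 :]:
                    shared[(a, b)] = shared.get((a, b), 0) + 1
        for (a, b), count in sorted(shared.items()):
            kg.add_edge(a, "paper", "shares_entity", b, "paper", a, shared_count=count)
    return kg


def average_degree(node_count: int, edge_count: int) -> float:
    """Average total degree of a directed multigraph: 2E/N, to 2 decimals.

    Each directed edge contributes to both endpoints' degree, so the mean
    degree over nodes is twice the edge count divided by the node count.
    The value is truncated (not rounded) to 2 decimals, the convention used
    for reported graph statistics here.
    """
    if node_count == 0:
        return 0.0
    return math.floor(200 * edge_count / node_count) / 100


def graph_stats(kg: KnowledgeGraph) -> dict:
    """Node/edge counts, average degree (2E/N, 2 decimals), degree histogram."""
    n = kg.node_count
    e = kg.edge_count
    if n == 0:
        return {"node_count": 0, "edge_count": 0, "average_degree": 0.0, "degree_histogram": {}}
    histogram: dict[int, int] = {}
    for _, degree in kg.graph.degree():
        histogram[degree] = histogram.get(degree, 0) + 1
    return {
        "node_count": n,
        "edge_count": e,
        "average_degree": average_degree(n, e),
        "degree_histogram": dict(sorted(histogram.items())),
    }


def export_graph(kg: KnowledgeGraph, destination: str | Path) -> dict[str, Path]:
    """Write bulk-import CSV tables (nodes, relationships) plus a GraphML file.

    The CSV layout follows graph-database bulk-import conventions: nodes carry
    ``:ID`` and ``:LABEL`` columns, relationships ``:START_ID``, ``:END_ID``
    and ``:TYPE``, with ``evidence_source`` as a property column.  Parallel
    edges appear as separate relationship rows.
    """
    destination = Path(destination)
    destination.mkdir(parents=True, exist_ok=True)
    nodes_path = destination / "nodes.csv"
    rels_path = destination / "relationships.csv"
    graphml_path = destination / "graph.graphml"

    with nodes_path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([":ID", "name", ":LABEL"])
        for key in sorted(kg.graph.nodes):
            data = kg.graph.nodes[key]
            writer.writerow([key, data["name"], data["type"]])

    with rels_path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([":START_ID", ":END_ID", ":TYPE", "evidence_source", "shared_count"])
        rows = [
            (u, v, data["relation"], data["evidence_source"], data.get("shared_count", ""))
            for u, v, _, data in kg.edges()
        ]
        writer.writerows(sorted(rows))

    nx.write_graphml(kg.graph, graphml_path)
    return {"nodes": nodes_path, "relationships": rels_path, "graphml": graphml_path}


def import_graph(destination: str | Path) -> KnowledgeGraph:
    """Re-load a graph from the bulk-import CSV tables written by :func:`export_graph`."""
    destination = Path(destination)
    kg = KnowledgeGraph()
    with (destination / "nodes.csv").open("r", encoding="utf-8", newline="") as fh:
        for row in list(csv.reader(fh))[1:]:
            _, name, etype = row
            kg.add_node(name, etype)
    with (destination / "relationships.csv").open("r", encoding="utf-8", newline="") as fh:
        for row in list(csv.reader(fh))[1:]:
            start, end, relation, evidence, shared = row
            s_type, s_name = start.split("::", 1)
            e_type, e_name = end.split("::", 1)
            attrs = {"shared_count": int(shared)} if shared else {}
            kg.add_edge(s_name, s_type, relation, e_name, e_type, evidence, **attrs)
    return kg
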