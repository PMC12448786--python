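"""Knowledge-graph construction: extraction, normalization, merging,
assembly, statistics, and export round trips."""

import math
import random

import numpy as np
import pytest

from litrag.backends import MockEmbedding
from litrag.corpus import Document
from litrag.kg import (
    DOCUMENT_LAYER,
    ENTITY_LAYER,
    KnowledgeGraph,
    MergeRegistry,
    MockExtractor,
    Triplet,
    VocabularyIndex,
    assemble_graph,
    average_degree,
    export_graph,
    extract_triplets,
    graph_stats,
    import_graph,
    load_vocabulary,
    merge_document_entity,
    normalize_entity,
)


class FixedEmbedding:
    """Embedding with hand-assigned vectors, for exact similarity control."""

    def __init__(self, table: dict[str, list[float]], dimension: int = 2):
        self.table = table
        self.dimension = dimension

    def embed(self, texts):
        return np.array([self.table[t] for t in texts], dtype=float)


@pytest.fixture
def extractor():
    return MockExtractor(
        entity_lexicon={
            "DrugX": "drug",
            "DiseaseY": "disease",
            "GeneZ": "gene",
            "NSCLC": "disease",
        },
        doc_info={"p1": {"method": "cohort analysis", "dataset": "Registry-A",
                         "domain": "oncology"}},
        thesaurus={"NSCLC": ["non-small cell lung carcinoma"]},
    )


class TestExtractTriplets:
    def test_planted_fact_extracted_with_evidence(self, extractor):
        doc = Document(doc_id="p1", title="T", abstract="We show DrugX treats DiseaseY.")
        (t,) = extract_triplets(doc, extractor, ENTITY_LAYER)
        assert (t.e1, t.r, t.e2) == ("DrugX", "treats", "DiseaseY")
        assert (t.e1_type, t.e2_type) == ("drug", "disease")
        assert t.evidence_source == "p1"

    def test_unknown_type_dropped_and_counted(self):
        class BadBackend:
            def extract_entity_triplets(self, text):
                return [("HeLa", "cell_line", "treats", "DiseaseY", "disease")]

        doc = Document(doc_id="p1", title="T", abstract="x.")
        counters = {}
        out = extract_triplets(doc, BadBackend(), ENTITY_LAYER, counters=counters)
        assert out == []
        assert counters["dropped"] == 1

    def test_document_layer_summarizes_method_dataset_domain(self, extractor):
        doc = Document(doc_id="p1", title="T", abstract="a.", full_text="b")
        triplets = extract_triplets(doc, extractor, DOCUMENT_LAYER)
        assert {(t.r, t.e2) for t in triplets} == {
            ("uses_method", "cohort analysis"),
            ("uses_dataset", "Registry-A"),
            ("in_domain", "oncology"),
        }
        assert all(t.e1 == "p1" and t.e1_type == "paper" for t in triplets)


class TestNormalizeEntity:
    def test_exact_match_returns_vocabulary_term(self, extractor):
        emb = MockEmbedding()
        vocab = VocabularyIndex(
            [("DiseaseY", "disease", "mesh"), ("OtherD", "disease", "mesh")], emb
        )
        assert normalize_entity("DiseaseY", "disease", vocab, emb, extractor) == "DiseaseY"

    def test_candidate_list_capped_at_five(self):
        emb = MockEmbedding()
        vocab = VocabularyIndex(
            [(f"term {i}", "drug", "mesh") for i in range(9)], emb
        )
        assert len(vocab.candidates("term", "drug", 5)) == 5

    def test_abbreviation_resolved_via_thesaurus_link(self, extractor):
        emb = MockEmbedding()
        vocab = VocabularyIndex(
            [
                ("non-small cell lung carcinoma", "disease", "mesh"),
                ("mammary neoplasm", "disease", "mesh"),
            ],
            emb,
        )
        out = normalize_entity("NSCLC", "disease", vocab, emb, extractor)
        assert out == "non-small cell lung carcinoma"

    def test_out_of_vocabulary_mention_passes_through(self, extractor):
        emb = MockEmbedding()
        vocab = VocabularyIndex([("unrelated term", "disease", "mesh")], emb)
        assert normalize_entity("Zzqx", "disease", vocab, emb, extractor) == "Zzqx"

    def test_empty_vocabulary_passes_through_with_warning(self, extractor):
        emb = MockEmbedding()
        vocab = VocabularyIndex([], emb)
        assert normalize_entity("DrugX", "drug", vocab, emb, extractor) == "DrugX"

    def test_vocabulary_tsv_round_trip(self, tmp_path):
        emb = MockEmbedding()
        path = tmp_path / "vocab.tsv"
        path.write_text("aspirin\tdrug\tmesh\nTP53\tgene\tuniprot\n", encoding="utf-8")
        vocab = load_vocabulary(path, emb)
        assert vocab.candidates("aspirin", "drug", 5) == ["aspirin"]
        assert vocab.candidates("TP53", "gene", 5) == ["TP53"]


class TestMergeRegistry:
    def test_similarity_exactly_half_is_not_merged(self):
        # cosine([0,1,1], [3,0,3]) evaluates to exactly 0.5 in floating point;
        # the strictly-greater threshold keeps the two names separate
        emb = FixedEmbedding({"a": [0.0, 1.0, 1.0], "b": [3.0, 0.0, 3.0]}, dimension=3)
        reg = MergeRegistry(emb)
        assert merge_document_entity("a", reg, emb) == "a"
        assert merge_document_entity("b", reg, emb) == "b"
        assert len(reg) == 2

    def test_identical_names_merge(self):
        emb = MockEmbedding()
        reg = MergeRegistry(emb)
        reg.resolve("flow cytometry")
        assert reg.resolve("flow cytometry") == "flow cytometry"
        assert len(reg) == 1

    def test_resubmission_is_idempotent(self):
        emb = MockEmbedding()
        reg = MergeRegistry(emb)
        first = reg.resolve("single-cell profiling")
        size = len(reg)
        assert reg.resolve("single-cell profiling") == first
        assert len(reg) == size

    def test_six_name_sequential_trace(self):
        # unit vectors at controlled angles; expected outcome hand-traced:
        #   n1 -> new; n2 (cos .9 to n1) -> n1; n3 (orthogonal to n1) -> new;
        #   n4 (cos .6 to n1, .8 to n3) -> merges into the closer n3;
        #   n5 (cos .31 to n1, negative to n3) -> new;
        #   n6 (cos .995 to n5, below threshold for n1 and n3) -> n5
        s = math.sqrt
        angle5 = math.radians(-72)
        table = {
            "n1": [1.0, 0.0],
            "n2": [0.9, s(1 - 0.81)],
            "n3": [0.0, 1.0],
            "n4": [0.6, 0.8],
            "n5": [math.cos(angle5), math.sin(angle5)],
            "n6": [math.cos(angle5 + 0.1), math.sin(angle5 + 0.1)],
        }
        emb = FixedEmbedding(table)
        reg = MergeRegistry(emb)
        mapping = {name: reg.resolve(name) for name in ["n1", "n2", "n3", "n4", "n5", "n6"]}
        assert mapping == {
            "n1": "n1", "n2": "n1", "n3": "n3", "n4": "n3", "n5": "n5", "n6": "n5",
        }
        assert reg.canonical == ["n1", "n3", "n5"]


class TestAssembleGraph:
    T = lambda self, e1, r, e2, src: Triplet(e1, "drug", r, e2, "disease", src, "entity")

    def test_same_assertion_from_two_papers_gives_parallel_edges(self):
        kg = assemble_graph([self.T("DrugX", "treats", "DiseaseY", "p1"),
                             self.T("DrugX", "treats", "DiseaseY", "p2")])
        assert kg.node_count == 2
        assert kg.edge_count == 2
        evidences = {d["evidence_source"] for _, _, _, d in kg.edges()}
        assert evidences == {"p1", "p2"}

    def test_exact_duplicate_from_one_paper_stored_once(self):
        kg = assemble_graph([self.T("DrugX", "treats", "DiseaseY", "p1"),
                             self.T("DrugX", "treats", "DiseaseY", "p1")])
        assert kg.edge_count == 1

    def test_unknown_evidence_rejected_when_corpus_known(self):
        docs = {"p1": Document(doc_id="p1", title="T", abstract="a")}
        counters = {}
        kg = assemble_graph([self.T("DrugX", "treats", "DiseaseY", "px")], docs, counters)
        assert kg.edge_count == 0
        assert counters["rejected"] == 1

    def test_ten_triplet_fixture_matches_hand_built_adjacency(self):
        triplets = [
            self.T("DrugA", "treats", "Dis1", "p1"),
            self.T("DrugA", "treats", "Dis1", "p2"),   # parallel edge
            self.T("DrugA", "treats", "Dis1", "p2"),   # duplicate -> skipped
            self.T("DrugA", "inhibits", "Dis2", "p1"),
            self.T("DrugB", "treats", "Dis1", "p3"),
            self.T("DrugB", "treats", "Dis2", "p3"),
            self.T("DrugB", "promotes", "Dis2", "p4"),
            self.T("DrugC", "treats", "Dis3", "p4"),
            self.T("DrugC", "treats", "Dis3", "p4"),   # duplicate -> skipped
            self.T("DrugA", "treats", "Dis3", "p1"),
        ]
        kg = assemble_graph(triplets)
        # nodes: 3 drugs + 3 diseases; edges: 10 - 2 duplicates = 8
        assert kg.node_count == 6
        assert kg.edge_count == 8

    def test_citation_and_shared_entity_links(self, manifest7):
        docs = {
            d["doc_id"]: Document(
                doc_id=d["doc_id"], title=d["title"], abstract=d["abstract"],
                cited_doc_ids=tuple(d["cited_doc_ids"]),
            )
            for d in manifest7.documents
        }
        triplets = [Triplet(**t, layer="entity") for t in manifest7.planted_triplets]
        kg = assemble_graph(triplets, docs)
        relations = {d["relation"] for _, _, _, d in kg.edges()}
        assert "cites" in relations
        assert "shares_entity" in relations
        # gold documents of one question share drug+gene+disease nodes
        shared_counts = [
            d["shared_count"] for _, _, _, d in kg.edges() if d["relation"] == "shares_entity"
        ]
        assert all(c >= 1 for c in shared_counts)


class TestGraphStats:
    def test_published_scale_counts_give_six_point_one_one(self):
        assert average_degree(94_962, 290_403) == 6.11

    def test_smallest_graph(self):
        kg = KnowledgeGraph()
        kg.add_edge("a", "drug", "treats", "b", "disease", "p1")
        assert graph_stats(kg)["average_degree"] == 1.0

    def test_empty_graph_all_zero(self):
        stats = graph_stats(KnowledgeGraph())
        assert stats == {"node_count": 0, "edge_count": 0, "average_degree": 0.0,
                         "degree_histogram": {}}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_histogram_consistency_on_random_graphs(self, seed):
        rng = random.Random(seed)
        kg = KnowledgeGraph()
        names = [f"e{i}" for i in range(rng.randint(2, 15))]
        for _ in range(rng.randint(1, 40)):
            a, b = rng.sample(names, 2)
            kg.add_edge(a, "gene", "interacts_with", b, "gene", f"p{rng.randrange(5)}")
        stats = graph_stats(kg)
        hist = stats["degree_histogram"]
        assert sum(hist.values()) == stats["node_count"]
        mean = sum(k * v for k, v in hist.items()) / stats["node_count"]
        assert mean == pytest.approx(2 * stats["edge_count"] / stats["node_count"])
        assert stats["average_degree"] == pytest.approx(mean, abs=0.01)


class TestExport:
    def _fixture_graph(self):
        kg = KnowledgeGraph()
        kg.add_edge("DrugX", "drug", "treats", "DiseaseY", "disease", "p1")
        kg.add_edge("DrugX", "drug", "treats", "DiseaseY", "disease", "p2")
        kg.add_edge("GeneZ", "gene", "associated_with", "DiseaseY", "disease", "p1")
        kg.add_edge("p1", "paper", "shares_entity", "p2", "paper", "p1", shared_count=2)
        return kg

    def test_empty_graph_exports_header_only(self, tmp_path):
        paths = export_graph(KnowledgeGraph(), tmp_path)
        assert paths["nodes"].read_text().strip() == ":ID,name,:LABEL"
        assert len(paths["relationships"].read_text().strip().splitlines()) == 1

    def test_round_trip_preserves_counts_and_evidence(self, tmp_path):
        kg = self._fixture_graph()
        export_graph(kg, tmp_path)
        back = import_graph(tmp_path)
        assert back.node_count == kg.node_count
        assert back.edge_count == kg.edge_count
        original = sorted(
            (u, v, d["relation"], d["evidence_source"]) for u, v, _, d in kg.edges()
        )
        restored = sorted(
            (u, v, d["relation"], d["evidence_source"]) for u, v, _, d in back.edges()
        )
        assert original == restored

    def test_multi_edge_pair_yields_two_relationship_rows(self, tmp_path):
        paths = export_graph(self._fixture_graph(), tmp_path)
        rows = paths["relationships"].read_text().strip().splitlines()[1:]
        treats_rows = [r for r in rows if ",treats," in r]
        assert len(treats_rows) == 2

    def test_graphml_written_and_parsable(self, tmp_path):
        import networkx as nx

        export_graph(self._fixture_graph(), tmp_path)
        g = nx.read_graphml(tmp_path / "graph.graphml")
        assert g.number_of_nodes() == 5
        assert g.number_of_edges() == 4
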