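"""Strategy retrieval, keyword matching, and the weighted fusion aggregator."""

import random

import pytest

from litrag.backends import KeywordGroup
from litrag.corpus import Chunk, CorpusIndex, Document
from litrag.preretrieval import run_preretrieval
from litrag.retrieval import (
    STRATEGIES,
    AggregatorWeights,
    StrategyHit,
    aggregate,
    keyword_match_score,
    retrieve_all,
)

# ---------------------------------------------------------------------------
# Synthetic pools for aggregator tests
# ---------------------------------------------------------------------------


def make_index(doc_of: dict[str, str]) -> CorpusIndex:
    """Index with one fulltext chunk per entry of chunk_id -> doc_id."""
    index = CorpusIndex()
    for doc_id in sorted(set(doc_of.values())):
        index.add_document(Document(doc_id=doc_id, title=doc_id, abstract="a"))
    for cid in sorted(doc_of):
        index.add_chunk(
            Chunk(cid, doc_of[cid], "fulltext", "text", 0, 4)
        )
    return index


def fused_oracle(hits, doc_of, w):
    """Independent one-line evaluation of the weighted normalization score."""
    chunks = sorted({h.chunk_id for h in hits})
    s = {c: max(h.raw_score for h in hits if h.chunk_id == c) for c in chunks}
    m = {c: len({h.strategy for h in hits if h.chunk_id == c}) for c in chunks}
    r = {c: sum(1 for c2 in chunks if doc_of[c2] == doc_of[c]) for c in chunks}
    smax, mmax, rmax = max(s.values()), max(m.values()), max(r.values())
    return {
        c: (w.w_s * s[c] / smax if smax else 0.0)
        + (w.w_m * m[c] / mmax if mmax else 0.0)
        + (w.w_r * r[c] / rmax if rmax else 0.0)
        for c in chunks
    }


def random_pool(rng: random.Random, max_chunks: int = 20):
    n_docs = rng.randint(1, 6)
    n_chunks = rng.randint(1, max_chunks)
    doc_of = {f"c{i:02d}": f"d{rng.randrange(n_docs)}" for i in range(n_chunks)}
    hits = []
    for cid in doc_of:
        for strategy in rng.sample(STRATEGIES, rng.randint(1, 5)):
            hits.append(
                StrategyHit(cid, strategy, round(rng.random(), 6), rng.randint(1, 10))
            )
    return hits, doc_of


class TestAggregate:
    def test_single_candidate_scores_nine_under_default_weights(self):
        index = make_index({"c1": "d1"})
        hits = [StrategyHit("c1", "keyword", 0.4, 1)]
        (cand,) = aggregate(hits, index)
        assert cand.fused_score == pytest.approx(9.0)
        assert (cand.s_sim, cand.m, cand.r) == (0.4, 1, 1)

    def test_default_weights_are_five_three_one(self):
        w = AggregatorWeights()
        assert (w.w_s, w.w_m, w.w_r) == (5.0, 3.0, 1.0)

    def test_three_candidate_worked_example(self):
        # A: s=.9 m=2 r=1 | B: s=.6 m=3 r=2 | C: s=.3 m=1 r=2
        doc_of = {"A": "d1", "B": "d2", "C": "d2"}
        index = make_index(doc_of)
        hits = [
            StrategyHit("A", "question_fulltext", 0.9, 1),
            StrategyHit("A", "virtual_fulltext", 0.7, 2),
            StrategyHit("B", "question_fulltext", 0.6, 3),
            StrategyHit("B", "virtual_fulltext", 0.5, 1),
            StrategyHit("B", "keyword", 0.6, 1),
            StrategyHit("C", "keyword", 0.3, 2),
        ]
        cands = aggregate(hits, index)
        assert [c.chunk_id for c in cands] == ["A", "B", "C"]
        assert cands[0].fused_score == pytest.approx(7.5)
        assert cands[1].fused_score == pytest.approx(7 + 1 / 3)
        assert cands[2].fused_score == pytest.approx(11 / 3)
        oracle = fused_oracle(hits, doc_of, AggregatorWeights())
        for c in cands:
            assert c.fused_score == pytest.approx(oracle[c.chunk_id], abs=1e-9)

    def test_empty_hits_yield_empty_ranking(self):
        assert aggregate([], make_index({"c": "d"})) == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_oracle_equivalence_on_random_pools(self, seed):
        rng = random.Random(seed)
        w = AggregatorWeights()
        for _ in range(50):
            hits, doc_of = random_pool(rng)
            index = make_index(doc_of)
            oracle = fused_oracle(hits, doc_of, w)
            for cand in aggregate(hits, index, w):
                assert cand.fused_score == pytest.approx(oracle[cand.chunk_id], abs=1e-9)

    def test_scale_invariance_of_ranking(self):
        rng = random.Random(5)
        for _ in range(20):
            hits, doc_of = random_pool(rng)
            index = make_index(doc_of)
            scaled = [
                StrategyHit(h.chunk_id, h.strategy, h.raw_score * 0.25, h.rank_within_strategy)
                for h in hits
            ]
            order = [c.chunk_id for c in aggregate(hits, index)]
            order_scaled = [c.chunk_id for c in aggregate(scaled, index)]
            assert order == order_scaled

    def test_monotonicity_in_similarity(self):
        rng = random.Random(9)
        for _ in range(20):
            hits, doc_of = random_pool(rng)
            index = make_index(doc_of)
            ranked = aggregate(hits, index)
            target = ranked[-1].chunk_id
            if ranked[-1].s_sim >= max(c.s_sim for c in ranked):
                continue
            boosted = [
                StrategyHit(
                    h.chunk_id,
                    h.strategy,
                    min(1.0, h.raw_score + 0.3) if h.chunk_id == target else h.raw_score,
                    h.rank_within_strategy,
                )
                for h in hits
            ]
            before = [c.chunk_id for c in ranked].index(target)
            after = [c.chunk_id for c in aggregate(boosted, index)].index(target)
            assert after <= before

    def test_fused_score_bounded_by_weight_sum(self):
        rng = random.Random(13)
        w = AggregatorWeights()
        for _ in range(20):
            hits, doc_of = random_pool(rng)
            for cand in aggregate(hits, make_index(doc_of), w):
                assert cand.fused_score <= w.w_s + w.w_m + w.w_r + 1e-12

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            AggregatorWeights(-1, 3, 1)
        with pytest.raises(ValueError):
            AggregatorWeights(0, 0, 0)


class TestKeywordMatchScore:
    G = [
        KeywordGroup("lung cancer", ("pulmonary carcinoma",)),
        KeywordGroup("EGFR", ()),
    ]

    def test_all_heads_present_scores_one(self):
        assert keyword_match_score("EGFR mutations in lung cancer.", self.G) == 1.0

    def test_synonym_counts_for_its_group(self):
        assert keyword_match_score("A pulmonary carcinoma cohort.", self.G) == 0.5

    def test_word_boundaries_respected(self):
        assert keyword_match_score("the EGFRx protein", [self.G[1]]) == 0.0

    def test_empty_chunk_scores_zero(self):
        assert keyword_match_score("", self.G) == 0.0

    def test_matches_exhaustive_scan_oracle(self):
        rng = random.Random(21)
        words = ["lung", "cancer", "egfr", "pulmonary", "carcinoma", "cell", "assay"]
        for _ in range(100):
            text = " ".join(rng.choices(words, k=rng.randint(0, 25)))
            score = keyword_match_score(text, self.G)
            tokens = text.lower().split()
            joined = " " + " ".join(tokens) + " "
            matched = 0
            for group in self.G:
                terms = [group.head_term.lower()] + [s.lower() for s in group.synonyms]
                if any(f" {t} " in joined for t in terms):
                    matched += 1
            assert score == pytest.approx(matched / len(self.G))


class TestRetrieveAll:
    def test_empty_virtual_answer_skips_two_strategies(self, index7, emb7, vectors7):
        from litrag.backends import PreretrievalBundle

        bundle = PreretrievalBundle(
            question="Which compound shows benefit in lung cancer?",
            keyword_groups=(KeywordGroup("lung cancer", ("pulmonary carcinoma",)),),
            virtual_answer="",
        )
        hits = retrieve_all(bundle, index7, emb7, vectors=vectors7)
        strategies = {h.strategy for h in hits}
        assert "virtual_abstract" not in strategies
        assert "virtual_fulltext" not in strategies
        assert {"question_abstract", "question_fulltext", "keyword"} <= strategies

    def test_top_k_default_is_ten(self, index7, emb7, llm7, vectors7):
        bundle = run_preretrieval("Which compound shows benefit in lung cancer?", llm7)
        hits = retrieve_all(bundle, index7, emb7, vectors=vectors7)
        for strategy in ("question_abstract", "virtual_abstract",
                         "question_fulltext", "virtual_fulltext"):
            assert sum(1 for h in hits if h.strategy == strategy) == 10

    def test_planted_fact_chunk_hit_by_multiple_strategies(
        self, manifest7, index7, emb7, llm7, vectors7
    ):
        gold = manifest7.gold_qa[0]
        bundle = run_preretrieval(gold["question"], llm7)
        hits = retrieve_all(bundle, index7, emb7, vectors=vectors7)
        token = gold["fact_tokens"][0]
        fact_chunks = {
            cid
            for cid in index7.chunks
            if token in index7.chunks[cid].text
            and index7.chunks[cid].doc_id in gold["gold_doc_ids"]
        }
        strategies_hitting_gold = {
            h.strategy for h in hits if h.chunk_id in fact_chunks
        }
        assert len(strategies_hitting_gold) >= 2

    def test_unchunked_index_is_hard_error(self, manifest7, emb7, llm7):
        from litrag.fixtures import manifest_index

        bundle = run_preretrieval("Which compound shows benefit in lung cancer?", llm7)
        with pytest.raises(ValueError):
            retrieve_all(bundle, manifest_index(manifest7), emb7)

    def test_raw_scores_clamped_to_unit_interval(self, index7, emb7, llm7, vectors7):
        bundle = run_preretrieval("Which compound shows benefit in kidney failure?", llm7)
        for hit in retrieve_all(bundle, index7, emb7, vectors=vectors7):
            assert 0.0 <= hit.raw_score <= 1.0
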