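# litrag

Retrieval-augmented question answering over a local corpus of biomedical
research papers, combining **integrated reasoning-based retrieval** (query
expansion + multi-strategy retrieval with weighted rank fusion) with
**progressive reasoning-based generation** (sequential relevance checking,
self-reflective evidence scoring, and a final deep-reasoning pass).  The
package also builds a dual-layer **knowledge graph** from the same corpus —
typed biomedical entities at one layer, papers linked through shared methods,
datasets, domains and citations at the other — with full per-edge provenance,
and ships the evaluation harness used to measure document retrieval and
answer quality.

It is written for text-mining researchers and engineers who want a fully
deterministic, offline-testable reference implementation: every
model-dependent step (text embedding, LLM reasoning and judging) sits behind
a backend contract, and the shipped backends are transparent rule-based mocks
driven by a synthetic corpus generator with planted facts.

## The method

Answering one question proceeds in four phases.

1. **Pre-retrieval reasoning.** The question is expanded into key terms with
   synonym groups and a *virtual answer* — a hypothesized answer used as an
   additional query (hypothetical-document expansion).

2. **Multilevel, multigranularity retrieval.** Five strategies each return
   their top k = 10 hits: question and virtual answer against whole abstracts,
   question and virtual answer against full-text chunks (500 characters,
   100-character overlap, split by a recursive character splitter), plus
   synonym-expanded keyword matching over full-text chunks.  All hits are
   fused into one ranking by a weighted normalization score

   $$S_i \;=\; w_S\,\frac{S_{\mathrm{sim},i}}{S_{\mathrm{sim},\max}}
         \;+\; w_M\,\frac{M_i}{M_{\max}}
         \;+\; w_R\,\frac{R_i}{R_{\max}}$$

   where $S_{\mathrm{sim},i}$ is chunk *i*'s best similarity over the
   strategies that hit it, $M_i$ the number of distinct strategies that hit
   it, and $R_i$ the number of retrieved chunks from the same document, with
   weights $(w_S, w_M, w_R) = (5, 3, 1)$.

3. **Progressive selection.** Candidates are examined in fused-score order;
   a relevance judge accepts chunks until 5 are found (if fewer exist, just
   those are kept; if none, the top 5 by score are used regardless).  A draft
   answer is generated, then each selected chunk receives a 0–100 support
   score for that draft.

4. **Deep thinking.** Chunks with positive support, in descending score
   order, feed the final reasoning pass, which produces the answer together
   with its full evidence trail.

The knowledge-graph workflow extracts (e₁, r, e₂) triplets per paper,
normalizes entity mentions against reference vocabularies (top-5
nearest-neighbour candidates + adjudication), merges document-level names
sequentially whenever embedding similarity strictly exceeds 0.5, and
assembles a typed multigraph in which every edge carries the id of the paper
supporting it.  Graphs export to bulk-import CSV tables and GraphML.

## Worked example

```bash
litrag fixtures --seed 7 --workspace ws   # 12-document synthetic corpus
litrag index --workspace ws               # -> 12 documents, 90 chunks
litrag ask "Which compound shows benefit in lung cancer?" --workspace ws
```

The fixture plants the fact "Velcorafin treats pulmonary carcinoma" in two
documents and phrases the question with the lay alias *lung cancer*, so only
the synonym-expanded strategies can reach the evidence.  The answer record
printed by `ask` (abridged):

```json
{
  "question": "Which compound shows benefit in lung cancer?",
  "final_answer": "Velcorafin treats pulmonary carcinoma.",
  "selection_mode": "partial",
  "evidence": [
    {"chunk_id": "D00:abstract:0", "support_score": 100, "doc_id": "D00"},
    {"chunk_id": "D00:fulltext:0", "support_score": 100, "doc_id": "D00"}
  ]
}
```

`selection_mode: partial` means the relevance check exhausted its
examination budget having accepted fewer than 5 chunks — exactly the planted
evidence.  Evaluation over the whole gold set:

```bash
litrag evaluate --workspace ws
# mean_precision 1.0, mean_recall 1.0, mean_f1 1.0, mean_answer_score 100.0
litrag ablate --mode no_integrated --workspace ws
# mean_recall 0.0  — flat top-50 embedding retrieval misses the
#                    synonym-gated documents entirely
litrag ablate --mode no_retrieval --workspace ws
# retrieval metrics n/a, mean_answer_score 20.0
```

Answer scores are a 1–5 judge grade rescaled to a percentage; retrieval
metrics treat the unique source documents of the evidence actually used as
the retrieved set.

## Scope notes

Mock backends are the shipped implementation; live embedding/LLM adapters
can be plugged in behind the same two contracts (`EmbeddingBackend`,
`LLMBackend`) without touching pipeline code.  Graph export targets
bulk-import file formats; no database server is required.  See
`docs/methods.md` for modelling assumptions, parameter defaults, and known
limitations.
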