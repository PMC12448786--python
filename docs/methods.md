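# Methods

This note records the modelling assumptions, parameter choices and numerical
conventions behind litrag, and what the deterministic test setup does and
does not establish about behaviour on real literature corpora.

## Corpus model and chunking

A corpus is a set of documents (id, title, abstract, full text, year,
keywords, citation ids) read from JSON Lines, optionally with one
markdown/plain-text file per document supplying the full text (markdown
formatting marks are stripped; no structural parsing of sections is
attempted, since nothing downstream uses section structure).

Retrieval operates at two levels. Each non-empty abstract is kept whole as a
single abstract-level chunk regardless of length, because abstract-level
retrieval ranks whole abstracts. Full texts are segmented by a recursive
character splitter: the separator hierarchy is paragraph break, line break,
sentence-ending punctuation followed by a space, single space, and finally
the empty string as a character-level fallback, so every text is splittable
and every chunk is at most `chunk_size` characters. Splits are chosen at the
coarsest separator available inside the window, which preserves sentence
integrity where possible. Where a split occurs, the next chunk restarts
exactly `overlap` characters before the previous chunk's end. Defaults are
500 characters with 100 overlap.

Chunks are exact `[char_start, char_end)` slices of their source text. This
buys three invariants that the tests enforce on random inputs: coverage (the
spans tile `[0, len)`), a bounded overlap (`char_end(i) − char_start(i+1) ≤
overlap + longest separator`), and byte-level reconstructability of the
source from the chunk store. Chunk ids are `doc:level:ordinal`, stable
across runs.

## Backend contracts and the mock implementations

Two contracts isolate everything model-dependent:

* `EmbeddingBackend` — deterministic text-to-vector mapping plus cosine
  similarity; ranking ties are always broken lexicographically by id so runs
  are reproducible.
* `LLMBackend` — pre-retrieval expansion, chunk relevance judging, draft
  answering, 0–100 support scoring, deep final generation, no-context
  answering, and 1–5 answer grading.

The shipped `MockEmbedding` hashes character 3-grams of the lower-cased,
whitespace-collapsed text into a fixed number of buckets (CRC-32, 256
dimensions by default) and length-normalizes. It is seed-free: identical
strings embed identically, and texts with disjoint (collision-free) 3-gram
sets have similarity exactly 0. It captures surface-form similarity only —
deliberately, since the synthetic corpora encode semantic links through an
explicit thesaurus rather than through learned geometry.

`MockLLM` is driven by two tables: a synonym thesaurus and a map from
question to planted fact tokens. Its rules are chosen to be hand-traceable:
keywords are thesaurus terms and capitalized words found in the question; the
virtual answer concatenates the question with all keywords and synonyms (a
typed error is raised when no key terms are found, which routes the caller
into the degraded fallback: the whole question as a single head term); a
chunk is relevant iff it contains a fact token for the question; drafting and
deep answering return the evidence sentences containing fact tokens; support
scores are the rounded percentage of draft content words present in the
chunk; and the answer judge maps content-word overlap with the gold answer
onto grades 5/4/3/2/1 at thresholds 0.8/0.6/0.4/0.2.

Live adapters (HTTP chat models, trained embedding models) can implement the
same two protocols; no pipeline code or test depends on which backend is
plugged in.

## Retrieval fusion

Five strategies contribute hits: question→abstracts, virtual
answer→abstracts, question→fulltext chunks, virtual answer→fulltext chunks
(each top-10 by cosine similarity, negative similarities clamped to 0), and
keyword matching over fulltext chunks. A keyword group matches when its head
term or any synonym occurs case-insensitively on word boundaries; the
keyword score of a chunk is the fraction of groups matched, and all
positive-scoring chunks enter the pool, capped at 50 by score to bound pool
size. Keyword matching runs at the fulltext level only — keyword hits on
abstracts contribute little beyond what the dense abstract strategies
already provide, and the recall-decomposition harness still measures the
abstract-level keyword column for reporting.

Fusion deduplicates hits by chunk and scores each candidate with the
weighted normalization formula (README). Conventions the formula leaves
open, resolved here:

* `S_sim` for a chunk hit by several strategies is the **maximum** raw score
  (the strongest signal; averaging would penalize keyword hits that also
  embed well).
* `M` and `R` are counted over the **deduplicated** candidate pool, and `R`
  counts chunks per document across both levels (abstracts are chunks here).
* A zero maximum makes its term contribute 0 rather than dividing by zero.
* Default weights (5, 3, 1); a single-candidate pool therefore scores
  exactly 9, and no score exceeds the weight sum.

## Progressive generation

The relevance check examines candidates strictly in fused-score order and
stops at 5 acceptances. The examination budget — how far down the ranking
the judge may look — is unbounded in principle; a configurable cap (default
30) bounds cost, after which the partial (1–4 found) or top-5 fallback
(0 found) rules apply. Each chunk is judged independently; previously
accepted chunks are not shown to the judge.

After drafting, chunks are scored 0–100 for support of the draft;
out-of-range backend values are clamped and logged, unparseable ones become
0. The final pass receives only chunks with score > 0, in descending score
order (all chunks in rank order if every score is 0) — dropping only
evidence flagged irrelevant or contradictory while preserving everything
else. The draft itself is not forwarded to the final pass; its only role is
to anchor support scoring.

## Knowledge graph

Entity-layer triplets are extracted from abstracts over the types {gene,
protein, drug, disease}; document-layer extraction summarizes each paper's
method, dataset and research domain over {paper, method, dataset,
research_domain}. Out-of-schema items are dropped and counted. The relation
vocabulary is configuration; the defaults (treats, inhibits, promotes,
associated_with, interacts_with, uses_method, uses_dataset, in_domain,
cites, shares_entity) are placeholders for a domain-curated list.

Entity normalization retrieves the 5 nearest vocabulary terms of the right
type by embedding similarity and lets the adjudication capability choose;
rejection of all candidates keeps the mention as canonical (logged as
out-of-vocabulary). Document-level names are merged sequentially: a name
joins the most similar existing canonical entry if cosine similarity is
**strictly greater than 0.5**, else becomes a new entry. The procedure is
order-dependent by construction, so builds process names in doc-id-sorted
order for reproducibility, and resubmitting a known name is idempotent.

Papers are graph nodes keyed by doc id. Cross-document structure comes from
citation edges (restricted to in-corpus ids, evidenced by the citing paper)
and `shares_entity` edges linking any two papers whose extracted entities
overlap, carrying the shared-entity count and evidenced by the source paper
of the edge. Nodes are unique per (canonical name, type); edges are keyed by
(relation, evidence paper), so the same assertion from two papers yields two
parallel edges while an exact duplicate is stored once. Every edge carries a
resolvable evidence id — provenance totality is an invariant, not a goal.

The average degree statistic is 2E/N (each directed edge contributes to both
endpoints), **truncated** to two decimals — the convention that reproduces
the reported value at the published corpus scale (2·290,403/94,962 = 6.1162
→ 6.11). Export writes bulk-import-style `nodes.csv` / `relationships.csv`
(`:ID`, `:LABEL`, `:START_ID`, `:END_ID`, `:TYPE` headers) plus GraphML;
re-importing the CSVs reproduces an isomorphic graph.

## Evaluation protocol

Per question: document precision, recall and F1 with the 0/0 → 0 guard,
where the *retrieved* set is defined as the unique source documents of the
chunks selected for final generation — the evidence actually used, a
precision-oriented reading that every results file records explicitly.
Answer quality is a 1–5 judge grade reported as (grade/5)·100.

Ablations: `full` (whole pipeline), `no_progressive` (answer directly from
the top-5 fused candidates), `no_integrated` (flat top-50 fulltext retrieval
by question embedding, then progressive generation), `no_retrieval`
(backend answers with no context; retrieval metrics not applicable). The
recall decomposition reports document recall per query granularity
(question, virtual answer, keyword) at abstract, fulltext and combined
levels, plus cumulative recall as granularities are added in that order —
cumulative recall is a set union and hence monotone.

## Synthetic corpora

The generator emulates the structure that makes this retrieval problem hard,
not the language of real papers. Each question hinges on a coined drug name
(the fact token) planted inside a "drug treats disease" sentence in 1–3 gold
documents; questions name the disease by a lay alias while documents use the
formal term, linked only by the thesaurus (synonym gating). Distractor
documents (one per gold-bearing document at the default ratio 0.5) densely
repeat the lay aliases and the questions' surface vocabulary but never a
fact token, and each focuses on a single question's alias. Document lengths
deliberately straddle the 500-character boundary so single-chunk and
multi-chunk paths are both exercised; the default world is 12 documents and
4 questions.

This construction makes two outcomes structural rather than statistical:
surface-similarity retrieval ranks distractor chunks above gold chunks (so
the flat-retrieval ablation misses the gold documents), while
synonym-expanded keyword matching plus fusion places the gold chunks inside
the examination budget (so the full pipeline recovers every gold document).
Passing these tests demonstrates that the machinery implements its contracts
exactly; it does not estimate performance on real corpora, where embedding
quality, judge reliability and terminology drift dominate and no planted
token separates evidence from noise.

## Numerical conventions and edge cases

Cosine similarity of any zero-norm vector is defined as 0; dimension
mismatches are hard errors. All rankings break ties lexicographically by id.
Similarities are clamped to [0, 1] on entry to fusion so all score terms are
non-negative. Empty questions, empty candidate pools at generation time, and
duplicate document or chunk ids are hard errors; empty strategy hit lists
and empty vocabularies degrade with warnings. Problem sizes in the test
suite and acceptance script (500 random pools of ≤ 20 candidates, 200 random
texts of ≤ 5,000 characters, 12-document corpora) are chosen so the entire
suite runs in seconds while every code path is exercised.

## Known limitations

* The mock embedding measures character-3-gram overlap; it has no notion of
  meaning, so semantic phenomena beyond the explicit thesaurus are invisible.
* The mock relevance judge is an oracle over planted facts; real judges are
  noisy, and the partial/fallback selection rules have different failure
  modes under noise.
* Document-level merging is order-dependent; a different processing order
  can yield a different (valid) registry.
* The default relation vocabulary is a placeholder; serious graph builds
  should supply a curated list.
* Keyword matching is exact on word boundaries — no stemming, no spelling
  correction, no ontology expansion.
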