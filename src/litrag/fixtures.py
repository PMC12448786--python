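"""Self-contained synthetic test worlds: a toy literature corpus with planted
entities and facts, a synonym thesaurus, reference vocabularies, and gold QA
records.

Every fixture question hinges on one *fact token* — a coined drug name that
appears only in that question's gold documents, inside a planted fact sentence
("<drug> treats <disease>").  The questions are deliberately *synonym-gated*:
they name each disease by a lay alias ("lung cancer") while the documents use
the formal term ("pulmonary carcinoma"), and only the thesaurus links the two.
Distractor documents densely repeat the lay aliases and the questions' surface
vocabulary but never a fact token, so retrieval driven purely by surface
similarity ranks them first, whereas synonym-expanded keyword matching reaches
the gold documents.  No real biomedical claim is asserted: drugs and genes are
coined names, and every sentence is template-generated.

Generation is fully deterministic: the same seed reproduces the manifest and
every emitted file byte-for-byte.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .backends import MockEmbedding, MockLLM
from .corpus import CorpusIndex, Document
from .evaluation import GoldQARecord
from .kg import MockExtractor

__all__ = ["FixtureManifest", "generate_corpus", "build_mocks", "manifest_index"]


# Fixed token pools.  Drug and gene names are coined; disease pairs map the
# lay alias used in questions to the formal term used in documents.
DRUGS = (
    "Velcorafin", "Dorametrix", "Xanthrozil", "Belunatam", "Quorvastin",
    "Miralexib", "Tavoricin", "Zephrenol", "Orvustane", "Peltrazine",
)
GENES = (
    "TQK5A", "RBX9L", "MAF7D", "PLD3K", "VNT2B",
    "KSM8E", "JRP4C", "WDF6H", "GLT1N", "HZQ9F",
)
DISEASE_PAIRS = (
    ("lung cancer", "pulmonary carcinoma"),
    ("breast cancer", "mammary neoplasm"),
    ("bowel cancer", "colorectal adenocarcinoma"),
    ("kidney failure", "renal insufficiency"),
    ("heart attack", "myocardial infarction"),
    ("liver scarring", "hepatic fibrosis"),
    ("bone thinning", "skeletal fragility"),
    ("high blood pressure", "essential hypertension"),
)
METHODS = ("single-cell profiling", "longitudinal cohort analysis",
           "randomized trial design", "network meta-analysis")
DATASETS = ("Registry-Aurora", "BioBank-Meridian", "Cohort-Tessellate")
DOMAINS = ("oncology", "nephrology", "cardiology")

#: Gold filler vocabulary deliberately avoids the question-template words
#: (compound, benefit) and the lay aliases, so gold chunks stay dissimilar to
#: the raw question under surface embedding.
_GOLD_FILLER = (
    "Dose escalation of the study agent was tolerated across the {disease} cohort.",
    "Histology confirmed {disease} in all enrolled cases.",
    "Expression of {gene} tracked progression of {disease} over follow-up.",
    "Pharmacokinetic profiles of the study agent remained stable throughout therapy.",
    "Tissue samples from {disease} cases underwent standardized staining.",
    "Longitudinal imaging quantified {disease} burden at twelve weeks.",
)

#: Distractor sentences repeat the lay aliases and the question-template
#: surface words but never a fact token.
_DISTRACTOR_FILLER = (
    "Screening for {alias} shows benefit in population health programs.",
    "Public awareness of {alias} remains a priority, and {alias} outcomes vary.",
    "Which compound class merits study in {alias} is widely debated.",
    "Registry audits of {alias} care pathways show benefit for early referral.",
    "Commentaries on {alias} emphasize compound screening initiatives.",
)


@dataclass
class FixtureManifest:
    """Complete description of one generated test world."""

    seed: int
    documents: list[dict] = field(default_factory=list)
    thesaurus: dict[str, list[str]] = field(default_factory=dict)
    vocabularies: dict[str, list[str]] = field(default_factory=dict)
    gold_qa: list[dict] = field(default_factory=list)
    planted_triplets: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "documents": self.documents,
                "thesaurus": self.thesaurus,
                "vocabularies": self.vocabularies,
                "gold_qa": self.gold_qa,
                "planted_triplets": self.planted_triplets,
            },
            indent=2,
            sort_keys=True,
        )

    def gold_records(self) -> list[GoldQARecord]:
        return [
            GoldQARecord(
                question=q["question"],
                gold_answer=q["gold_answer"],
                gold_doc_ids=frozenset(q["gold_doc_ids"]),
                question_type=q.get("question_type", ""),
            )
            for q in self.gold_qa
        ]


def _gold_paragraph(
    rng: random.Random, drug: str, disease: str, gene: str, with_fact: bool
) -> str:
    sentences = []
    if with_fact:
        sentences.append(f"{drug} treats {disease}.")
    while sum(len(s) + 1 for s in sentences) < 380:
        template = rng.choice(_GOLD_FILLER)
        sentences.append(template.format(drug=drug, disease=disease, gene=gene))
    return " ".join(sentences)


def _distractor_paragraph(rng: random.Random, aliases: list[str]) -> str:
    sentences = []
    while sum(len(s) + 1 for s in sentences) < 340:
        template = rng.choice(_DISTRACTOR_FILLER)
        sentences.append(template.format(alias=rng.choice(aliases)))
    return " ".join(sentences)


def generate_corpus(
    seed: int,
    n_docs: int = 12,
    n_questions: int = 4,
    distractor_ratio: float = 0.5,
    out_dir: str | Path | None = None,
) -> FixtureManifest:
    """Generate a fixture corpus with planted facts and gold QA records.

    ``distractor_ratio`` is the number of distractor documents per
    fact-bearing document; with ratio 0 every document carries a planted
    fact.  Each question's fact is planted in 1-3 documents, recorded in the
    manifest as that question's ``gold_doc_ids``.  When ``out_dir`` is given,
    the corpus (JSON Lines + markdown), thesaurus, vocabulary TSVs, gold QA
    records and the manifest itself are written there.
    """
    if n_questions < 1 or n_docs < n_questions:
        raise ValueError("require n_docs >= n_questions >= 1")
    if distractor_ratio < 0:
        raise ValueError("distractor_ratio must be non-negative")
    if n_questions > len(DISEASE_PAIRS):
        raise ValueError(f"at most {len(DISEASE_PAIRS)} questions supported")
    n_gold = round(n_docs / (1 + distractor_ratio))
    n_distractors = n_docs - n_gold
    if not n_questions <= n_gold <= 3 * n_questions:
        raise ValueError(
            f"inconsistent sizes: {n_gold} fact-bearing documents cannot host "
            f"{n_questions} questions at 1-3 documents each"
        )

    rng = random.Random(seed)
    # assign 1-3 gold documents per question
    per_question = [1] * n_questions
    for _ in range(n_gold - n_questions):
        eligible = [i for i in range(n_questions) if per_question[i] < 3]
        per_question[rng.choice(eligible)] += 1

    manifest = FixtureManifest(seed=seed)
    aliases = [alias for alias, _ in DISEASE_PAIRS[:n_questions]]
    used_genes: list[str] = []

    doc_counter = 0
    for qi in range(n_questions):
        alias, disease = DISEASE_PAIRS[qi]
        drug = DRUGS[qi]
        gene = GENES[qi]
        used_genes.append(gene)
        manifest.thesaurus[alias] = [disease]
        gold_doc_ids = []
        for j in range(per_question[qi]):
            doc_id = f"D{doc_counter:02d}"
            doc_counter += 1
            gold_doc_ids.append(doc_id)
            # first gold document of the first question stays below one chunk
            short = qi == 0 and j == 0
            n_paragraphs = 1 if short else 4
            fact_at = 0 if short else rng.randrange(n_paragraphs)
            paragraphs = [
                _gold_paragraph(rng, drug, disease, gene, with_fact=(p == fact_at))
                for p in range(n_paragraphs)
            ]
            if short:
                paragraphs = [paragraphs[0][:420]]
            abstract = (
                f"{drug} treats {disease}. "
                f"{gene} is associated with {disease}. "
                f"Follow-up confirmed durable responses across the {disease} cohort."
            )
            info = {
                "method": rng.choice(METHODS),
                "dataset": rng.choice(DATASETS),
                "domain": rng.choice(DOMAINS),
            }
            manifest.documents.append(
                {
                    "doc_id": doc_id,
                    "title": f"Evaluation of {drug} in {disease}",
                    "abstract": abstract,
                    "full_text": "\n\n".join(paragraphs),
                    "year": 2015 + rng.randrange(10),
                    "keywords": [disease, drug],
                    "cited_doc_ids": [],
                    "fact_tokens": [drug],
                    "question_index": qi,
                    "info": info,
                }
            )
            manifest.planted_triplets.extend(
                [
                    {"e1": drug, "e1_type": "drug", "r": "treats",
                     "e2": disease, "e2_type": "disease", "evidence_source": doc_id},
                    {"e1": gene, "e1_type": "gene", "r": "associated_with",
                     "e2": disease, "e2_type": "disease", "evidence_source": doc_id},
                ]
            )
        manifest.gold_qa.append(
            {
                "question": f"Which compound shows benefit in {alias}?",
                "gold_answer": f"{drug} treats {disease}.",
                "gold_doc_ids": sorted(gold_doc_ids),
                "question_type": "factual",
                "fact_tokens": [drug],
            }
        )

    for d in range(n_distractors):
        doc_id = f"X{d:02d}"
        # each distractor focuses on one question's alias; all of them reuse
        # the question-template surface vocabulary
        focus = [aliases[d % len(aliases)]]
        paragraphs = [_distractor_paragraph(rng, focus) for _ in range(9)]
        info = {
            "method": rng.choice(METHODS),
            "dataset": rng.choice(DATASETS),
            "domain": rng.choice(DOMAINS),
        }
        manifest.documents.append(
            {
                "doc_id": doc_id,
                "title": f"Perspectives on screening priorities {d}",
                "abstract": _distractor_paragraph(rng, focus)[:300],
                "full_text": "\n\n".join(paragraphs),
                "year": 2015 + rng.randrange(10),
                "keywords": aliases,
                "cited_doc_ids": [],
                "fact_tokens": [],
                "question_index": None,
                "info": info,
            }
        )

    # citations: each later gold document cites the first document of its question
    by_question: dict[int, list[str]] = {}
    for doc in manifest.documents:
        if doc["question_index"] is not None:
            by_question.setdefault(doc["question_index"], []).append(doc["doc_id"])
    for docs in by_question.values():
        for doc_id in docs[1:]:
            for doc in manifest.documents:
                if doc["doc_id"] == doc_id:
                    doc["cited_doc_ids"] = [docs[0]]

    manifest.vocabularies = {
        "disease": sorted({d for _, d in DISEASE_PAIRS[:n_questions]}),
        "drug": sorted(DRUGS[:n_questions]),
        "gene": sorted(used_genes),
    }

    if out_dir is not None:
        _write_fixture(manifest, Path(out_dir))
    return manifest


def _write_fixture(manifest: FixtureManifest, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    texts_dir = out_dir / "texts"
    texts_dir.mkdir(exist_ok=True)
    with (out_dir / "corpus.jsonl").open("w", encoding="utf-8") as fh:
        for doc in manifest.documents:
            record = {
                k: doc[k]
                for k in ("doc_id", "title", "abstract", "year", "keywords", "cited_doc_ids")
            }
            record["full_text"] = ""
            fh.write(json.dumps(record, sort_keys=True) + "\n")
            (texts_dir / f"{doc['doc_id']}.md").write_text(
                doc["full_text"], encoding="utf-8"
            )
    with (out_dir / "gold_qa.jsonl").open("w", encoding="utf-8") as fh:
        for q in manifest.gold_qa:
            fh.write(json.dumps(q, sort_keys=True) + "\n")
    (out_dir / "thesaurus.json").write_text(
        json.dumps(manifest.thesaurus, indent=2, sort_keys=True), encoding="utf-8"
    )
    with (out_dir / "vocabulary.tsv").open("w", encoding="utf-8") as fh:
        sources = {"disease": "mesh", "drug": "mesh", "gene": "uniprot"}
        for etype in sorted(manifest.vocabularies):
            for term in manifest.vocabularies[etype]:
                fh.write(f"{term}\t{etype}\t{sources[etype]}\n")
    (out_dir / "manifest.json").write_text(manifest.to_json(), encoding="utf-8")


def manifest_index(manifest: FixtureManifest) -> CorpusIndex:
    """Build an (unchunked) corpus index directly from a manifest."""
    index = CorpusIndex()
    for doc in manifest.documents:
        index.add_document(
            Document(
                doc_id=doc["doc_id"],
                title=doc["title"],
                abstract=doc["abstract"],
                full_text=doc["full_text"],
                year=doc["year"],
                keywords=tuple(doc["keywords"]),
                cited_doc_ids=tuple(doc["cited_doc_ids"]),
            )
        )
    return index


def build_mocks(
    manifest: FixtureManifest, dimension: int = 256
) -> tuple[MockEmbedding, MockLLM, MockExtractor]:
    """Wire the deterministic mock backends to a fixture manifest."""
    emb = MockEmbedding(dimension=dimension)
    question_facts = {
        MockLLM._norm_question(q["question"]): list(q["fact_tokens"])
        for q in manifest.gold_qa
    }
    llm = MockLLM(thesaurus=dict(manifest.thesaurus), question_facts=question_facts)
    lexicon: dict[str, str] = {}
    for etype, terms in manifest.vocabularies.items():
        for term in terms:
            lexicon[term] = etype
    extractor = MockExtractor(
        entity_lexicon=lexicon,
        doc_info={d["doc_id"]: d["info"] for d in manifest.documents},
        thesaurus=dict(manifest.thesaurus),
    )
    return emb, llm, extractor
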