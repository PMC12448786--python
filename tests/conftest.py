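"""Shared fixtures: the seed-7 synthetic corpus with its wired mock backends."""

import pytest

import litrag as lr
from litrag.retrieval import CorpusVectors


@pytest.fixture(scope="session")
def manifest7():
    return lr.generate_corpus(seed=7, n_docs=12, n_questions=4, distractor_ratio=0.5)


@pytest.fixture(scope="session")
def index7(manifest7):
    return lr.chunk_corpus(lr.manifest_index(manifest7))


@pytest.fixture(scope="session")
def mocks7(manifest7):
    return lr.build_mocks(manifest7)


@pytest.fixture(scope="session")
def emb7(mocks7):
    return mocks7[0]


@pytest.fixture(scope="session")
def llm7(mocks7):
    return mocks7[1]


@pytest.fixture(scope="session")
def extractor7(mocks7):
    return mocks7[2]


@pytest.fixture(scope="session")
def vectors7(index7, emb7):
    return CorpusVectors(index7, emb7)


@pytest.fixture(scope="session")
def gold7(manifest7):
    return manifest7.gold_records()
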