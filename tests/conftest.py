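import numpy as np
import pytest

from needsminer.corpus import Corpus, QueryDoc, ReferenceDoc, Taxonomy


@pytest.fixture
def toy_taxonomy() -> Taxonomy:
    return Taxonomy(
        {
            "1": "outpatient",
            "2": "tests",
            "3": "treatment",
            "11": "symptoms and side effects",
            "16": "suspicion of cancer",
            "1.1.1.1": "difficulty selecting a hospital",
            "2.2.2.1": "worried about test results",
            "3.1.1.1": "uncertainty about treatment options",
            "11.1.2.3": "persistent side effects of drugs",
            "16.3.1.1": "worrying about cancer with subjective symptoms",
        }
    )


@pytest.fixture
def toy_d_corpus(toy_taxonomy) -> Corpus:
    docs = (
        ReferenceDoc("d0", "hospital doctor selection information", ("1.1.1.1",), "description"),
        ReferenceDoc("d1", "test results worry waiting", ("2.2.2.1",), "description"),
        ReferenceDoc("d2", "treatment options surgery choice", ("3.1.1.1",), "description"),
        ReferenceDoc("d3", "side effects drug numbness persistent", ("11.1.2.3",), "description"),
        ReferenceDoc("d4", "lump symptoms worried cancer", ("16.3.1.1",), "description"),
    )
    return Corpus(docs=docs, taxonomy=toy_taxonomy, mode="D")


@pytest.fixture
def toy_e_corpus(toy_taxonomy) -> Corpus:
    docs = (
        ReferenceDoc("e0", "which hospital should i pick doctor", ("1.1.1.1",), "example"),
        ReferenceDoc("e1", "scared waiting for my test results", ("2.2.2.1", "16.3.1.1"), "example"),
        ReferenceDoc("e2", "should i have surgery or radiation treatment", ("3.1.1.1",), "example"),
        ReferenceDoc("e3", "my hands feel numb after the drug", ("11.1.2.3",), "example"),
        ReferenceDoc("e4", "i found a lump and i am worried", ("16.3.1.1",), "example"),
        ReferenceDoc("e5", "lump worried doctor test", ("16.3.1.1", "2.2.2.1", "1.1.1.1"), "example"),
    )
    return Corpus(docs=docs, taxonomy=toy_taxonomy, mode="E")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_text_corpus(rng, n_docs, vocab_size=30, max_len=12):
    """Random word-soup corpus for oracle-equivalence tests."""
    vocab = [f"t{i}" for i in range(vocab_size)]
    docs = []
    for i in range(n_docs):
        length = int(rng.integers(1, max_len + 1))
        words = rng.choice(vocab, size=length)
        docs.append(" ".join(words))
    return docs
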