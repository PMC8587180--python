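"""Tokenization contract and from-scratch TF-IDF vectorization.

The weighting convention is the widely used smoothed-IDF, L2-normalized
bag of words:

    tf(t, d)  = raw count of term t in document d
    idf(t)    = ln((1 + N) / (1 + df(t))) + 1
    w(t, d)   = tf(t, d) * idf(t),   then the vector is L2-normalized.

N is the number of fitting documents and df(t) the number of fitting
documents containing t.  The "+1" terms smooth the ratio as if one extra
document contained every term, so idf(t) == 1 exactly when t occurs in
every document, and no term is ever weighted zero.  A document containing
no in-vocabulary token maps to the zero vector.

Tokenizers are pluggable.  The default is a language-agnostic content
filter: lowercase, split on non-word characters, drop tokens made purely
of digits.  Morphological analyzers (e.g. a Japanese part-of-speech
tagger) can be registered through :func:`pos_filter_tokenizer`, which
keeps only content-word classes (nouns, verbs, adjectives) -- the
contract under which the method was designed, without bundling any
dictionary.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Protocol, Sequence

import numpy as np
from scipy import sparse

from .corpus import Corpus, QueryDoc, ReferenceDoc
from .errors import ValidationError

__all__ = [
    "Tokenizer",
    "RegexTokenizer",
    "pos_filter_tokenizer",
    "get_tokenizer",
    "register_tokenizer",
    "Vocabulary",
    "IdfModel",
    "fit",
    "transform",
    "transform_corpus",
    "save_model",
    "load_model",
]


class Tokenizer(Protocol):
    """Deterministic text -> ordered token list."""

    name: str

    def tokenize(self, text: str) -> list[str]: ...


_WORD_RE = re.compile(r"\w+", re.UNICODE)
_NONCONTENT_RE = re.compile(r"^[\d_]+$")


@dataclass(frozen=True)
class RegexTokenizer:
    """Default tokenizer: lowercase, split on non-word characters, and drop
    tokens consisting purely of digits or underscores (symbols and numbers
    carry no topical content)."""

    name: str = "regex"

    def tokenize(self, text: str) -> list[str]:
        return [
            t
            for t in _WORD_RE.findall(text.lower())
            if not _NONCONTENT_RE.match(t)
        ]


CONTENT_POS = frozenset({"noun", "verb", "adjective"})


@dataclass(frozen=True)
class PosFilterTokenizer:
    """Adapter for morphological analyzers.

    ``analyze`` returns (surface, pos) pairs; only content-word classes
    (``CONTENT_POS``) are kept.  Casing is the analyzer's business --
    unlike the default tokenizer, no lowercasing is applied here.
    """

    name: str
    analyze: Callable[[str], Iterable[tuple[str, str]]]

    def tokenize(self, text: str) -> list[str]:
        return [tok for tok, pos in self.analyze(text) if pos in CONTENT_POS]


def pos_filter_tokenizer(
    name: str, analyze: Callable[[str], Iterable[tuple[str, str]]]
) -> PosFilterTokenizer:
    """Wrap a part-of-speech analyzer into the tokenizer contract and
    register it under ``name``."""
    tok = PosFilterTokenizer(name=name, analyze=analyze)
    register_tokenizer(tok)
    return tok


_REGISTRY: dict[str, Tokenizer] = {}


def register_tokenizer(tok: Tokenizer) -> None:
    _REGISTRY[tok.name] = tok


def get_tokenizer(name: str = "regex") -> Tokenizer:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ValidationError(
            f"unknown tokenizer {name!r}; registered: {sorted(_REGISTRY)}"
        ) from None


register_tokenizer(RegexTokenizer())


# ---------------------------------------------------------------------------
# fitted model


@dataclass(frozen=True)
class Vocabulary:
    """Term -> column map plus the document frequencies it was fitted on.

    Indices are 0-based, contiguous, and assigned in lexicographic term
    order so that refitting the same corpus is bit-reproducible.
    """

    index: dict[str, int]
    df: np.ndarray  # document frequency per column
    n_docs: int

    def __len__(self) -> int:
        return len(self.index)

    @property
    def terms(self) -> list[str]:
        out = [""] * len(self.index)
        for t, i in self.index.items():
            out[i] = t
        return out


@dataclass(frozen=True)
class IdfModel:
    """Smoothed inverse document frequencies aligned with a Vocabulary."""

    idf: np.ndarray

    @staticmethod
    def from_df(df: np.ndarray, n_docs: int) -> "IdfModel":
        idf = np.log((1.0 + n_docs) / (1.0 + df)) + 1.0
        return IdfModel(idf=idf)


def _doc_tokens(doc: ReferenceDoc | QueryDoc, tokenizer: Tokenizer) -> list[str]:
    return tokenizer.tokenize(doc.text)


def fit(
    corpus: Corpus, tokenizer: Tokenizer | None = None
) -> tuple[Vocabulary, IdfModel]:
    """Fit vocabulary and IDF statistics on a reference corpus.

    The vocabulary covers exactly the terms appearing in at least one
    fitting document; no frequency pruning is applied.  Raises if the
    corpus is empty or no document yields any token.
    """
    tokenizer = tokenizer or get_tokenizer()
    if len(corpus) == 0:
        raise ValidationError("cannot fit on an empty corpus")
    doc_term_sets = []
    terms: set[str] = set()
    for doc in corpus:
        toks = set(_doc_tokens(doc, tokenizer))
        doc_term_sets.append(toks)
        terms |= toks
    if not terms:
        raise ValidationError("every document tokenized to nothing; cannot fit")
    index = {t: i for i, t in enumerate(sorted(terms))}
    df = np.zeros(len(index), dtype=np.int64)
    for toks in doc_term_sets:
        for t in toks:
            df[index[t]] += 1
    vocab = Vocabulary(index=index, df=df, n_docs=len(corpus))
    return vocab, IdfModel.from_df(df, len(corpus))


def transform(
    text: str,
    vocab: Vocabulary,
    idf: IdfModel,
    tokenizer: Tokenizer | None = None,
) -> sparse.csr_matrix:
    """TF-IDF vector (1 x |V| CSR row) of a text under a fitted model.

    Out-of-vocabulary tokens are ignored; the result is L2-normalized
    unless it is the zero vector (empty or fully out-of-vocabulary text).
    """
    tokenizer = tokenizer or get_tokenizer()
    cols: dict[int, float] = {}
    for tok in tokenizer.tokenize(text):
        j = vocab.index.get(tok)
        if j is not None:
            cols[j] = cols.get(j, 0.0) + 1.0
    if not cols:
        return sparse.csr_matrix((1, len(vocab)))
    js = np.fromiter(cols.keys(), dtype=np.int64)
    tfs = np.fromiter(cols.values(), dtype=np.float64)
    w = tfs * idf.idf[js]
    w /= math.sqrt(float(np.dot(w, w)))
    order = np.argsort(js)
    return sparse.csr_matrix(
        (w[order], js[order], np.array([0, len(js)])), shape=(1, len(vocab))
    )


def transform_corpus(
    corpus: Corpus,
    vocab: Vocabulary,
    idf: IdfModel,
    tokenizer: Tokenizer | None = None,
) -> sparse.csr_matrix:
    """Stack the TF-IDF vectors of every document (|corpus| x |V| CSR)."""
    rows = [transform(d.text, vocab, idf, tokenizer) for d in corpus]
    if not rows:
        return sparse.csr_matrix((0, len(vocab)))
    return sparse.vstack(rows, format="csr")


# ---------------------------------------------------------------------------
# serialization -- JSON so fitted models diff cleanly under version control


def save_model(vocab: Vocabulary, idf: IdfModel, path: str | Path) -> None:
    terms = vocab.terms
    payload = {
        "N": vocab.n_docs,
        "terms": [
            [t, int(vocab.df[i]), float(idf.idf[i])] for i, t in enumerate(terms)
        ],
    }
    Path(path).write_text(
        json.dumps(payload, ensure_ascii=False, indent=0), encoding="utf-8"
    )


def load_model(path: str | Path) -> tuple[Vocabulary, IdfModel]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    terms = payload["terms"]
    index = {row[0]: i for i, row in enumerate(terms)}
    df = np.array([row[1] for row in terms], dtype=np.int64)
    idf = np.array([row[2] for row in terms], dtype=np.float64)
    return Vocabulary(index=index, df=df, n_docs=payload["N"]), IdfModel(idf=idf)
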