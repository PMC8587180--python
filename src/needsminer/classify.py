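"""Cosine-similarity ranking of query vectors against a reference index.

A query is classified by computing the cosine between its TF-IDF vector
and every reference document vector, then scoring each category by the
MAX cosine over the reference documents that carry its label, and
returning the top-k categories.  Max aggregation keeps the "most relevant
single reference text" reading even when a category is represented by
several texts or a reference example carries multiple labels; mean
aggregation is available for sensitivity checks.

All vectors are unit-norm (or zero), so the dot product IS the cosine,
and scores lie in [0, 1] for the nonnegative TF-IDF weights used here.
Queries that vectorize to the zero vector (empty, or sharing no term with
the fitted vocabulary) yield an empty ranking rather than an arbitrary
assignment.

Determinism: score ties are broken by ascending category code (numeric
segment order), so permuting the reference corpus never changes a
ranking.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import sparse

from .corpus import Corpus, QueryDoc, ReferenceDoc, code_sort_key
from .errors import ValidationError
from .vectorize import IdfModel, Tokenizer, Vocabulary, fit, transform, transform_corpus

__all__ = [
    "ReferenceIndex",
    "RankedPrediction",
    "build_index",
    "cosine",
    "rank_categories",
    "classify_corpus",
    "write_predictions",
]

log = logging.getLogger(__name__)

Aggregation = Literal["max", "mean"]


@dataclass(frozen=True)
class RankedPrediction:
    """Ordered (category code, cosine score) list for one query.

    Scores are non-increasing; each category appears at most once.  An
    empty ranking marks a query that could not be scored (zero vector).
    """

    query_id: str
    ranking: tuple[tuple[str, float], ...]

    @property
    def top1(self) -> tuple[str, float] | None:
        return self.ranking[0] if self.ranking else None

    def codes(self, k: int | None = None) -> tuple[str, ...]:
        r = self.ranking if k is None else self.ranking[:k]
        return tuple(code for code, _ in r)


@dataclass(frozen=True)
class ReferenceIndex:
    """Reference corpus vectorized under its own fitted TF-IDF model.

    Rows of ``matrix`` align with ``labels``/``sources``; the fitted
    vocabulary and IDF are kept so queries are transformed consistently.
    """

    mode: Literal["D", "E", "DplusE"]
    matrix: sparse.csr_matrix
    labels: tuple[tuple[str, ...], ...]
    sources: tuple[str, ...]
    vocab: Vocabulary
    idf: IdfModel
    tokenizer: Tokenizer | None = None

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != len(self.labels):
            raise ValidationError("index matrix rows must align with label metadata")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def category_codes(self) -> tuple[str, ...]:
        seen = {c for labels in self.labels for c in labels}
        return tuple(sorted(seen, key=code_sort_key))


def build_index(
    reference: Corpus,
    tokenizer: Tokenizer | None = None,
    vocab: Vocabulary | None = None,
    idf: IdfModel | None = None,
) -> ReferenceIndex:
    """Fit (or reuse) a TF-IDF model on the reference corpus and vectorize it.

    By default the IDF statistics come from the reference corpus alone, so
    the resulting classifier can score streaming queries without refitting.
    Pass a pre-fitted ``vocab``/``idf`` (e.g. fitted on reference+queries)
    for sensitivity analyses.
    """
    if reference.mode not in ("D", "E", "DplusE"):
        raise ValidationError(f"cannot index a corpus with mode {reference.mode!r}")
    if (vocab is None) != (idf is None):
        raise ValidationError("vocab and idf must be provided together")
    if vocab is None:
        vocab, idf = fit(reference, tokenizer)
    matrix = transform_corpus(reference, vocab, idf, tokenizer)
    labels = tuple(
        d.labels for d in reference if isinstance(d, ReferenceDoc)
    )
    sources = tuple(d.source for d in reference if isinstance(d, ReferenceDoc))
    if len(labels) != len(reference):
        raise ValidationError("reference corpus contains non-reference docs")
    return ReferenceIndex(
        mode=reference.mode,
        matrix=matrix,
        labels=labels,
        sources=sources,
        vocab=vocab,
        idf=idf,
        tokenizer=tokenizer,
    )


def cosine(u: sparse.csr_matrix, v: sparse.csr_matrix) -> float:
    """Cosine similarity of two unit-norm (or zero) sparse row vectors.

    Because the vectors are already normalized this is just the dot
    product; either vector being zero gives 0.
    """
    return float(u.multiply(v).sum())


def _category_scores(
    sims: np.ndarray,
    labels: Sequence[tuple[str, ...]],
    aggregation: Aggregation,
) -> dict[str, float]:
    # zero cosine means no shared term, i.e. no evidence of relevance:
    # such categories are left out rather than ranked by tie-break
    per_cat: dict[str, list[float]] = {}
    for s, labs in zip(sims, labels):
        if s <= 0.0:
            continue
        for c in labs:
            per_cat.setdefault(c, []).append(float(s))
    if aggregation == "max":
        return {c: max(v) for c, v in per_cat.items()}
    return {c: float(np.mean(v)) for c, v in per_cat.items()}


def rank_categories(
    query: QueryDoc,
    index: ReferenceIndex,
    k: int = 10,
    aggregation: Aggregation = "max",
) -> RankedPrediction:
    """Top-k categories for one query by aggregated cosine similarity.

    The score of a category is the max (default) or mean cosine over the
    reference documents labeled with it.  Ties break by ascending category
    code.  A zero-vector query yields an empty ranking.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if len(index) == 0:
        raise ValidationError("cannot rank against an empty index")
    qvec = transform(query.text, index.vocab, index.idf, index.tokenizer)
    if qvec.nnz == 0:
        log.info("query %s vectorized to zero; empty ranking", query.doc_id)
        return RankedPrediction(query_id=query.doc_id, ranking=())
    sims = np.asarray(index.matrix @ qvec.T.toarray()).ravel()
    scores = _category_scores(sims, index.labels, aggregation)
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], code_sort_key(kv[0])))
    return RankedPrediction(query_id=query.doc_id, ranking=tuple(ordered[:k]))


def classify_corpus(
    queries: Corpus,
    index: ReferenceIndex,
    k: int = 10,
    aggregation: Aggregation = "max",
) -> list[RankedPrediction]:
    """One :class:`RankedPrediction` per query, in input order."""
    out = []
    for doc in queries:
        if not isinstance(doc, QueryDoc):
            doc = QueryDoc(doc_id=doc.doc_id, text=doc.text)
        out.append(rank_categories(doc, index, k=k, aggregation=aggregation))
    return out


def write_predictions(
    predictions: Sequence[RankedPrediction],
    path: str | Path,
    fmt: Literal["tsv", "jsonl"] = "tsv",
) -> None:
    """TSV: ``query_id<TAB>rank<TAB>code<TAB>score`` (score to 3 decimals,
    matching human-readable convention); JSONL keeps full precision."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for p in predictions:
            if fmt == "tsv":
                for rank, (code, score) in enumerate(p.ranking, start=1):
                    fh.write(f"{p.query_id}\t{rank}\t{code}\t{score:.3f}\n")
            else:
                fh.write(
                    json.dumps(
                        {
                            "query_id": p.query_id,
                            "ranking": [[c, s] for c, s in p.ranking],
                        }
                    )
                    + "\n"
                )
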