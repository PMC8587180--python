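"""Top-k accuracy, cross-validation, and distribution comparison.

The hit rule is multi-label: a prediction counts as correct if at least
one of the query's (up to 3) gold categories appears among the top-k
predicted categories.  Acc@k is the fraction of labeled queries with a
hit; queries with an empty gold set are excluded from the denominator
(they have no correct answer by construction).

The example-based and combined classifiers are scored by k-fold
cross-validation (default 5 folds): the labeled corpus is shuffled with
an explicit seed, split into near-equal folds, a fresh index is fitted on
the training folds (plus the full description corpus for the combined
method), and Acc@1/Acc@10 are measured on the held-out fold.  Per-fold
values are aggregated as mean, median, and unbiased sample SD (n-1
denominator).  The description-based classifier needs no CV -- its
reference corpus is fixed -- so it is scored by a single pass.

Category distributions from two labelings (e.g. automatic vs manual) are
compared with the Jensen-Shannon divergence after zero-extension onto the
union support:

    JSD(p, q) = 1/2 KL(p || m) + 1/2 KL(q || m),   m = (p + q) / 2

with 0*log(0/x) = 0.  JSD is symmetric, zero iff p == q, and bounded by
log 2 in the chosen base (natural log by default).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .classify import (
    Aggregation,
    RankedPrediction,
    ReferenceIndex,
    build_index,
    classify_corpus,
    rank_categories,
)
from .corpus import Corpus, QueryDoc, ReferenceDoc, code_sort_key, fuse_corpora
from .errors import ValidationError
from .vectorize import Tokenizer

__all__ = [
    "EvalReport",
    "CategoryDistribution",
    "hit_at_k",
    "accuracy_at_k",
    "cross_validate",
    "evaluate_d_based",
    "category_distribution",
    "jensen_shannon_divergence",
]


def hit_at_k(prediction: RankedPrediction, gold: Iterable[str], k: int) -> bool:
    """True iff any gold category appears among the top-k predictions."""
    gold_set = set(gold)
    if not gold_set:
        raise ValidationError(
            f"query {prediction.query_id!r} has no gold labels; filter unlabeled queries upstream"
        )
    return bool(gold_set & set(prediction.codes(k)))


def accuracy_at_k(
    queries: Corpus,
    index: ReferenceIndex,
    k: int,
    aggregation: Aggregation = "max",
) -> float:
    """Fraction of labeled queries whose gold set intersects the top-k.

    Unlabeled queries are skipped; at least one labeled query is required.
    """
    hits = 0
    n = 0
    for doc in queries:
        gold = doc.labels if isinstance(doc, ReferenceDoc) else doc.gold_labels
        if not gold:
            continue
        q = QueryDoc(doc_id=doc.doc_id, text=doc.text)
        pred = rank_categories(q, index, k=k, aggregation=aggregation)
        hits += hit_at_k(pred, gold, k)
        n += 1
    if n == 0:
        raise ValidationError("no labeled queries to evaluate")
    return hits / n


@dataclass(frozen=True)
class EvalReport:
    """Per-fold and aggregate Acc@1/Acc@10 for one classification method.

    ``sd`` entries are None (omitted, not zero) when there is a single
    fold, mirroring the single-pass description-based evaluation.
    """

    method: Literal["D", "E", "DplusE"]
    folds: int
    seed: int | None
    acc1_per_fold: tuple[float, ...]
    acc10_per_fold: tuple[float, ...]

    def _agg(self, values: tuple[float, ...]) -> dict[str, float | None]:
        arr = np.asarray(values, dtype=float)
        return {
            "mean": float(arr.mean()),
            "median": float(np.median(arr)) if len(arr) > 1 else None,
            "sd": float(arr.std(ddof=1)) if len(arr) > 1 else None,
        }

    @property
    def acc1(self) -> dict[str, float | None]:
        return self._agg(self.acc1_per_fold)

    @property
    def acc10(self) -> dict[str, float | None]:
        return self._agg(self.acc10_per_fold)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "folds": self.folds,
            "seed": self.seed,
            "acc1": self.acc1,
            "acc10": self.acc10,
            "acc1_per_fold": list(self.acc1_per_fold),
            "acc10_per_fold": list(self.acc10_per_fold),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2), encoding="utf-8"
        )


def _fold_indices(n: int, folds: int, seed: int) -> list[np.ndarray]:
    """Uniform shuffle then near-equal split; every index lands in exactly
    one fold and fold sizes differ by at most 1."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return np.array_split(perm, folds)


def cross_validate(
    labeled: Corpus,
    d_corpus: Corpus | None = None,
    folds: int = 5,
    mode: Literal["E", "DplusE"] = "E",
    seed: int = 0,
    tokenizer: Tokenizer | None = None,
    aggregation: Aggregation = "max",
) -> EvalReport:
    """k-fold CV of the example-based or combined classifier.

    Per fold, the reference index is refit on the training folds -- plus
    the full description corpus when ``mode="DplusE"`` -- and Acc@1/Acc@10
    are computed on the held-out fold.  Shuffling is controlled by
    ``seed``; results are bit-reproducible.
    """
    if folds < 2:
        raise ValidationError(f"folds must be >= 2, got {folds}")
    if len(labeled) < folds:
        raise ValidationError(
            f"{len(labeled)} labeled docs cannot fill {folds} folds"
        )
    if mode == "DplusE" and d_corpus is None:
        raise ValidationError("DplusE cross-validation requires a description corpus")

    fold_idx = _fold_indices(len(labeled), folds, seed)
    acc1, acc10 = [], []
    for held_out in fold_idx:
        train_mask = np.ones(len(labeled), dtype=bool)
        train_mask[held_out] = False
        train = labeled.subset(np.flatnonzero(train_mask))
        if mode == "DplusE":
            train = fuse_corpora(d_corpus, train)
        index = build_index(train, tokenizer=tokenizer)
        val = labeled.subset(held_out)
        acc1.append(accuracy_at_k(val, index, k=1, aggregation=aggregation))
        acc10.append(accuracy_at_k(val, index, k=10, aggregation=aggregation))
    return EvalReport(
        method=mode,
        folds=folds,
        seed=seed,
        acc1_per_fold=tuple(acc1),
        acc10_per_fold=tuple(acc10),
    )


def evaluate_d_based(
    labeled: Corpus,
    d_index: ReferenceIndex,
    aggregation: Aggregation = "max",
) -> EvalReport:
    """Single-pass Acc@1/Acc@10 of labeled queries against the full
    description index (no CV, hence no SD/median)."""
    a1 = accuracy_at_k(labeled, d_index, k=1, aggregation=aggregation)
    a10 = accuracy_at_k(labeled, d_index, k=10, aggregation=aggregation)
    return EvalReport(
        method="D",
        folds=1,
        seed=None,
        acc1_per_fold=(a1,),
        acc10_per_fold=(a10,),
    )


# ---------------------------------------------------------------------------
# distribution comparison


@dataclass(frozen=True)
class CategoryDistribution:
    """Relative category frequencies over an explicit ordered support.

    The zero distribution (empty sample) is representable; nonempty
    samples sum to 1.
    """

    support: tuple[str, ...]
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if len(p) != len(self.support):
            raise ValidationError("support and probabilities must align")
        if (p < 0).any():
            raise ValidationError("probabilities must be nonnegative")
        total = p.sum()
        if total > 0 and abs(total - 1.0) > 1e-12:
            raise ValidationError(f"probabilities sum to {total}, not 1")

    @property
    def is_zero(self) -> bool:
        return float(np.asarray(self.probabilities).sum()) == 0.0

    def extend_to(self, support: Sequence[str]) -> "CategoryDistribution":
        """Zero-extend onto a larger support (order given by ``support``)."""
        missing = set(self.support) - set(support)
        if missing:
            raise ValidationError(f"target support lacks categories: {sorted(missing)}")
        pos = {c: i for i, c in enumerate(self.support)}
        p = np.zeros(len(support))
        for i, c in enumerate(support):
            if c in pos:
                p[i] = self.probabilities[pos[c]]
        return CategoryDistribution(support=tuple(support), probabilities=p)


def category_distribution(
    assignments: Sequence[str], support: Sequence[str]
) -> CategoryDistribution:
    """Relative frequencies of ``assignments`` over ``support`` (zeros for
    unobserved categories); an empty assignment list gives the zero
    distribution."""
    support = tuple(support)
    pos = {c: i for i, c in enumerate(support)}
    counts = np.zeros(len(support))
    for a in assignments:
        if a not in pos:
            raise ValidationError(f"assignment {a!r} outside the declared support")
        counts[pos[a]] += 1
    total = counts.sum()
    probs = counts / total if total > 0 else counts
    return CategoryDistribution(support=support, probabilities=probs)


def jensen_shannon_divergence(
    p: CategoryDistribution,
    q: CategoryDistribution,
    log_base: Literal["e", "2"] = "e",
) -> float:
    """Jensen-Shannon divergence between two category distributions.

    Distributions on different supports are first zero-extended onto the
    union support (sorted by code).  Returns a value in [0, log 2] (or
    [0, 1] in base 2); 0 iff the distributions coincide.
    """
    if p.is_zero or q.is_zero:
        raise ValidationError("cannot compare a zero distribution")
    union = sorted(set(p.support) | set(q.support), key=code_sort_key)
    pv = p.extend_to(union).probabilities
    qv = q.extend_to(union).probabilities
    m = 0.5 * (pv + qv)

    def kl(a: np.ndarray, b: np.ndarray) -> float:
        mask = a > 0
        return float(np.sum(a[mask] * np.log(a[mask] / b[mask])))

    jsd = 0.5 * kl(pv, m) + 0.5 * kl(qv, m)
    if log_base == "2":
        jsd /= math.log(2.0)
    # clip the tiny negative round-off that exact-equality inputs can leave
    return max(jsd, 0.0)
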