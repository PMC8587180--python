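"""Frequency tables, long-tail diagnostics, and application filters.

After classifying a large query corpus, the distribution of top-1
category assignments is itself the result of interest: which patient
needs dominate, how heavy the long tail is, and which slices of the
corpus deserve manual reading.  This module builds ranked frequency
tables and the derived diagnostics (rank-to-rank change rate, cumulative
share of the top-n categories, overlap between two top-n lists), plus the
two downstream filters:

* category-prefix extraction -- e.g. everything under the "symptoms,
  side effects, and sequelae" branch, a candidate pool for adverse-drug-
  event signals;
* raw-text keyword search -- e.g. an emergent topic word, a probe for
  needs the taxonomy does not yet cover.

Shares are computed against the number of classified queries; queries
whose ranking is empty stay in the denominator by default, so shares
reflect the full classified corpus.  Printed percentages round half-up
to one decimal place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .classify import RankedPrediction
from .corpus import Corpus, Taxonomy, code_has_prefix, code_sort_key, normalize_code
from .errors import ValidationError

__all__ = [
    "FrequencyTable",
    "frequency_table",
    "rank_change_curve",
    "cumulative_share",
    "top_overlap",
    "filter_by_category_prefix",
    "keyword_search",
    "round_pct",
]


def round_pct(x: float, digits: int = 1) -> float:
    """Percentage rounding, half-up (0.05 -> 0.1), as printed in tables."""
    factor = 10**digits
    return math.floor(x * 100 * factor + 0.5) / factor


@dataclass(frozen=True)
class FrequencyTable:
    """Ranked top-1 assignment counts per category.

    ``rows`` are (rank, code, name, count, share) with counts
    non-increasing; ``total_classified`` is the share denominator and may
    exceed the summed counts when the table is truncated to top-n or when
    some queries had empty rankings.
    """

    rows: tuple[tuple[int, str, str, int, float], ...]
    total_classified: int

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def counts(self) -> tuple[int, ...]:
        return tuple(r[3] for r in self.rows)

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(r[1] for r in self.rows)

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("rank\tcode\tname\tcount\tshare_pct\n")
            for rank, code, name, count, share in self.rows:
                fh.write(f"{rank}\t{code}\t{name}\t{count}\t{round_pct(share)}\n")


def frequency_table(
    predictions: Sequence[RankedPrediction],
    taxonomy: Taxonomy,
    top_n: int | None = None,
    count_empty_in_total: bool = True,
) -> FrequencyTable:
    """Ranked table of top-1 category assignments.

    Empty rankings contribute no counts; they stay in the denominator by
    default (``count_empty_in_total``).  Equal counts rank by ascending
    category code.
    """
    counts: dict[str, int] = {}
    n_nonempty = 0
    for p in predictions:
        if p.top1 is None:
            continue
        n_nonempty += 1
        code = p.top1[0]
        counts[code] = counts.get(code, 0) + 1
    total = len(predictions) if count_empty_in_total else n_nonempty
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], code_sort_key(kv[0])))
    if top_n is not None:
        ordered = ordered[:top_n]
    rows = tuple(
        (rank, code, taxonomy.name(code), count, count / total if total else 0.0)
        for rank, (code, count) in enumerate(ordered, start=1)
    )
    return FrequencyTable(rows=rows, total_classified=total)


def rank_change_curve(table: FrequencyTable) -> list[float]:
    """Relative drop between consecutive ranks:
    element i = (count_i - count_{i+1}) / count_i.

    A slowly decaying tail shows up as small late values; a dominant head
    as a large first value.
    """
    counts = table.counts
    if len(counts) < 2:
        raise ValidationError("rank-change curve needs at least 2 rows")
    return [(counts[i] - counts[i + 1]) / counts[i] for i in range(len(counts) - 1)]


def cumulative_share(table: FrequencyTable, n: int) -> float:
    """Share of the total classified queries captured by the top-n
    categories; ``n`` beyond the table length uses all rows."""
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    counts = table.counts[:n]
    if table.total_classified == 0:
        return 0.0
    return sum(counts) / table.total_classified


def top_overlap(a: FrequencyTable, b: FrequencyTable, n: int) -> int:
    """Number of category codes shared by the two tables' top-n lists."""
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    return len(set(a.codes[:n]) & set(b.codes[:n]))


def filter_by_category_prefix(
    predictions: Sequence[RankedPrediction],
    queries: Corpus,
    prefix: str,
) -> tuple[Corpus, int, float]:
    """Queries whose top-1 code falls under a category branch.

    ``prefix`` is a level-1..3 code ("11", "3.2", ...); matching respects
    segment boundaries.  Returns the matching sub-corpus, its size, and
    its share of all classified queries.
    """
    prefix = normalize_code(prefix)
    by_id = {p.query_id: p for p in predictions}
    keep = []
    for i, doc in enumerate(queries):
        p = by_id.get(doc.doc_id)
        if p is None or p.top1 is None:
            continue
        if code_has_prefix(p.top1[0], prefix):
            keep.append(i)
    subset = queries.subset(keep)
    total = len(predictions)
    share = len(keep) / total if total else 0.0
    return subset, len(keep), share


def keyword_search(
    queries: Corpus, term: str, case_sensitive: bool = False
) -> Corpus:
    """Substring search on raw question text (pre-tokenization), preserving
    corpus order.  Probes for emergent topics the taxonomy may not cover."""
    if not term:
        raise ValidationError("search term must be nonempty")
    needle = term if case_sensitive else term.lower()
    keep = []
    for i, doc in enumerate(queries):
        hay = doc.text if case_sensitive else doc.text.lower()
        if needle in hay:
            keep.append(i)
    return queries.subset(keep)
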