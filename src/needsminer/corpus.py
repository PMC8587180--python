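"""Domain types and file I/O for taxonomies and question corpora.

The label space is a 4-level hierarchical taxonomy of patient-needs
categories.  Codes are dotted strings of 1-4 positive integers
("16.3.1.1"); the number of segments is the level, and the first segment
identifies the top-level branch (used by prefix filters such as the
"symptoms, side effects, and sequelae" branch, code 11).  Source material
often prints codes with a trailing dot ("16.3.1.1."); the canonical
internal form strips it, and writers can restore it on request.

Two flavors of labeled reference text exist:

* *description* entries -- one curated worry text per category (the
  D corpus), carrying exactly one label;
* *example* entries -- real question texts annotated with 1-3 category
  labels (the E corpus).

Their concatenation is the D+E corpus.  Query corpora hold unlabeled (or
gold-labeled, for evaluation) question texts; an empty gold set marks a
question with no corresponding category in the taxonomy.

File formats (UTF-8):

* taxonomy TSV: ``code<TAB>name``, no header by default;
* corpus TSV: ``doc_id<TAB>labels<TAB>text`` with ";"-separated labels
  (may be empty for queries);
* corpus JSONL: one object per line with keys ``doc_id``, ``labels``
  (list), ``text`` and optionally ``source``.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence, Union

from .errors import ParseError, ValidationError

__all__ = [
    "normalize_code",
    "code_level",
    "code_sort_key",
    "code_has_prefix",
    "Taxonomy",
    "ReferenceDoc",
    "QueryDoc",
    "Corpus",
    "read_taxonomy",
    "write_taxonomy",
    "read_corpus",
    "write_corpus",
    "fuse_corpora",
]

_CODE_RE = re.compile(r"^\d+(\.\d+){0,3}$")

Mode = Literal["D", "E", "DplusE", "query"]
MAX_LABELS = 3  # annotation cap: up to 3 categories per question


def normalize_code(code: str) -> str:
    """Normalize a category code: strip whitespace and a trailing dot.

    Raises :class:`ValidationError` if the result is not 1-4 dot-separated
    positive integers.
    """
    c = code.strip()
    if c.endswith("."):
        c = c[:-1]
    if not _CODE_RE.match(c):
        raise ValidationError(f"malformed category code: {code!r}")
    return c


def code_level(code: str) -> int:
    """Hierarchy level of a normalized code (1-4): its segment count."""
    return code.count(".") + 1


def code_sort_key(code: str) -> tuple[int, ...]:
    """Sort key ordering codes by numeric segments ('2' before '11')."""
    return tuple(int(s) for s in code.split("."))


def code_has_prefix(code: str, prefix: str) -> bool:
    """True if ``code`` equals ``prefix`` or lies under it in the hierarchy.

    Matching respects segment boundaries: prefix "11" matches "11.1.2.3"
    but not "1.1.2.3" or "110.1".
    """
    return code == prefix or code.startswith(prefix + ".")


@dataclass(frozen=True)
class Taxonomy:
    """The classifier's label space: category code -> name.

    Codes are stored in canonical (no trailing dot) form.  Every level-4
    code's level-1 prefix must itself be declared.
    """

    categories: dict[str, str]

    def __post_init__(self) -> None:
        level1 = {c for c in self.categories if code_level(c) == 1}
        for code in self.categories:
            if code_level(code) == 4:
                head = code.split(".", 1)[0]
                if head not in level1:
                    raise ValidationError(
                        f"level-4 code {code!r} has no declared level-1 category {head!r}"
                    )

    def __contains__(self, code: str) -> bool:
        return code in self.categories

    def __len__(self) -> int:
        return len(self.categories)

    def name(self, code: str) -> str:
        try:
            return self.categories[code]
        except KeyError:
            raise ValidationError(f"unknown category code: {code!r}") from None

    def counts_per_level(self) -> dict[int, int]:
        counts: Counter[int] = Counter(code_level(c) for c in self.categories)
        return {lvl: counts.get(lvl, 0) for lvl in (1, 2, 3, 4)}

    def codes(self, level: int | None = None) -> list[str]:
        """Declared codes in numeric order, optionally one level only."""
        cs = [
            c
            for c in self.categories
            if level is None or code_level(c) == level
        ]
        return sorted(cs, key=code_sort_key)

    def validate_label(self, code: str) -> str:
        c = normalize_code(code)
        if c not in self.categories:
            raise ValidationError(f"label {code!r} not in taxonomy")
        return c


@dataclass(frozen=True)
class ReferenceDoc:
    """A labeled reference text: a category description or an annotated example.

    Label order is preserved as given (annotations are ranked); set
    semantics apply only when testing hits.  Description-source docs carry
    exactly one label; example-source docs carry 1-3.
    """

    doc_id: str
    text: str
    labels: tuple[str, ...]
    source: Literal["description", "example"]

    def __post_init__(self) -> None:
        if not 1 <= len(self.labels) <= MAX_LABELS:
            raise ValidationError(
                f"doc {self.doc_id!r}: {len(self.labels)} labels, need 1-{MAX_LABELS}"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError(f"doc {self.doc_id!r}: duplicate labels")
        if self.source == "description" and len(self.labels) != 1:
            raise ValidationError(
                f"description doc {self.doc_id!r} must carry exactly 1 label"
            )


@dataclass(frozen=True)
class QueryDoc:
    """A question text to classify; gold labels, if known, are 0-3 codes.

    An empty gold set means unlabeled, or annotated as having no
    corresponding category in the taxonomy.
    """

    doc_id: str
    text: str
    gold_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.gold_labels) > MAX_LABELS:
            raise ValidationError(
                f"query {self.doc_id!r}: {len(self.gold_labels)} labels exceed cap {MAX_LABELS}"
            )

    @property
    def is_labeled(self) -> bool:
        return len(self.gold_labels) > 0


Doc = Union[ReferenceDoc, QueryDoc]


@dataclass(frozen=True)
class Corpus:
    """An ordered document collection bound to a taxonomy.

    ``mode`` tags the corpus role: "D" (descriptions), "E" (examples),
    "DplusE" (fusion) or "query".
    """

    docs: tuple[Doc, ...]
    taxonomy: Taxonomy
    mode: Mode

    def __post_init__(self) -> None:
        ids = [d.doc_id for d in self.docs]
        if len(set(ids)) != len(ids):
            dup = next(i for i, c in Counter(ids).items() if c > 1)
            raise ValidationError(f"duplicate doc_id in corpus: {dup!r}")
        for d in self.docs:
            labels = d.labels if isinstance(d, ReferenceDoc) else d.gold_labels
            if isinstance(d, QueryDoc) and not labels and self.mode != "query":
                raise ValidationError(
                    f"unlabeled doc {d.doc_id!r} not allowed in mode {self.mode!r}"
                )
            for lab in labels:
                if lab not in self.taxonomy:
                    raise ValidationError(
                        f"doc {d.doc_id!r}: label {lab!r} not in taxonomy"
                    )

    def __len__(self) -> int:
        return len(self.docs)

    def __iter__(self) -> Iterator[Doc]:
        return iter(self.docs)

    def __getitem__(self, i: int) -> Doc:
        return self.docs[i]

    @property
    def labeled_docs(self) -> tuple[Doc, ...]:
        """Docs carrying at least one (gold) label."""
        out = []
        for d in self.docs:
            labels = d.labels if isinstance(d, ReferenceDoc) else d.gold_labels
            if labels:
                out.append(d)
        return tuple(out)

    def label_multiset(self) -> Counter[str]:
        c: Counter[str] = Counter()
        for d in self.docs:
            labels = d.labels if isinstance(d, ReferenceDoc) else d.gold_labels
            c.update(labels)
        return c

    def subset(self, indices: Sequence[int]) -> "Corpus":
        return replace(self, docs=tuple(self.docs[i] for i in indices))


# ---------------------------------------------------------------------------
# taxonomy I/O


def read_taxonomy(
    path: str | Path,
    fmt: Literal["tsv", "jsonl"] = "tsv",
    header: bool = False,
) -> Taxonomy:
    """Read a taxonomy file into a validated :class:`Taxonomy`.

    TSV rows are ``code<TAB>name``; JSONL rows are objects with keys
    ``code`` and ``name``.  Trailing-dot codes are normalized on read.
    Duplicate codes are rejected.
    """
    path = Path(path)
    categories: dict[str, str] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line:
                continue
            if fmt == "tsv":
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ParseError(
                        f"{path}:{lineno}: expected 2 tab-separated fields, got {len(parts)}"
                    )
                raw_code, name = parts
            else:
                try:
                    obj = json.loads(line)
                    raw_code, name = obj["code"], obj["name"]
                except (json.JSONDecodeError, KeyError, TypeError) as e:
                    raise ParseError(f"{path}:{lineno}: bad JSONL row ({e})") from e
            try:
                code = normalize_code(raw_code)
            except ValidationError as e:
                raise ParseError(f"{path}:{lineno}: {e}") from e
            if code in categories:
                raise ValidationError(f"{path}:{lineno}: duplicate code {code!r}")
            categories[code] = name
    return Taxonomy(categories)


def write_taxonomy(
    taxonomy: Taxonomy,
    path: str | Path,
    fmt: Literal["tsv", "jsonl"] = "tsv",
    trailing_dot: bool = False,
) -> None:
    """Write a taxonomy; ``trailing_dot`` emits the printed-source dialect."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for code in taxonomy.codes():
            out_code = code + "." if trailing_dot else code
            if fmt == "tsv":
                fh.write(f"{out_code}\t{taxonomy.categories[code]}\n")
            else:
                fh.write(
                    json.dumps(
                        {"code": out_code, "name": taxonomy.categories[code]},
                        ensure_ascii=False,
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# corpus I/O

LABEL_SEP = ";"


def _parse_labels(raw: str | list, taxonomy: Taxonomy, where: str) -> tuple[str, ...]:
    if isinstance(raw, str):
        parts = [p for p in raw.split(LABEL_SEP) if p.strip()]
    else:
        parts = [str(p) for p in raw]
    if len(parts) > MAX_LABELS:
        raise ValidationError(f"{where}: {len(parts)} labels exceed cap {MAX_LABELS}")
    return tuple(taxonomy.validate_label(p) for p in parts)


def read_corpus(
    path: str | Path,
    taxonomy: Taxonomy,
    mode: Mode,
    fmt: Literal["tsv", "jsonl"] = "tsv",
) -> Corpus:
    """Read a corpus file into a validated :class:`Corpus`.

    Reference modes ("D", "E", "DplusE") yield :class:`ReferenceDoc` rows;
    "query" yields :class:`QueryDoc` rows, for which the label field may be
    empty.  Unknown label codes and rows with more than 3 labels are
    rejected.
    """
    path = Path(path)
    default_source = "description" if mode == "D" else "example"
    docs: list[Doc] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            where = f"{path}:{lineno}"
            if fmt == "tsv":
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ParseError(
                        f"{where}: expected 3 tab-separated fields, got {len(parts)}"
                    )
                doc_id, raw_labels, text = parts
                source = default_source
            else:
                try:
                    obj = json.loads(line)
                    doc_id, raw_labels, text = obj["doc_id"], obj["labels"], obj["text"]
                    source = obj.get("source", default_source)
                except (json.JSONDecodeError, KeyError, TypeError) as e:
                    raise ParseError(f"{where}: bad JSONL row ({e})") from e
            labels = _parse_labels(raw_labels, taxonomy, where)
            if mode == "query":
                docs.append(QueryDoc(doc_id=doc_id, text=text, gold_labels=labels))
            else:
                if not labels:
                    raise ValidationError(f"{where}: reference doc has no labels")
                docs.append(
                    ReferenceDoc(doc_id=doc_id, text=text, labels=labels, source=source)
                )
    return Corpus(docs=tuple(docs), taxonomy=taxonomy, mode=mode)


def write_corpus(
    corpus: Corpus,
    path: str | Path,
    fmt: Literal["tsv", "jsonl"] = "tsv",
    trailing_dot: bool = False,
    include_labels: bool = True,
) -> None:
    """Write a corpus; ``include_labels=False`` blanks the label column
    (used when publishing query sets whose answer key lives elsewhere)."""
    path = Path(path)

    def fmt_code(c: str) -> str:
        return c + "." if trailing_dot else c

    with path.open("w", encoding="utf-8") as fh:
        for d in corpus.docs:
            labels = d.labels if isinstance(d, ReferenceDoc) else d.gold_labels
            if not include_labels:
                labels = ()
            if fmt == "tsv":
                fh.write(
                    f"{d.doc_id}\t{LABEL_SEP.join(fmt_code(c) for c in labels)}\t{d.text}\n"
                )
            else:
                obj = {
                    "doc_id": d.doc_id,
                    "labels": [fmt_code(c) for c in labels],
                    "text": d.text,
                }
                if isinstance(d, ReferenceDoc):
                    obj["source"] = d.source
                fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def fuse_corpora(d: Corpus, e: Corpus) -> Corpus:
    """Concatenate a description corpus and an example corpus into D+E.

    Order is preserved (D first), source tags are retained, and doc_ids are
    disambiguated with a source prefix.  Both corpora must share one
    taxonomy object (or equal taxonomies).
    """
    if d.taxonomy.categories != e.taxonomy.categories:
        raise ValidationError("cannot fuse corpora with different taxonomies")

    def reprefix(doc: Doc, tag: str) -> ReferenceDoc:
        assert isinstance(doc, ReferenceDoc)
        return replace(doc, doc_id=f"{tag}:{doc.doc_id}")

    docs = [reprefix(x, "D") for x in d.docs] + [reprefix(x, "E") for x in e.docs]
    return Corpus(docs=tuple(docs), taxonomy=d.taxonomy, mode="DplusE")
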