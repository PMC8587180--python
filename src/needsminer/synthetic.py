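"""Seeded generator of synthetic taxonomies and corpora.

The real corpora this package targets -- a curated taxonomy of patient
worries with one description text per category, a few hundred manually
annotated question texts, and thousands of unlabeled questions from a QA
service -- are not publicly deposited.  This module generates structural
stand-ins so every other module is testable end to end:

* a 4-level taxonomy of dotted codes with one disjoint *signature
  vocabulary* per leaf category, over a shared background vocabulary;
* a description corpus (one text per leaf category: the category name
  plus its signature terms);
* a labeled example corpus whose primary category follows a Zipf law
  (long-tail prevalence), with 1-3 gold labels per text and a signature
  rate ``s`` controlling how many of a text's tokens come from its
  categories' signature vocabularies (s=1: perfectly separable; s=0: pure
  background noise);
* a query corpus mixing in-taxonomy questions (gold labels recorded for
  evaluation) with out-of-taxonomy questions drawn from background plus a
  held-out novel-topic vocabulary -- the analogue of questions about an
  emergent topic the taxonomy does not cover.

Default parameters mirror the study conditions the package emulates:
16 first-level / 631 fourth-level categories, 456 labeled examples, an
out-of-taxonomy rate of 0.546, and a multi-label mix averaging ~1.45
labels per labeled question.

A single global seed derives independent per-stream sub-seeds (taxonomy,
descriptions, examples, queries), so e.g. enlarging the query set does
not perturb the taxonomy.  Tokens are synthetic strings ("w0421",
"c016sig3"); no language resources are required.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .classify import build_index, classify_corpus
from .corpus import (
    Corpus,
    QueryDoc,
    ReferenceDoc,
    Taxonomy,
    fuse_corpora,
    write_corpus,
    write_taxonomy,
)
from .errors import ValidationError
from .evaluate import (
    category_distribution,
    cross_validate,
    evaluate_d_based,
    jensen_shannon_divergence,
)

__all__ = ["GeneratorConfig", "SyntheticDataset", "generate", "write_dataset", "benchmark_suite"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic-corpus generator.

    ``signature_rate`` (s) is the fraction of a question's tokens drawn
    from its gold categories' signature vocabularies; the rest are
    background.  ``zipf_exponent`` shapes the long tail of category
    prevalence (0 = uniform).  ``out_of_taxonomy_rate`` is the fraction
    of queries with no corresponding category.
    """

    n_level1: int = 16
    n_level4: int = 631
    vocab_background: int = 2000
    signature_terms_per_category: int = 8
    signature_rate: float = 0.7
    doc_length: float = 40.0  # mean tokens per text (Poisson, min 1)
    n_descriptions_per_category: int = 1
    # how many signature terms each description text includes; None = all.
    # low values emulate terse one-sentence descriptions that cover only a
    # sliver of the wording real questions use
    signature_terms_in_description: int | None = None
    n_labeled_examples: int = 456
    n_queries: int = 1000
    multi_label_probs: tuple[float, float, float] = (0.62, 0.31, 0.07)
    zipf_exponent: float = 1.0
    out_of_taxonomy_rate: float = 0.546
    novel_vocab: int = 50
    novel_token_rate: float = 0.3  # novel-vs-background mix for off-taxonomy texts
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.multi_label_probs) - 1.0) > 1e-9:
            raise ValidationError("multi_label_probs must sum to 1")
        for name in (
            "n_level1",
            "n_level4",
            "vocab_background",
            "signature_terms_per_category",
            "n_descriptions_per_category",
            "n_labeled_examples",
            "n_queries",
        ):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        for name in ("signature_rate", "out_of_taxonomy_rate", "novel_token_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.zipf_exponent < 0:
            raise ValidationError("zipf_exponent must be >= 0")
        if (
            self.signature_terms_in_description is not None
            and self.signature_terms_in_description < 1
        ):
            raise ValidationError("signature_terms_in_description must be >= 1")
        if self.n_level4 < self.n_level1:
            raise ValidationError("need at least one leaf per first-level category")


@dataclass(frozen=True)
class SyntheticDataset:
    taxonomy: Taxonomy
    d_corpus: Corpus
    e_corpus: Corpus
    queries: Corpus  # QueryDocs; gold labels present for evaluation
    leaf_codes: tuple[str, ...]
    prevalence: np.ndarray  # Zipf weights over leaf_codes
    config: GeneratorConfig


def _leaf_codes(cfg: GeneratorConfig) -> list[str]:
    """Distribute leaves round-robin over first-level branches; sub-codes
    count upward within each branch (j.k.l supports 125 leaves/branch)."""
    per_branch: dict[int, int] = {}
    codes = []
    for i in range(cfg.n_level4):
        g = i % cfg.n_level1 + 1
        m = per_branch.get(g, 0)
        per_branch[g] = m + 1
        j, k, l = m // 25 + 1, (m // 5) % 5 + 1, m % 5 + 1
        codes.append(f"{g}.{j}.{k}.{l}")
    return codes


def _signature(cat_idx: int, cfg: GeneratorConfig) -> list[str]:
    return [f"c{cat_idx:03d}sig{t}" for t in range(cfg.signature_terms_per_category)]


def _background_word(rng: np.random.Generator, cfg: GeneratorConfig) -> str:
    return f"w{rng.integers(cfg.vocab_background):04d}"


def _draw_labels(
    rng: np.random.Generator, prevalence: np.ndarray, cfg: GeneratorConfig
) -> list[int]:
    n_labels = int(rng.choice([1, 2, 3], p=cfg.multi_label_probs))
    primary = int(rng.choice(len(prevalence), p=prevalence))
    labels = [primary]
    while len(labels) < n_labels:
        extra = int(rng.integers(len(prevalence)))
        if extra not in labels:
            labels.append(extra)
    return labels


def _question_tokens(
    rng: np.random.Generator,
    label_idx: Sequence[int],
    cfg: GeneratorConfig,
) -> list[str]:
    length = max(1, int(rng.poisson(cfg.doc_length)))
    sigs = [_signature(i, cfg) for i in label_idx]
    toks = []
    for _ in range(length):
        if rng.random() < cfg.signature_rate:
            sig = sigs[int(rng.integers(len(sigs)))]
            toks.append(sig[int(rng.integers(len(sig)))])
        else:
            toks.append(_background_word(rng, cfg))
    return toks


def generate(cfg: GeneratorConfig) -> SyntheticDataset:
    """Generate (taxonomy, D corpus, E corpus, query corpus) from a config.

    Deterministic under a fixed seed.  The query corpus's gold labels are
    carried on the :class:`QueryDoc` objects; :func:`write_dataset` keeps
    them in a separate answer-key file that the classifier never reads.
    """
    streams = np.random.SeedSequence(cfg.seed).spawn(4)
    rng_tax = np.random.default_rng(streams[0])
    rng_desc = np.random.default_rng(streams[1])
    rng_ex = np.random.default_rng(streams[2])
    rng_q = np.random.default_rng(streams[3])

    leaves = _leaf_codes(cfg)
    categories: dict[str, str] = {}
    for g in range(1, cfg.n_level1 + 1):
        categories[str(g)] = f"branch {g}"
    for i, code in enumerate(leaves):
        categories[code] = f"worry about topic{i:03d}"
    taxonomy = Taxonomy(categories)

    # prevalence of leaf categories: Zipf over a seeded shuffle of the
    # leaves, so prevalence rank is independent of code order
    order = rng_tax.permutation(len(leaves))
    ranks = np.empty(len(leaves), dtype=int)
    ranks[order] = np.arange(len(leaves))
    weights = 1.0 / (ranks + 1.0) ** cfg.zipf_exponent
    prevalence = weights / weights.sum()

    d_docs = []
    n_desc_sig = (
        cfg.signature_terms_per_category
        if cfg.signature_terms_in_description is None
        else min(cfg.signature_terms_in_description, cfg.signature_terms_per_category)
    )
    for i, code in enumerate(leaves):
        for rep in range(cfg.n_descriptions_per_category):
            text = " ".join([categories[code]] + _signature(i, cfg)[:n_desc_sig])
            if cfg.n_descriptions_per_category > 1:
                # jitter replicate descriptions with a little background
                text += " " + " ".join(
                    _background_word(rng_desc, cfg) for _ in range(3)
                )
            doc_id = f"d{i:04d}" if rep == 0 else f"d{i:04d}_{rep}"
            d_docs.append(
                ReferenceDoc(doc_id=doc_id, text=text, labels=(code,), source="description")
            )
    d_corpus = Corpus(docs=tuple(d_docs), taxonomy=taxonomy, mode="D")

    e_docs = []
    for n in range(cfg.n_labeled_examples):
        label_idx = _draw_labels(rng_ex, prevalence, cfg)
        toks = _question_tokens(rng_ex, label_idx, cfg)
        e_docs.append(
            ReferenceDoc(
                doc_id=f"e{n:05d}",
                text=" ".join(toks),
                labels=tuple(leaves[i] for i in label_idx),
                source="example",
            )
        )
    e_corpus = Corpus(docs=tuple(e_docs), taxonomy=taxonomy, mode="E")

    q_docs = []
    for n in range(cfg.n_queries):
        if rng_q.random() < cfg.out_of_taxonomy_rate:
            length = max(1, int(rng_q.poisson(cfg.doc_length)))
            toks = [
                f"novel{rng_q.integers(cfg.novel_vocab):03d}"
                if rng_q.random() < cfg.novel_token_rate
                else _background_word(rng_q, cfg)
                for _ in range(length)
            ]
            q_docs.append(QueryDoc(doc_id=f"q{n:05d}", text=" ".join(toks)))
        else:
            label_idx = _draw_labels(rng_q, prevalence, cfg)
            toks = _question_tokens(rng_q, label_idx, cfg)
            q_docs.append(
                QueryDoc(
                    doc_id=f"q{n:05d}",
                    text=" ".join(toks),
                    gold_labels=tuple(leaves[i] for i in label_idx),
                )
            )
    queries = Corpus(docs=tuple(q_docs), taxonomy=taxonomy, mode="query")

    return SyntheticDataset(
        taxonomy=taxonomy,
        d_corpus=d_corpus,
        e_corpus=e_corpus,
        queries=queries,
        leaf_codes=tuple(leaves),
        prevalence=prevalence,
        config=cfg,
    )


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset as TSV: taxonomy, D corpus, E corpus, unlabeled
    queries, and a separate gold answer key (never read by the classifier)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "taxonomy": out / "taxonomy.tsv",
        "d_corpus": out / "d_corpus.tsv",
        "e_corpus": out / "e_corpus.tsv",
        "queries": out / "queries.tsv",
        "answer_key": out / "answer_key.tsv",
    }
    write_taxonomy(ds.taxonomy, paths["taxonomy"])
    write_corpus(ds.d_corpus, paths["d_corpus"])
    write_corpus(ds.e_corpus, paths["e_corpus"])
    write_corpus(ds.queries, paths["queries"], include_labels=False)
    write_corpus(ds.queries, paths["answer_key"])
    return paths


def benchmark_suite(
    signature_rates: Sequence[float],
    modes: Sequence[Literal["D", "E", "DplusE"]] = ("D", "E", "DplusE"),
    base_config: GeneratorConfig | None = None,
    folds: int = 5,
    seeds: Sequence[int] = (0,),
) -> pd.DataFrame:
    """Accuracy/JSD benchmark over a grid of signature rates and modes.

    Per (s, seed): generate a dataset; score the description-based
    classifier single-pass on the labeled examples, and the example-based
    and combined classifiers by k-fold CV; classify the labeled queries
    with the full-reference index and compare the predicted top-1
    distribution with the gold-label distribution by Jensen-Shannon
    divergence.  Returns one row per (s, mode, seed).
    """
    if not signature_rates:
        raise ValidationError("signature-rate grid must be nonempty")
    base = base_config or GeneratorConfig()
    rows = []
    for s in signature_rates:
        for seed in seeds:
            cfg = replace(base, signature_rate=float(s), seed=int(seed))
            ds = generate(cfg)
            labeled_q = ds.queries.subset(
                [i for i, d in enumerate(ds.queries) if d.gold_labels]
            )
            for mode in modes:
                if mode == "D":
                    report = evaluate_d_based(ds.e_corpus, build_index(ds.d_corpus))
                    reference = ds.d_corpus
                elif mode == "E":
                    report = cross_validate(ds.e_corpus, folds=folds, mode="E", seed=seed)
                    reference = ds.e_corpus
                else:
                    report = cross_validate(
                        ds.e_corpus, ds.d_corpus, folds=folds, mode="DplusE", seed=seed
                    )
                    reference = fuse_corpora(ds.d_corpus, ds.e_corpus)
                index = build_index(reference)
                preds = classify_corpus(labeled_q, index, k=1)
                assigned = [p.top1[0] for p in preds if p.top1 is not None]
                gold = [c for d in labeled_q for c in d.gold_labels]
                support = ds.taxonomy.codes(level=4)
                if assigned and gold:
                    jsd = jensen_shannon_divergence(
                        category_distribution(assigned, support),
                        category_distribution(gold, support),
                    )
                else:  # no scorable queries: distance undefined
                    jsd = float("nan")
                rows.append(
                    {
                        "s": float(s),
                        "mode": mode,
                        "seed": int(seed),
                        "acc1_mean": report.acc1["mean"],
                        "acc10_mean": report.acc10["mean"],
                        "jsd_pred_vs_gold": jsd,
                    }
                )
    return pd.DataFrame(rows)
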