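"""Generate a synthetic taxonomy plus reference and query corpora.

Builds a small study-shaped dataset: a 4-level taxonomy, one description
text per leaf category (D corpus), labeled example questions with a
Zipf-distributed category prevalence (E corpus), and a query corpus in
which roughly half the questions have no corresponding category.
"""

from collections import Counter

from needsminer import GeneratorConfig, generate, write_dataset

cfg = GeneratorConfig(
    n_level1=8,
    n_level4=60,
    n_labeled_examples=200,
    n_queries=300,
    seed=42,
)
ds = generate(cfg)
paths = write_dataset(ds, "scratch/example_dataset")

n_unlabeled = sum(1 for d in ds.queries if not d.gold_labels)
label_counts = Counter(len(d.labels) for d in ds.e_corpus)

print(f"taxonomy: {len(ds.taxonomy.codes(level=4))} leaf categories "
      f"under {len(ds.taxonomy.codes(level=1))} branches")
print(f"D corpus: {len(ds.d_corpus)} description texts (one per leaf)")
print(f"E corpus: {len(ds.e_corpus)} labeled examples; "
      f"labels per example: {dict(sorted(label_counts.items()))}")
print(f"queries:  {len(ds.queries)} texts, {n_unlabeled} without any "
      f"matching category ({n_unlabeled / len(ds.queries):.1%})")
print("files written:")
for name, p in paths.items():
    print(f"  {name}: {p}")

# The unlabeled fraction tracks the configured out-of-taxonomy rate
# (0.546 by default): these are the questions a fixed taxonomy cannot
# describe, e.g. ones about an emergent topic.
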