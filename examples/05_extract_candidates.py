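"""Extract question subsets for manual review.

Two filters mirror the downstream applications: (1) all questions whose
top-1 category falls under one taxonomy branch -- e.g. the side-effects
branch, a candidate pool for adverse-drug-event signals -- and (2) a raw
keyword search for an emergent topic the taxonomy does not cover yet.
"""

from needsminer import (
    GeneratorConfig,
    build_index,
    classify_corpus,
    filter_by_category_prefix,
    fuse_corpora,
    generate,
    keyword_search,
)

ds = generate(GeneratorConfig(
    n_level1=8, n_level4=60, n_labeled_examples=200, n_queries=400, seed=5,
))
index = build_index(fuse_corpora(ds.d_corpus, ds.e_corpus))
preds = classify_corpus(ds.queries, index, k=1)

# branch "3" plays the role of the symptoms/side-effects branch here
subset, count, share = filter_by_category_prefix(preds, ds.queries, "3")
print(f"branch filter: {count} of {len(preds)} classified queries "
      f"({share:.1%}) have their top-1 category under branch 3")
print("these would be handed to a reviewer to read for drug names and "
      "adverse events\n")

# the generator marks out-of-taxonomy questions with a held-out 'novel'
# vocabulary -- the stand-in for an emergent topic keyword
hits = keyword_search(ds.queries, "novel00")
print(f"keyword search: {len(hits)} of {len(ds.queries)} questions mention "
      "'novel00' (an emergent-topic token)")
print(f"of those, {sum(1 for d in hits if not d.gold_labels)} have no "
      "category in the taxonomy at all -- candidate unmet needs")
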