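"""Cross-language commonality of the anchor model against permutation nulls.

Computes the mean inter-language correlation (ILC: per-concept Pearson r
between two languages' projected representations, Fisher-z, averaged) of the
neurocognitive model, and benchmarks it against the random-word and
random-dimension control models (499 resampled anchor sets each).
"""

import numpy as np

import semscape as ss

world = ss.generate_world(ss.WorldParams(seed=1))
tables = ss.emit_embeddings(world)
spaces = {t.language: ss.neurocognitive_space(t, world.anchor_spec) for t in tables}

observed = ss.mean_ilc(spaces)
rw = ss.random_word_null(tables, targets=world.target_concepts,
                         n_anchors=13, n_iters=499, rng=1)
rd = ss.random_dimension_null(tables, targets=world.target_concepts,
                              n_words=52, n_clusters=13, n_iters=499, rng=2)

p_rw = ss.NullDistribution("random_word", "mean_ILC", rw, observed).one_tailed_p
p_rd = ss.NullDistribution("random_dimension", "mean_ILC", rd, observed).one_tailed_p
pc1 = ss.pca_universality(spaces)

print(f"mean ILC (neurocognitive): {observed:.3f}")
print(f"random-word null 95th pct: {np.percentile(rw, 95):.3f}  (one-tailed p = {p_rw:.3f})")
print(f"random-dim  null 95th pct: {np.percentile(rd, 95):.3f}  (one-tailed p = {p_rd:.3f})")
print(f"PC1 universality share:    {100 * pc1:.1f}%")
print("\nThe anchor model sits above both control distributions: the shared")
print("structure it captures is specific to the chosen dimensions, not a")
print("by-product of projecting onto any 13 anchors.")
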