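# semscape

Cross-linguistic semantic spaces, their universality, and their environmental
correlates.

Languages differ widely in form, yet word meanings appear to be organized
along shared dimensions. `semscape` implements an analysis pipeline for
testing this quantitatively: it builds comparable semantic representations
from per-language word embeddings via **anchor-word projection**, measures
how much of that structure is shared across languages against **permutation
null models**, tests whether the structure generalizes to
**colexification-network topology**, and asks what explains the residual
variation by regressing semantic (and neural) dissimilarity between
languages on **environmental distance matrices** — climate, geography,
linguistic history, and culture — with crossed random intercepts for
language families. A fully synthetic world generator with planted effect
sizes makes every stage testable end to end without external data.

It is intended for computational cognitive scientists and linguists working
with multilingual embeddings, cross-linguistic databases, and
representational similarity analysis (RSA).

## The models

**Anchor projection.** A concept `c` in language `l` is represented by its
cosine similarities to anchor vectors in `l`'s native embedding space. The
*neurocognitive* model uses 13 brain-motivated dimensions (color, shape,
taste, smell, sound, touch, motor; time, space, number, cognition, emotion,
social), each defined by a small group of anchor words; entry `(c, d)` is
the mean cosine to dimension `d`'s anchors. Alternatives: *global*
(all other concepts as anchors), *local* (top-k nearest neighbors,
transferred across a language pair through concept translations), *feature*
(feature-norm words), and two statistical controls — *random word* (13
random anchors) and *random dimension* (random words grouped into 13
pseudo-dimensions by K-means in a reference language).

**Universality.** For a language pair, the inter-language correlation (ILC)
is the per-concept Pearson `r` between the two projected representations,
Fisher `z`-transformed and averaged over concepts. A model's mean ILC is
benchmarked against the null distribution of its statistic under repeated
random anchor draws, with one-tailed `p = (1 + #{null ≥ observed}) /
(n_iters + 1)`. A complementary PCA treats languages as features and
concept × dimension cells as samples; the PC1 explained-variance share
estimates shared structure.

**Environmental RSA.** With `y_ij` the standardized semantic (or neural)
distance between languages `i` and `j`:

```
y_ij = β₀ + β₁·Climate_ij + β₂·Culture_ij + β₃·Geography_ij
       + β₄·LingHist_ij + (1|Family_i) + (1|Family_j) + ε_ij
```

estimated by REML with two-sided t-tests on the fixed effects. Climate
distance is the z-scored Euclidean distance over 19 bioclim variables;
geographic distance is great-circle km; linguistic history counts steps to
the lowest common ancestor on the family tree; cultural distance is
consumed as a precomputed matrix. Commonality analysis partitions the
explained variance of a response into parts unique to the semantic and
climate predictors and the part they share.

## Worked example

```python
import semscape as ss

world = ss.generate_world(ss.WorldParams(seed=1))     # 30 languages, 5 families
tables = ss.emit_embeddings(world)
spaces = {t.language: ss.neurocognitive_space(t, world.anchor_spec)
          for t in tables}

observed = ss.mean_ilc(spaces)
null = ss.random_word_null(tables, targets=world.target_concepts,
                           n_anchors=13, n_iters=499, rng=1)
print(observed, ss.NullDistribution("rw", "mean_ILC", null, observed).one_tailed_p)
```

Running `examples/02_universality_nulls.py` (which does the above plus the
dimension-matched control) prints:

```
mean ILC (neurocognitive): 1.679
random-word null 95th pct: 1.185  (one-tailed p = 0.002)
random-dim  null 95th pct: 1.141  (one-tailed p = 0.002)
PC1 universality share:    92.7%
```

The anchor model's mean ILC of 1.679 (Fisher-z units; back-transformed,
mean per-concept `r ≈ 0.93`) sits far above the 95th percentiles of both
null distributions: the cross-language commonality is specific to the
chosen dimensions, not a by-product of projecting onto any 13 anchors.
`examples/04_environment_rsa.py` then fits the mixed model on the same
world and prints `beta_climate = +0.414` (95% CI [+0.336, +0.492]) with the
other environmental coefficients near zero — recovering the world's planted
climate pathway. Each capability has one short script under `examples/`.

A thin CLI mirrors the stages (`semscape synth | project | universality |
colex | envdist | rsa | commonality | climatepc | run`); `semscape run
--seed 7 --out artifacts/` executes the whole synthetic pipeline and writes
a manifest of SHA-256 digests (identical seed ⇒ byte-identical outputs).

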