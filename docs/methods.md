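# Methods

This note documents the statistical models, conventions, and the synthetic
generative model behind `semscape`, in enough detail to interpret what a
passing test suite does and does not establish.

## Anchor-projection semantic spaces

All semantic models share one mechanism: a concept is represented by its
cosine similarities to anchor vectors in the language's own embedding
space, which removes the arbitrary rotation between independently trained
embedding spaces and makes representations comparable across languages.

Conventions:

- **Overlap exclusion.** Target concepts appearing among their own anchors
  are dropped (feature model: the anchor is dropped instead), so a model
  cannot inflate cross-language commonality by correlating a word with
  itself.
- **Missing anchors** are averaged over, never imputed; a dimension left
  with zero available anchors is an error naming the dimension.
- **Global model** columns follow the master concept order with the self
  cell stored as NaN; comparisons drop NaN cells pairwise, which keeps
  columns aligned across languages.
- **Local model** anchor transfer: for an ordered pair (A→B), concept `c`'s
  anchors are its top-k cosine neighbors in A, mapped to B through the
  concept translations; the pair-level value symmetrizes the two directions
  by averaging their Fisher-z per-concept correlations. The anchor-set
  alignment across languages is underdetermined in the field; directional
  transfer with symmetrized averaging is this package's choice. Default
  k = 100.
- **Random-word control**: 13 anchors sampled without replacement from the
  master list, identical anchor identities across all languages within one
  iteration. (Descriptions of this control vary between 13 and 100 words in
  the literature this follows; 13 — dimensionality-matched to the anchor
  model — is the default, exposed as a parameter.)
- **Random-dimension control**: a random word set is partitioned by K-means
  *on one designated reference language's vectors*, and the grouping is
  transferred by concept identity — the only construction that yields
  aligned pseudo-dimension columns across languages. Empty clusters trigger
  a reseeded retry. On small synthetic inventories the word budget defaults
  to the anchor model's total (52 = 13 × 4) rather than the literature's
  100-of-1016, keeping the masked-target fraction comparable.

## Universality statistics

- **ILC**: per shared concept, Pearson r between the two languages' rows
  over aligned columns; r is clipped to ±(1 − 1e−7) before `atanh` (so
  identical spaces sit at the finite bound z ≈ 8.41); the mean over
  concepts is the pair's ILC, and the mean over pairs the model's score.
  Zero-variance concepts are skipped with a count.
- **Permutation p**: `p = (1 + #{null ≥ observed})/(n_iters + 1)` — never
  exactly zero, exactly uniform under exchangeability. Null distributions
  default to 10,000 iterations for embedding controls and 1,000 for
  colexification controls; the test suite and acceptance script use 199–499
  iterations, which changes only the p-value granularity.
- **PCA universality**: language columns are centered and unit-scaled
  (correlation PCA) before the SVD, so fully independent languages tend to
  a PC1 share of 1/n_languages — this choice makes the isotropy limit
  testable. Whether centering-only would be preferable is undecidable from
  the available descriptions; correlation PCA is the package's convention.
- **Model comparison**: two-sided Wilcoxon signed-rank over language pairs,
  exact null for n ≤ 25 and the normal approximation above; the median
  difference carries a seeded bootstrap percentile CI (2,000 resamples).
  Multiple comparisons use Benjamini–Hochberg throughout.

## Colexification topology

Edge weight (0 for non-adjacent pairs), weighted common neighbors
(Σ min(w(a,z), w(b,z)); the product convention is available behind a flag),
and Louvain/Infomap co-membership fractions over seeded runs (default 10)
are each min–max normalized over all node pairs and averaged; topology
distance is 1 − combined. A metric constant over all pairs (e.g. Infomap
finding a single community on a dense graph) contributes 0.5 uniformly and
is flagged. Louvain comes from networkx, Infomap from igraph; both are
seeded per run. The generalization statistic is the per-language Spearman
correlation between semantic pair distances (1 − Pearson between concept
rows) and topology distances, averaged over languages.

## Environmental distances

- **Climate**: each of the 19 bioclim variables z-scored (sample SD) across
  included languages, then Euclidean distance; languages with missing
  variables are excluded, never imputed. Affine rescaling of any variable
  is absorbed by the z-scoring.
- **Geography**: spherical haversine with R = 6371.0088 km. An ellipsoidal
  option is deliberately not provided: the < 0.6% deviation is irrelevant
  once distances are standardized for regression.
- **Linguistic history**: steps from both leaves to their lowest common
  ancestor on the family tree, summed (symmetric, a metric); a max-steps
  convention is available behind a flag.
- **Demographics**: language-level means of age, gender (proportion of a
  reference category), education and SES, z-scored, Euclidean.
- Coordinates aggregate as arithmetic means per language; a longitude span
  above 180° (antimeridian) triggers a warning rather than silent nonsense.

## Mixed representational-similarity regression

The pair table holds one row per unordered language pair; the response and
every predictor column are standardized (sample SD). The model carries
crossed random intercepts for the families of both pair members, estimated
by REML (statsmodels MixedLM with two variance components), with
coefficients on the standardized scale.

**Inference.** p-values and CIs use a two-sided t reference with a
conservative degrees-of-freedom bound of `n_languages − k − 1`: language
pairs are not independent units, and the far tail of the normal reference
is measurably anti-conservative on this design (under a pure-noise
response, p < 0.002 occurred at a 0.5% rate). With the t reference the
empirical type-I error at α = 0.05 is ≈ 0.05 and the familywise
any-discovery rate of the 12-ROI screen under pure noise stays at its
nominal level.

**Boundary and failure handling.** Variance components estimated at zero
are permitted and flagged (`boundary`); with both components at zero the
GLS weighting is the identity and the fixed effects coincide with OLS
(`gls_at_zero_variance` exposes that evaluation; it matches an independent
OLS fit to ~1e−9). Note that REML *estimates* of a truly-zero variance are
positive with probability ≈ 1/2 on any finite design, so the estimated fit
tracks OLS only up to estimation noise. If the optimizer fails outright,
the fit falls back to OLS with the same t reference, flagged as
`ols-fallback` — unusable standard errors must never leak into FDR.

**Other conventions.** Semantic RDM distance is `1 − atanh(r)` over shared
flattened cells — the Fisher transform spreads the top of the correlation
scale; the value can be negative for near-identical languages, which is
harmless after standardization. Per-dimension RDMs default to correlation
distance over the dimension's concept-length vector (Euclidean behind a
flag). Commonality analysis partitions OLS R² into unique and common
shares; its CIs use a cluster bootstrap that resamples *languages* and
rebuilds the pair table, respecting the dependence between pairs sharing a
language; negative common shares (suppression) are reported and flagged.
Hierarchical regression reports block-1 R², the increment, and the
Spearman correlation between fitted and observed distances.

## The synthetic world generator

Every downstream stage is tested against worlds with known ground truth.
The generative model (all pure functions of parameters + seed):

- **Family tree**: F families under the root; leaves all at equal depth
  below their family node, so within-family path distances are strictly
  smaller than between-family ones.
- **Latent loadings L** (concepts × 13, values in [0, 1]): anchor concepts
  load 0.85–1.0 on their own dimension and ≤ 0.1 elsewhere; target concepts
  load 0.6–1.0 on 1–3 dimensions and ≤ 0.2 elsewhere.
- **Climate**: a latent factor with family-level intraclass correlation
  (default ICC 0.5), realized as 19 variables = factor loadings × (two
  latent factors) + noise, so climate PC1 tracks the first factor — which
  is also the factor that modulates semantics (making the climate-PC
  projection stage testable with a known sign).
- **Climate → semantics**, two mechanisms: (i) log-linear per-dimension
  scaling `s_l = exp(β_s·c_l·h + family effect + noise)`; (ii) *pattern
  deflection* — selected dimensions' loading columns shift along a fixed
  direction proportionally to the language's climate factor. The deflection
  exists because a pure column rescaling is invisible to correlation-based
  per-dimension distances; it is what makes the per-dimension-FDR and
  projection tests well-posed.
- **Embeddings**: rotated, zero-padded concatenation of the language's
  loading matrix and its *idiosyncratic* loadings (15 extra latent
  dimensions, unshared across languages), plus isotropic noise. Both
  corruption scales are relative to the mean signal norm (0.3 ≈ 30%
  corruption regardless of embedding dimension). Idiosyncrasy is weighted
  per concept: anchor words — hand-picked for cross-linguistically stable
  reference — get weight 0.3, ordinary words draw log-normal weights
  (heavy-tailed). This unshared structured variation is essential: without
  it, any dimension-matched averaging control mechanically ties or beats
  the anchor model, because averaging suppresses isotropic noise for free.
  With it, random anchors import language-specific structure that the
  curated, coherent anchor groups average away.
- **Colexification edges**: per-pair pseudolanguage colexification
  probability is a logistic function of latent row similarity, scaled so
  the mean tracks the density parameter; weights are binomial counts.
- **Ratings**: fixed affine map of the language-level matrix into the 0–6
  scale plus rater noise, clipped; optional "careless" participants rate
  uniform noise (quality-control bait); demographics attached.
- **Neural RDMs**: one planted ROI mixes the standardized semantic and
  climate RDMs with noise; the other 11 ROIs are pure noise.
- **Calibrated pair response**: for mixed-model recovery the world also
  provides `planted_pair_table`, whose response is built directly on the
  standardized scale: `y = β·z(climate distance) + u(Family_i) + u(Family_j)
  + ε` with variances summing to 1. The structural (embedding) route plants
  the *sign and monotonicity* of the climate effect; only this pair-level
  route plants an exact standardized coefficient — the exp-link route's
  induced pair-level slope depends on noise bookkeeping and is not a clean
  target for recovery tests.

**What passing tests show — and don't.** On these worlds the pipeline
recovers a planted standardized climate effect of 0.5 with |bias| < 0.01
and ~96% CI coverage, keeps type-I error at ~0.05, localizes a planted
climate-sensitive dimension and a planted ROI under BH-FDR, and beats both
permutation nulls in ≥ 90% of worlds. Real embeddings differ in ways the
generator does not emulate: anisotropic frequency-linked vector norms,
polysemy, translation error in wordlists, non-Gaussian climate geography,
and phylogenetic signal richer than family intercepts. Results on synthetic
worlds validate the *machinery*, not substantive claims about real
languages.

## Numerical and degenerate-input conventions

Correlations clip at ±(1 − 1e−7) before `atanh`; RDMs must be symmetric
within 1e−8 (exact symmetrization internally, zero diagonal enforced on
write); constant metrics/variables are dropped or pinned to 0.5 with a
flag; the directional association ratio of a full projected map is
identically 0.5 (per-language column z-scoring makes every column sum to
zero), so directional ratios are computed on domain-level summaries;
tabular floats serialize at 10 significant digits, which is what makes
equal-seed pipeline runs byte-identical.

## Problem sizes

Tests and the acceptance script run worlds of 30 languages (5 families × 6)
with 60 target + 52 anchor concepts in 50-dimensional embeddings; 20–50
worlds per Monte-Carlo check; null distributions of 199–499 iterations; the
p-value calibration check uses 200 structure-free worlds of 8 languages.
These sizes give Monte-Carlo error comfortably inside every stated
tolerance band. All defaults scale up by parameter.
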