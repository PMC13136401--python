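"""Anchor-word projection semantic models.

Every model represents a target concept by its vector of cosine similarities
to a set of anchor vectors in the language's native embedding space, which
makes representations from different languages directly comparable:

* **neurocognitive** — 13 brain-motivated dimensions (color, shape, taste,
  smell, sound, touch, motor; time, space, number, cognition, emotion,
  social), each defined by a hand-picked group of anchor words; the entry for
  (concept, dimension) is the mean cosine to that dimension's anchors.
* **global distributional** — all other target concepts serve as anchors.
* **local distributional** — per concept, its top-k nearest neighbors serve
  as anchors; anchor sets are transferred across a language pair through the
  concept translations.
* **feature** — the most frequently nominated feature-norm words serve as
  anchors.
* **random word / random dimension** — theory-free statistical controls used
  to build permutation null distributions.

Targets that appear among their own anchors are excluded (or the anchor is
excluded, for the feature model) to avoid trivially inflating cross-language
commonality.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .io import EmbeddingTable

logger = logging.getLogger("semscape")

MODEL_NAMES = (
    "neurocognitive", "local", "global", "feature", "random_word", "random_dimension",
)


class AnchorError(ValueError):
    """A dimension has no usable anchor vectors."""


@dataclass
class SemanticSpace:
    """Concepts x model-dimensions matrix of (averaged) cosine similarities."""

    language: str
    model_name: str
    data: pd.DataFrame = field(repr=False)
    anchor_metadata: dict = field(default_factory=dict, repr=False)

    @property
    def concepts(self) -> list[str]:
        return list(self.data.index)

    @property
    def matrix(self) -> np.ndarray:
        return self.data.to_numpy()


def cosine(u, v) -> float:
    """Cosine similarity u.v / (|u||v|); zero vectors are rejected."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine undefined for zero vector")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def _unit(m: np.ndarray) -> np.ndarray:
    return m / np.linalg.norm(m, axis=1, keepdims=True)


def _resolve_targets(emb: EmbeddingTable, targets) -> list[str]:
    if targets is None:
        return list(emb.concepts)
    return [c for c in targets if c in emb.vectors]


def neurocognitive_space(emb: EmbeddingTable, anchors: dict[str, list[str]],
                         targets=None) -> SemanticSpace:
    """Project concepts onto dimension-anchor groups by averaged cosine.

    ``anchors`` maps dimension name -> anchor concept ids.  Anchors without a
    vector in this language are skipped (averaging over the available ones,
    never imputing); a dimension left with zero available anchors is an
    error.  Targets that are themselves anchor words are dropped.
    """
    targets = _resolve_targets(emb, targets)
    anchor_union = {a for lst in anchors.values() for a in lst}
    kept = [c for c in targets if c not in anchor_union]
    dropped = len(targets) - len(kept)
    if dropped:
        logger.info("%s neurocognitive: dropped %d targets overlapping anchors",
                    emb.language, dropped)
    if not kept:
        raise AnchorError(f"{emb.language}: no targets left after anchor-overlap exclusion")
    t_unit = emb.unit_matrix(kept)
    cols = {}
    counts = {}
    for dim_name, dim_anchors in anchors.items():
        avail = [a for a in dim_anchors if a in emb.vectors]
        if not avail:
            raise AnchorError(f"{emb.language}: dimension {dim_name!r} has no available anchors")
        counts[dim_name] = len(avail)
        a_unit = emb.unit_matrix(avail)
        cols[dim_name] = (t_unit @ a_unit.T).mean(axis=1)
    data = pd.DataFrame(cols, index=kept)
    return SemanticSpace(emb.language, "neurocognitive", data,
                         {"anchors": {d: [a for a in lst if a in emb.vectors]
                                      for d, lst in anchors.items()},
                          "available_counts": counts})


def distributional_global_space(emb: EmbeddingTable, targets=None) -> SemanticSpace:
    """Cosines of each target to every other target (self excluded).

    Stored as a square frame in master concept order with NaN on the
    diagonal; pairwise comparisons drop the NaN columns consistently.
    """
    targets = _resolve_targets(emb, targets)
    if len(targets) < 2:
        raise ValueError("global model needs at least 2 targets with vectors")
    u = emb.unit_matrix(targets)
    sims = u @ u.T
    np.fill_diagonal(sims, np.nan)
    data = pd.DataFrame(sims, index=targets, columns=targets)
    return SemanticSpace(emb.language, "global", data, {"anchors": "all-other-targets"})


def knn_anchor_sets(emb: EmbeddingTable, targets, k: int) -> dict[str, list[str]]:
    """Per concept, its top-k nearest target concepts by cosine (self excluded)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    targets = _resolve_targets(emb, targets)
    u = emb.unit_matrix(targets)
    sims = u @ u.T
    np.fill_diagonal(sims, -np.inf)
    out = {}
    for i, c in enumerate(targets):
        order = np.argsort(-sims[i], kind="stable")[: min(k, len(targets) - 1)]
        out[c] = [targets[j] for j in order]
    return out


def distributional_local_pair(emb_a: EmbeddingTable, emb_b: EmbeddingTable,
                              targets=None, k: int = 100,
                              translations=None) -> pd.DataFrame:
    """Pairwise-comparable local-neighborhood representations for (A, B).

    For each shared concept and each direction (A->B, B->A): the anchor set
    is the concept's top-k neighbors in the source language, transferred to
    the other language through the concept translations (identity on shared
    concept ids when ``translations`` is None); both languages' cosine
    vectors to the transferred set are correlated per concept.  Returns a
    frame with per-concept Pearson r for each direction; the pair-level
    representation is their symmetrized average (done by the caller via
    Fisher-z, see :func:`semscape.universality.local_pair_ilc`).
    """
    shared = [c for c in _resolve_targets(emb_a, targets) if c in emb_b.vectors]
    if len(shared) < 2:
        raise ValueError("local model needs >= 2 shared concepts")
    trans_ab = translations or {c: c for c in shared}
    neigh_a = knn_anchor_sets(emb_a, shared, k)
    neigh_b = knn_anchor_sets(emb_b, shared, k)
    rows = {}
    warned = False
    for c in shared:
        rs = []
        for src_neigh, src, dst, mapping in (
            (neigh_a, emb_a, emb_b, trans_ab),
            (neigh_b, emb_b, emb_a, trans_ab),
        ):
            anchors = [mapping.get(a, a) for a in src_neigh[c]]
            anchors = [a for a in anchors if a in src.vectors and a in dst.vectors and a != c]
            if len(anchors) < k and not warned:
                logger.info("local model %s-%s: fewer than k=%d mappable neighbors, using %d",
                            emb_a.language, emb_b.language, k, len(anchors))
                warned = True
            if len(anchors) < 3:
                rs.append(np.nan)
                continue
            va = src.unit_matrix(anchors) @ (src.vectors[c] / np.linalg.norm(src.vectors[c]))
            vb = dst.unit_matrix(anchors) @ (dst.vectors[c] / np.linalg.norm(dst.vectors[c]))
            with np.errstate(invalid="ignore"):
                rs.append(float(np.corrcoef(va, vb)[0, 1]))
        rows[c] = rs
    return pd.DataFrame.from_dict(rows, orient="index", columns=["r_ab", "r_ba"])


def feature_space(emb: EmbeddingTable, feature_words, n_features: int = 100,
                  targets=None) -> SemanticSpace:
    """Cosines of each target to the top-n ranked feature words.

    Feature words missing a vector are skipped with a warning; feature words
    that are themselves target concepts are excluded from the anchor set.
    """
    targets = _resolve_targets(emb, targets)
    target_set = set(targets)
    usable = [w for w in feature_words if w in emb.vectors and w not in target_set]
    n_skipped = sum(1 for w in feature_words[:n_features] if w not in emb.vectors)
    if n_skipped:
        logger.info("%s feature model: %d of top-%d feature words missing vectors",
                    emb.language, n_skipped, n_features)
    chosen = usable[:n_features]
    if not chosen:
        raise AnchorError(f"{emb.language}: no usable feature words")
    t_unit = emb.unit_matrix(targets)
    a_unit = emb.unit_matrix(chosen)
    data = pd.DataFrame(t_unit @ a_unit.T, index=targets, columns=chosen)
    return SemanticSpace(emb.language, "feature", data,
                         {"anchors": chosen, "n_missing_vectors": n_skipped})


def random_word_anchors(master_concepts, n_anchors, rng) -> list[str]:
    """Sample anchor identities once, to be reused across all languages."""
    master = list(master_concepts)
    if n_anchors > len(master):
        raise ValueError("n_anchors exceeds master concept list")
    idx = rng.choice(len(master), size=n_anchors, replace=False)
    return [master[i] for i in idx]


def random_word_space(emb: EmbeddingTable, targets=None, n_anchors: int = 13,
                      rng=None, anchors=None, master_concepts=None) -> SemanticSpace:
    """Statistical control: cosines to randomly sampled anchor words.

    Pass a pre-sampled ``anchors`` list to reuse the same anchor identities
    across the languages of one iteration (the intended use); otherwise the
    anchors are drawn here from ``master_concepts`` (default: this language's
    concepts) with ``rng``.
    """
    targets = _resolve_targets(emb, targets)
    if anchors is None:
        if rng is None:
            raise ValueError("either anchors or rng must be given")
        master = list(master_concepts) if master_concepts is not None else list(emb.concepts)
        anchors = random_word_anchors(master, n_anchors, rng)
    avail = [a for a in anchors if a in emb.vectors]
    if not avail:
        raise AnchorError(f"{emb.language}: no random anchors with vectors")
    kept = [c for c in targets if c not in set(anchors)]
    data = pd.DataFrame(emb.unit_matrix(kept) @ emb.unit_matrix(avail).T,
                        index=kept, columns=avail)
    return SemanticSpace(emb.language, "random_word", data, {"anchors": avail})


def random_dimension_grouping(reference: EmbeddingTable, master_concepts,
                              n_words: int = 100, n_clusters: int = 13,
                              rng=None, max_retries: int = 5) -> dict[str, int]:
    """Sample ``n_words`` anchors and partition them into ``n_clusters`` groups.

    K-means runs on the designated reference language's vectors; the grouping
    (by concept identity) is then applied in every language so that columns
    stay aligned across languages.  An empty cluster triggers a reseeded
    retry up to ``max_retries``.
    """
    if n_words < n_clusters:
        raise ValueError("n_words must be >= n_clusters")
    master = [c for c in master_concepts if c in reference.vectors]
    words = random_word_anchors(master, n_words, rng)
    vecs = reference.matrix(words)
    for _ in range(max_retries):
        seed = int(rng.integers(0, 2**31 - 1))
        km = KMeans(n_clusters=n_clusters, n_init=1, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            labels = km.fit_predict(vecs)
        if len(np.unique(labels)) == n_clusters:
            return {w: int(l) for w, l in zip(words, labels)}
    raise RuntimeError("K-means produced an empty cluster after retries")


def random_dimension_space(emb: EmbeddingTable, grouping: dict[str, int],
                           targets=None, n_clusters: int | None = None) -> SemanticSpace:
    """Project onto the K-means pseudo-dimensions defined by ``grouping``."""
    targets = _resolve_targets(emb, targets)
    kept = [c for c in targets if c not in grouping]
    words = [w for w in grouping if w in emb.vectors]
    if not words:
        raise AnchorError(f"{emb.language}: no grouped anchors with vectors")
    k = n_clusters if n_clusters is not None else max(grouping.values()) + 1
    t_unit = emb.unit_matrix(kept)
    a_unit = emb.unit_matrix(words)
    sims = t_unit @ a_unit.T
    cols = {}
    for g in range(k):
        members = [i for i, w in enumerate(words) if grouping[w] == g]
        if not members:
            raise AnchorError(f"{emb.language}: pseudo-dimension {g} empty")
        cols[f"dim{g}"] = sims[:, members].mean(axis=1)
    data = pd.DataFrame(cols, index=kept)
    return SemanticSpace(emb.language, "random_dimension", data, {"grouping": grouping})
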