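"""Colexification graphs and composite topology distance.

A colexification graph has concepts as nodes and, on each edge, the number
of languages in which one wordform expresses both concepts.  Four topology
metrics summarize first-order, second-order and global network structure
for every concept pair:

* edge weight (0 for non-adjacent pairs),
* weighted common neighbors (sum over shared neighbors of the smaller of
  the two edge weights, by default),
* Louvain community co-membership fraction over seeded runs,
* Infomap community co-membership fraction over seeded runs.

Each metric is min-max normalized over all pairs and the combined
similarity is their mean; topology distance is one minus that.
"""

from __future__ import annotations

import itertools
import logging
import random as _random
from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .spaces import SemanticSpace

logger = logging.getLogger("semscape")


def build_graph(edges: pd.DataFrame, known_concepts=None) -> nx.Graph:
    """Weighted undirected graph from an edge list (duplicates summed).

    Self-loops are dropped with a warning; negative weights are an error;
    with ``known_concepts`` given, unknown endpoints are an error.
    """
    g = nx.Graph()
    known = set(known_concepts) if known_concepts is not None else None
    n_self = 0
    for a, b, w in edges[["concept_a", "concept_b", "n_languages"]].itertuples(index=False):
        w = float(w)
        if w < 0:
            raise ValueError(f"negative weight on edge ({a}, {b})")
        if known is not None and (a not in known or b not in known):
            raise ValueError(f"edge ({a}, {b}) references unknown concept")
        if a == b:
            n_self += 1
            continue
        if g.has_edge(a, b):
            g[a][b]["weight"] += w
        else:
            g.add_edge(a, b, weight=w)
    if n_self:
        logger.warning("build_graph: dropped %d self-loop rows", n_self)
    return g


def common_neighbors(g: nx.Graph, a, b, mode: str = "min") -> float:
    """Weighted common-neighbor score of a pair.

    ``min`` (default) sums min(w(a,z), w(b,z)) over shared neighbors z —
    bounded and symmetric; ``product`` sums w(a,z) * w(b,z).
    """
    if a not in g or b not in g:
        raise KeyError(f"{a!r} or {b!r} not in graph")
    shared = set(g.adj[a]) & set(g.adj[b]) - {a, b}
    if mode == "min":
        return float(sum(min(g[a][z]["weight"], g[b][z]["weight"]) for z in shared))
    if mode == "product":
        return float(sum(g[a][z]["weight"] * g[b][z]["weight"] for z in shared))
    raise ValueError(f"unknown mode {mode!r}")


def _louvain_partition(g: nx.Graph, seed: int) -> dict:
    comms = nx.community.louvain_communities(g, weight="weight", seed=seed)
    return {node: i for i, c in enumerate(comms) for node in c}


def _infomap_partition(g: nx.Graph, seed: int) -> dict:
    nodes = list(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in g.edges]
    weights = [g[u][v]["weight"] for u, v in g.edges]
    graph = ig.Graph(n=len(nodes), edges=edges)
    ig.set_random_number_generator(_random.Random(seed))
    membership = graph.community_infomap(edge_weights=weights).membership
    ig.set_random_number_generator(None)  # restore igraph default RNG
    return {n: membership[index[n]] for n in nodes}


_PARTITIONERS = {"louvain": _louvain_partition, "infomap": _infomap_partition}


def community_comembership(g: nx.Graph, algorithm: str = "louvain",
                           n_runs: int = 10, seed: int = 0) -> pd.DataFrame:
    """Fraction of seeded runs in which each node pair shares a community.

    Both algorithms operate on the whole graph; nodes in different connected
    components never share a community, so components are effectively
    handled independently.
    """
    try:
        partitioner = _PARTITIONERS[algorithm]
    except KeyError:
        raise ValueError(f"community algorithm {algorithm!r} unavailable; "
                         f"choose from {sorted(_PARTITIONERS)}") from None
    nodes = list(g.nodes)
    counts = np.zeros((len(nodes), len(nodes)))
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_runs):
        run_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        part = partitioner(g, run_seed)
        labels = np.array([part[n] for n in nodes])
        counts += labels[:, None] == labels[None, :]
    frac = counts / n_runs
    np.fill_diagonal(frac, 1.0)
    return pd.DataFrame(frac, index=nodes, columns=nodes)


@dataclass
class TopologySimilarity:
    """Per-pair metric table with the min-max-normalized combined score."""

    table: pd.DataFrame = field(repr=False)  # index: (a, b) with a < b
    constant_metrics: tuple[str, ...] = ()

    METRICS = ("edge_weight", "common_neighbors", "louvain_comembership",
               "infomap_comembership")

    def similarity(self, a, b) -> float:
        key = (a, b) if (a, b) in self.table.index else (b, a)
        return float(self.table.loc[key, "combined"])

    def distance_series(self) -> pd.Series:
        return 1.0 - self.table["combined"]


def _minmax(v: np.ndarray):
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.full_like(v, 0.5), True
    return (v - lo) / (hi - lo), False


def combined_similarity(g: nx.Graph, common_neighbor_mode: str = "min",
                        n_runs: int = 10, seed: int = 0) -> TopologySimilarity:
    """Composite topology similarity over all node pairs.

    Pairs without an edge get edge weight 0 (maximal distance contribution
    from that metric).  A metric constant over all pairs contributes 0.5
    uniformly and is flagged.
    """
    nodes = sorted(g.nodes)
    if len(nodes) < 3:
        raise ValueError("need a graph with >= 3 nodes")
    pairs = list(itertools.combinations(nodes, 2))
    ew = np.array([g[a][b]["weight"] if g.has_edge(a, b) else 0.0 for a, b in pairs])
    cn = np.array([common_neighbors(g, a, b, common_neighbor_mode) for a, b in pairs])
    lv = community_comembership(g, "louvain", n_runs, seed)
    im = community_comembership(g, "infomap", n_runs, seed + 1)
    lvv = np.array([lv.loc[a, b] for a, b in pairs])
    imv = np.array([im.loc[a, b] for a, b in pairs])
    cols, constant = {}, []
    for name, vals in zip(TopologySimilarity.METRICS, (ew, cn, lvv, imv)):
        normed, is_const = _minmax(vals)
        cols[name] = normed
        if is_const:
            constant.append(name)
            logger.warning("combined_similarity: metric %s constant, contributes 0.5", name)
    table = pd.DataFrame(cols, index=pd.MultiIndex.from_tuples(pairs, names=["a", "b"]))
    table["combined"] = table[list(TopologySimilarity.METRICS)].mean(axis=1)
    return TopologySimilarity(table, tuple(constant))


def semantic_pair_distances(space: SemanticSpace | pd.DataFrame, concepts) -> pd.Series:
    """1 - Pearson correlation between concept rows of one language's space."""
    df = space.data if isinstance(space, SemanticSpace) else space
    concepts = [c for c in concepts if c in df.index]
    m = df.loc[concepts].to_numpy(dtype=float)
    r = np.corrcoef(m)
    pairs = list(itertools.combinations(range(len(concepts)), 2))
    idx = pd.MultiIndex.from_tuples([(concepts[i], concepts[j]) for i, j in pairs],
                                    names=["a", "b"])
    return pd.Series([1.0 - r[i, j] for i, j in pairs], index=idx)


def topology_null_spearman(tables, topo: TopologySimilarity, targets=None,
                           kind: str = "random_dimension", n_words: int = 100,
                           n_clusters: int = 13, n_anchors: int = 13,
                           n_iters: int = 1000, rng=None,
                           reference_index: int = 0) -> np.ndarray:
    """Null distribution of the mean semantic-vs-topology Spearman rho.

    Each iteration replaces the anchor model with a random-word or
    random-dimension control (same anchor identities across languages),
    recomputes per-language semantic pair distances and their Spearman
    correlation with the fixed topology distances, and averages over
    languages.  Shares the cosine precomputation with the ILC nulls, so
    thousand-iteration runs stay cheap.
    """
    from .universality import _NullEngine  # deferred: avoids import cycle
    rng = np.random.default_rng(rng)
    eng = _NullEngine(tables, targets)
    topo_dist = topo.distance_series()
    pos = {c: i for i, c in enumerate(eng.targets)}
    pair_rows, pair_cols, keep = [], [], []
    for (a, b), d in topo_dist.items():
        if a in pos and b in pos:
            pair_rows.append(pos[a])
            pair_cols.append(pos[b])
            keep.append(d)
    if len(keep) < 10:
        raise ValueError("fewer than 10 concept pairs shared with the topology table")
    pair_rows = np.asarray(pair_rows)
    pair_cols = np.asarray(pair_cols)
    topo_vec = np.asarray(keep, dtype=float)

    def stat_from_stack(stack: np.ndarray) -> float:
        rhos = []
        for l in range(stack.shape[0]):
            m = stack[l]
            valid = np.isfinite(m).all(axis=1)
            r = np.corrcoef(m[valid]) if valid.all() else None
            if r is None:
                idx = np.where(valid)[0]
                remap = -np.ones(len(m), dtype=int)
                remap[idx] = np.arange(len(idx))
                r_full = np.corrcoef(m[idx])
                ok = valid[pair_rows] & valid[pair_cols]
                sem = 1.0 - r_full[remap[pair_rows[ok]], remap[pair_cols[ok]]]
                tv = topo_vec[ok]
            else:
                sem = 1.0 - r[pair_rows, pair_cols]
                tv = topo_vec
            rhos.append(stats.spearmanr(sem, tv).statistic)
        return float(np.mean(rhos))

    samples = []
    for _ in range(n_iters):
        if kind == "random_dimension":
            grouping = None
            from .spaces import random_dimension_grouping
            grouping = random_dimension_grouping(
                eng.tables[reference_index], eng.master, n_words, n_clusters, rng)
            words = list(grouping)
            w_idx = [eng.master.index(w) for w in words]
            indic = np.zeros((len(words), n_clusters))
            for i, w in enumerate(words):
                indic[i, grouping[w]] = 1.0
            indic /= indic.sum(axis=0, keepdims=True)
            stack = eng.cos[:, :, w_idx] @ indic
            stack = eng._mask_anchor_targets(stack, words)
        elif kind == "random_word":
            idx = rng.choice(len(eng.master), size=n_anchors, replace=False)
            stack = eng._mask_anchor_targets(eng.cos[:, :, idx],
                                             [eng.master[i] for i in idx])
        else:
            raise ValueError(f"unknown kind {kind!r}")
        samples.append(stat_from_stack(stack))
    return np.array(samples)


def correlate_semantic_vs_topology(spaces: dict[str, SemanticSpace],
                                   topo: TopologySimilarity,
                                   shared_concepts=None):
    """Per-language Spearman between semantic and topology distances.

    For each language, pairwise semantic distance (1 - Pearson between
    concept rows) is rank-correlated with topology distance over the shared
    concept pairs; the mean over languages is the generalization statistic
    fed to the permutation null.  Ties get average ranks (scipy default).
    """
    topo_dist = topo.distance_series()
    topo_concepts = {c for pair in topo_dist.index for c in pair}
    rhos = {}
    for lang, space in spaces.items():
        df = space.data if isinstance(space, SemanticSpace) else space
        concepts = sorted(set(df.index) & topo_concepts)
        if shared_concepts is not None:
            concepts = [c for c in concepts if c in set(shared_concepts)]
        sem = semantic_pair_distances(space, concepts)
        common = sem.index.intersection(topo_dist.index)
        if len(common) < 10:
            raise ValueError(f"{lang}: fewer than 10 shared concept pairs")
        rho = stats.spearmanr(sem.loc[common], topo_dist.loc[common]).statistic
        rhos[lang] = float(rho)
    per_language = pd.Series(rhos)
    return per_language, float(per_language.mean())
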