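"""Ground-truth synthetic worlds for parameter-recovery and calibration tests.

A world emulates the statistical structure every downstream stage assumes:

* K languages in F families with a known rooted family tree;
* a shared latent concept x 13 loading matrix ``L`` with sparse block
  structure (each concept loads high on 1-3 dimensions), including
  designated anchor concepts whose loading concentrates on one dimension so
  the anchor specification is recoverable by construction;
* per-language embeddings that are rotated, climate-modulated,
  noise-corrupted realizations of the latent structure;
* a latent climate factor, spatially/phylogenetically correlated through
  family-level intraclass correlation, realized as 19 bioclim-style
  variables whose first principal component tracks the factor;
* colexification edges sampled from latent similarity, ratings as noisy
  affine readouts of the latent loadings, and neural RDMs as mixtures of the
  semantic RDM, the climate RDM and independent noise.

Climate modulates the structural route in two ways: a multiplicative
(log-linear) per-dimension scaling, and an additive deflection of selected
dimensions' loading patterns along a fixed direction, proportional to the
language's latent climate factor.  The deflection is what makes
per-dimension correlation distances climate-linked (a pure column rescaling
would be invisible to Pearson correlation).

For mixed-model recovery the world also provides a calibrated pair-level
response (:func:`planted_pair_table`): the planted standardized climate
coefficient there is exact by construction, with crossed family intercepts
and residual noise whose variances sum to one.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

from . import envdist
from .io import EmbeddingTable
from .rdm import RDM
from .tree import FamilyTree

logger = logging.getLogger("semscape")

DIMENSIONS = (
    "color", "shape", "taste", "smell", "sound", "touch", "motor",
    "time", "space", "number", "cognition", "emotion", "social",
)


@dataclass
class WorldParams:
    n_families: int = 5
    langs_per_family: int = 6
    tree_depth: int | None = None
    n_target_concepts: int = 60
    anchors_per_dim: int = 4
    embed_dim: int = 50
    noise_sd: float = 0.3
    # pair-level planted effect (standardized scale)
    planted_beta_climate: float = 0.5
    family_variance: float = 0.05
    # climate generation
    climate_icc: float = 0.5
    n_climate_vars: int = 19
    # structural climate modulation
    scaling_beta: float = 0.2
    scaling_family_sd: float = 0.1
    scaling_noise_sd: float = 0.05
    climate_deflection: float | np.ndarray = 0.15
    # language-idiosyncratic embedding structure (distributional variation
    # not shared across languages, on top of the 13 shared dimensions)
    n_idio_dims: int = 15
    idio_scale: float = 0.6
    # anchor words are hand-picked for cross-linguistically stable reference,
    # so they carry little idiosyncrasy; ordinary words are heterogeneous
    # (log-normal weights with a heavy tail)
    anchor_idio_weight: float = 0.3
    idio_tail_sd: float = 0.8
    # set False for no-structure (pure noise) calibration worlds
    structured: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 2:
            raise ValueError("n_families must be >= 2")
        if self.langs_per_family < 1:
            raise ValueError("langs_per_family must be >= 1")
        if self.embed_dim < len(DIMENSIONS) + self.n_idio_dims:
            raise ValueError(
                f"embed_dim must be >= {len(DIMENSIONS)} + n_idio_dims ({self.n_idio_dims})")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        resid = 1.0 - self.planted_beta_climate**2 - 2 * self.family_variance
        if resid <= 0:
            raise ValueError("planted_beta_climate^2 + 2*family_variance must be < 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(d["climate_deflection"], np.ndarray):
            d["climate_deflection"] = d["climate_deflection"].tolist()
        return d


def make_family_tree(n_families: int, langs_per_family: int,
                     depth: int | None = None, seed: int = 0) -> FamilyTree:
    """Random rooted tree with families at depth 1 and all leaves at equal depth.

    Every leaf sits exactly ``depth`` steps below its family node (binary
    splits padded with unary chains), so within-family path distances are
    strictly smaller than between-family ones.
    """
    if n_families < 2:
        raise ValueError("n_families must be >= 2")
    if langs_per_family < 1:
        raise ValueError("langs_per_family must be >= 1")
    if depth is None:
        depth = max(1, math.ceil(math.log2(max(langs_per_family, 2))))
    if depth < 1 or 2**depth < langs_per_family:
        raise ValueError(f"depth {depth} cannot host {langs_per_family} leaves")
    rng = np.random.default_rng(seed)
    g = nx.DiGraph()
    g.add_node("ROOT")
    counter = [0]

    def attach(parent: str, leaves: list[str], d: int) -> None:
        if d == 1:
            for leaf in leaves:
                g.add_edge(parent, leaf)
            return
        if len(leaves) == 1:
            counter[0] += 1
            node = f"n{counter[0]}"
            g.add_edge(parent, node)
            attach(node, leaves, d - 1)
            return
        order = list(rng.permutation(len(leaves)))
        half = len(leaves) // 2
        for part in (order[:half], order[half:]):
            counter[0] += 1
            node = f"n{counter[0]}"
            g.add_edge(parent, node)
            attach(node, [leaves[i] for i in part], d - 1)

    for f in range(n_families):
        fam = f"F{f}"
        g.add_edge("ROOT", fam)
        leaves = [f"f{f}l{i}" for i in range(langs_per_family)]
        attach(fam, leaves, depth)
    return FamilyTree(g)


@dataclass
class SynthWorld:
    params: WorldParams
    tree: FamilyTree = field(repr=False)
    languages: list[str] = field(repr=False)
    families: dict[str, str] = field(repr=False)
    target_concepts: list[str] = field(repr=False)
    anchor_spec: dict[str, list[str]] = field(repr=False)
    loadings: pd.DataFrame = field(repr=False)           # concepts x 13 latent L
    deflection: pd.DataFrame = field(repr=False)         # concepts x 13 direction
    gamma: np.ndarray = field(repr=False)                # per-dimension deflection strength
    climate_factor: pd.Series = field(repr=False)        # latent factor per language
    climate: pd.DataFrame = field(repr=False)            # languages x 19 bioclim-style
    coords: pd.DataFrame = field(repr=False)             # languages x (lat, lon)
    culture: RDM = field(repr=False)
    scaling: pd.DataFrame = field(repr=False)            # languages x 13, s_l > 0
    rotations: dict[str, np.ndarray] = field(repr=False)
    idiosyncratic: dict[str, np.ndarray] = field(repr=False)  # per-language concepts x n_idio
    idio_weights: pd.Series = field(repr=False)               # per-concept idiosyncrasy weight

    @property
    def concepts(self) -> list[str]:
        return list(self.loadings.index)

    def language_matrix(self, lang: str) -> pd.DataFrame:
        """Noise-free language-level concept x 13 loading matrix."""
        s = self.scaling.loc[lang].to_numpy()
        c = float(self.climate_factor[lang])
        m = self.loadings.to_numpy() + c * self.deflection.to_numpy() * self.gamma[None, :]
        return pd.DataFrame(m * s[None, :], index=self.concepts, columns=DIMENSIONS)

    def language_matrices(self) -> dict[str, pd.DataFrame]:
        return {l: self.language_matrix(l) for l in self.languages}


def _random_rotation(dim: int, rng) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((dim, dim)))
    return q * np.sign(np.diag(r))


def generate_world(params: WorldParams) -> SynthWorld:
    p = params
    rng = np.random.default_rng(p.seed)
    tree = make_family_tree(p.n_families, p.langs_per_family, p.tree_depth,
                            seed=int(rng.integers(2**31 - 1)))
    languages = sorted(tree.leaves)
    families = tree.family_map()
    n_dims = len(DIMENSIONS)

    # latent loadings: anchors concentrated on one dimension, targets block-sparse
    anchor_spec: dict[str, list[str]] = {}
    rows, names = [], []
    for d, dim_name in enumerate(DIMENSIONS):
        anchor_spec[dim_name] = []
        for i in range(p.anchors_per_dim):
            cid = f"a_{dim_name}_{i}"
            anchor_spec[dim_name].append(cid)
            row = rng.uniform(0.0, 0.1, size=n_dims)
            row[d] = rng.uniform(0.85, 1.0)
            rows.append(row)
            names.append(cid)
    targets = [f"t{i:03d}" for i in range(p.n_target_concepts)]
    for t in targets:
        row = rng.uniform(0.0, 0.2, size=n_dims)
        k = rng.integers(1, 4)
        hot = rng.choice(n_dims, size=k, replace=False)
        row[hot] = rng.uniform(0.6, 1.0, size=k)
        rows.append(row)
        names.append(t)
    loadings = pd.DataFrame(rows, index=names, columns=DIMENSIONS)
    if not p.structured:
        loadings = pd.DataFrame(rng.uniform(0.0, 1.0, size=loadings.shape),
                                index=names, columns=DIMENSIONS)

    # latent climate factor with family-level intraclass correlation
    fam_effect = {f: rng.standard_normal() for f in tree.families}
    raw = np.array([
        math.sqrt(p.climate_icc) * fam_effect[families[l]]
        + math.sqrt(1 - p.climate_icc) * rng.standard_normal()
        for l in languages
    ])
    c1 = (raw - raw.mean()) / raw.std(ddof=0)
    climate_factor = pd.Series(c1, index=languages)
    c2 = rng.standard_normal(len(languages))
    c2 = (c2 - c2.mean()) / c2.std(ddof=0)
    load1 = np.concatenate([rng.uniform(0.7, 1.0, size=p.n_climate_vars // 2 + 1),
                            rng.uniform(-0.3, 0.3, size=p.n_climate_vars - p.n_climate_vars // 2 - 1)])
    load2 = np.concatenate([rng.uniform(-0.2, 0.2, size=p.n_climate_vars // 2 + 1),
                            rng.uniform(0.5, 0.8, size=p.n_climate_vars - p.n_climate_vars // 2 - 1)])
    climate = pd.DataFrame(
        np.outer(c1, load1) + np.outer(c2, load2)
        + 0.25 * rng.standard_normal((len(languages), p.n_climate_vars)),
        index=languages, columns=list(envdist.BIOCLIM_VARS[: p.n_climate_vars]),
    )

    # family-clustered coordinates and culture space
    fam_lat = {f: rng.uniform(-55, 55) for f in tree.families}
    fam_lon = {f: rng.uniform(-150, 150) for f in tree.families}
    coords = pd.DataFrame({
        "lat": [np.clip(fam_lat[families[l]] + rng.uniform(-8, 8), -90, 90) for l in languages],
        "lon": [np.clip(fam_lon[families[l]] + rng.uniform(-8, 8), -180, 180) for l in languages],
    }, index=languages)
    fam_culture = {f: rng.standard_normal(5) for f in tree.families}
    pts = np.stack([fam_culture[families[l]] + 0.5 * rng.standard_normal(5) for l in languages])
    from scipy.spatial.distance import pdist, squareform
    culture = RDM(languages, squareform(pdist(pts)))

    # per-dimension scaling: log-linear in the latent climate factor
    if p.structured:
        h = rng.uniform(0.5, 1.0, size=n_dims)
        fam_s = {f: rng.standard_normal(n_dims) * p.scaling_family_sd for f in tree.families}
        log_s = np.stack([
            p.scaling_beta * climate_factor[l] * h
            + fam_s[families[l]]
            + p.scaling_noise_sd * rng.standard_normal(n_dims)
            for l in languages
        ])
    else:
        log_s = np.zeros((len(languages), n_dims))
    scaling = pd.DataFrame(np.exp(log_s), index=languages, columns=DIMENSIONS)

    # deflection direction and per-dimension strengths
    defl = rng.standard_normal(loadings.shape)
    defl /= np.linalg.norm(defl, axis=0, keepdims=True)
    gamma = np.asarray(p.climate_deflection, dtype=float)
    if gamma.ndim == 0:
        gamma = np.full(n_dims, float(gamma))
    if not p.structured:
        gamma = np.zeros(n_dims)

    rotations = {l: _random_rotation(p.embed_dim, rng) for l in languages}
    # language-idiosyncratic latent loadings: unit-variance per coordinate,
    # scaled at emission time relative to the shared-signal norm
    idio = {l: rng.standard_normal((len(names), p.n_idio_dims)) / np.sqrt(max(p.n_idio_dims, 1))
            for l in languages}
    # hand-picked anchors are cross-linguistically stable; ordinary words are
    # heterogeneous with a heavy tail.  In unstructured worlds the anchor
    # labels are arbitrary, so all concepts draw from the same distribution
    # (keeps anchor identity exchangeable with random draws).
    weights = pd.Series(np.exp(rng.normal(0.0, p.idio_tail_sd, size=len(names))), index=names)
    if p.structured:
        anchor_union = [c for lst in anchor_spec.values() for c in lst]
        weights.loc[anchor_union] = p.anchor_idio_weight
    return SynthWorld(p, tree, languages, families, targets, anchor_spec,
                      loadings, pd.DataFrame(defl, index=names, columns=DIMENSIONS),
                      gamma, climate_factor, climate, coords, culture,
                      scaling, rotations, idio, weights)


# ---------------------------------------------------------------------------
# emitters
# ---------------------------------------------------------------------------

def emit_embeddings(world: SynthWorld, dim: int | None = None,
                    noise_sd: float | None = None, idio_scale: float | None = None,
                    shared_rotation: bool = False, seed: int = 1) -> list[EmbeddingTable]:
    """Per-language embedding tables realizing the latent structure.

    A concept's vector in language ``l`` is the rotated, zero-padded
    concatenation of the climate-modulated shared loading row and the
    language's idiosyncratic loadings, plus isotropic Gaussian noise.  Both
    corruption scales are relative to the mean shared-signal norm:
    ``noise_sd`` sets the expected unstructured noise norm and
    ``idio_scale`` the expected norm of the structured language-specific
    component (distributional variation a language does not share), so 0.3
    means roughly 30% corruption regardless of the embedding dimension.
    """
    p = world.params
    dim = dim or p.embed_dim
    if dim < len(DIMENSIONS) + p.n_idio_dims:
        raise ValueError(f"dim must be >= {len(DIMENSIONS) + p.n_idio_dims}")
    noise_sd = p.noise_sd if noise_sd is None else noise_sd
    idio_scale = p.idio_scale if idio_scale is None else idio_scale
    rng = np.random.default_rng((p.seed, seed))
    tables = []
    shared_rot = world.rotations[world.languages[0]]
    for l in world.languages:
        m = world.language_matrix(l).to_numpy()
        signal_norm = float(np.mean(np.linalg.norm(m, axis=1)))
        padded = np.zeros((m.shape[0], dim))
        padded[:, : m.shape[1]] = m
        if p.n_idio_dims and idio_scale:
            padded[:, m.shape[1]: m.shape[1] + p.n_idio_dims] = (
                idio_scale * signal_norm * world.idiosyncratic[l]
                * world.idio_weights.to_numpy()[:, None])
        rot = shared_rot if shared_rotation else world.rotations[l]
        if rot.shape[0] != dim:
            rot = _random_rotation(dim, np.random.default_rng((p.seed, seed, 7)))
        coord_sd = noise_sd * signal_norm / np.sqrt(dim)
        vecs = padded @ rot.T + coord_sd * rng.standard_normal(padded.shape)
        # an exactly-zero vector is astronomically unlikely; guard anyway
        norms = np.linalg.norm(vecs, axis=1)
        vecs[norms == 0, 0] = 1e-9
        tables.append(EmbeddingTable(
            language=l, dim=dim,
            vectors={c: vecs[i] for i, c in enumerate(world.concepts)},
        ))
    return tables


def emit_colex_edges(world: SynthWorld, density: float = 0.2,
                     n_pseudolanguages: int = 50, steepness: float = 6.0,
                     seed: int = 2) -> pd.DataFrame:
    """Colexification edge list sampled from latent similarity.

    For each target-concept pair the per-pseudolanguage colexification
    probability is a logistic function of latent loading-row similarity,
    normalized so its mean matches ``density``; the edge weight is the
    binomial count of pseudolanguages colexifying the pair.  An empty
    result (density too low) is flagged with a warning.
    """
    if not 0.0 < density < 1.0:
        raise ValueError("density must be in (0, 1)")
    rng = np.random.default_rng((world.params.seed, seed))
    l = world.loadings.loc[world.target_concepts].to_numpy()
    z = (l - l.mean(axis=1, keepdims=True))
    z /= np.linalg.norm(z, axis=1, keepdims=True)
    sim = z @ z.T
    iu = np.triu_indices(len(world.target_concepts), k=1)
    s = sim[iu]
    u = 1.0 / (1.0 + np.exp(-steepness * (s - np.median(s))))
    # per-pseudolanguage colexification probability, mean scaled by density;
    # the 8/n factor keeps expected edge weights in the single digits so the
    # graph stays sparse at low density
    pi = np.clip(density * (u / u.mean()) * 8.0 / n_pseudolanguages, 0.0, 1.0)
    w = rng.binomial(n_pseudolanguages, pi)
    rows = [(world.target_concepts[i], world.target_concepts[j], int(wk))
            for i, j, wk in zip(iu[0], iu[1], w) if wk > 0]
    edges = pd.DataFrame(rows, columns=["concept_a", "concept_b", "n_languages"])
    if edges.empty:
        logger.warning("emit_colex_edges: empty edge list at density %g", density)
    else:
        g = nx.Graph()
        g.add_edges_from(edges[["concept_a", "concept_b"]].itertuples(index=False))
        if not nx.is_connected(g):
            logger.info("emit_colex_edges: graph not connected (%d components)",
                        nx.number_connected_components(g))
    return edges


def emit_ratings(world: SynthWorld, participants_per_language: int = 6,
                 rater_noise_sd: float = 1.0, n_careless: int = 0,
                 seed: int = 3) -> pd.DataFrame:
    """Participant rating table on the 0-6 scale with demographics attached.

    Ratings are a fixed affine map of the language-level loading matrix into
    [0, 6] plus participant noise, clipped to the scale; ``n_careless``
    participants per world rate pure uniform noise (quality-control bait).
    """
    if participants_per_language < 2:
        raise ValueError("participants_per_language must be >= 2")
    p = world.params
    rng = np.random.default_rng((p.seed, seed))
    mats = world.language_matrices()
    lo = min(m.to_numpy().min() for m in mats.values())
    hi = max(m.to_numpy().max() for m in mats.values())
    span = hi - lo if hi > lo else 1.0
    rows = []
    pid = 0
    careless_ids = set(range(n_careless))
    for l in world.languages:
        base = 6.0 * (mats[l].to_numpy() - lo) / span
        for _ in range(participants_per_language):
            name = f"p{pid:04d}"
            if pid in careless_ids:
                vals = rng.uniform(0.0, 6.0, size=base.shape)
            else:
                vals = np.clip(base + rater_noise_sd * rng.standard_normal(base.shape), 0.0, 6.0)
            age = float(np.clip(rng.normal(35, 12), 18, 83))
            gender = "female" if rng.random() < 0.5 else "male"
            edu = int(rng.integers(1, 6))
            ses = int(rng.integers(1, 11))
            for ci, c in enumerate(world.concepts):
                for di, d in enumerate(DIMENSIONS):
                    rows.append((name, l, c, d, vals[ci, di], age, gender, edu, ses))
            pid += 1
    return pd.DataFrame(rows, columns=["participant", "language", "concept", "dimension",
                                       "rating", "age", "gender", "education", "ses"])


DEFAULT_ROIS = (
    "l-IFG", "l-IFGorb", "l-MFG", "l-ATL", "l-MTG", "l-AG",
    "r-IFG", "r-IFGorb", "r-MFG", "r-ATL", "r-MTG", "r-AG",
)


def emit_neural_rdms(world: SynthWorld, lambda_sem: float = 0.5,
                     lambda_clim: float = 0.3, noise_sd: float = 1.0,
                     rois=DEFAULT_ROIS, planted_roi: str = "r-ATL",
                     seed: int = 4) -> dict[str, RDM]:
    """Language-level neural RDMs: one planted ROI mixes the semantic and
    climate RDMs with noise; all other ROIs are pure noise."""
    if lambda_sem < 0 or lambda_clim < 0:
        raise ValueError("mixture weights must be >= 0")
    rng = np.random.default_rng((world.params.seed, seed))
    sem = semantic_truth_rdm(world)
    clim = envdist.climate_distance(world.climate)

    def std(v):
        return (v - v.mean()) / v.std(ddof=0) if v.std(ddof=0) > 0 else v

    sem_v = std(sem.condensed())
    clim_v = std(clim.subset(sem.labels).condensed())
    out = {}
    for roi in rois:
        noise = rng.standard_normal(len(sem_v))
        if roi == planted_roi:
            v = lambda_sem * sem_v + lambda_clim * clim_v + noise_sd * noise
        else:
            v = noise
        out[roi] = RDM.from_condensed(sem.labels, v)
    return out


def concept_domains(world: SynthWorld) -> dict[str, str]:
    """Map each target concept to a domain named after its dominant latent
    dimension — the natural taxonomy for domain-level summaries of the
    climate-projected semantic maps."""
    sub = world.loadings.loc[world.target_concepts]
    return {c: str(sub.loc[c].idxmax()) for c in world.target_concepts}


def semantic_truth_rdm(world: SynthWorld) -> RDM:
    """Ground-truth semantic RDM from the noise-free language matrices
    (1 - Pearson over flattened concept x dimension cells)."""
    mats = world.language_matrices()
    flat = np.stack([mats[l].to_numpy().ravel() for l in world.languages])
    r = np.corrcoef(flat)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return RDM(world.languages, d)


# ---------------------------------------------------------------------------
# calibrated pair-level response for mixed-model recovery
# ---------------------------------------------------------------------------

def environment_rdms(world: SynthWorld) -> dict[str, RDM]:
    return {
        "climate": envdist.climate_distance(world.climate),
        "culture": world.culture,
        "geography": envdist.geodesic_distance(world.coords),
        "linguistic_history": envdist.tree_distance_matrix(world.tree, world.languages),
    }


def planted_pair_table(world: SynthWorld, seed: int = 5) -> pd.DataFrame:
    """Language-pair table whose response carries the planted climate effect.

    The response is built directly on the standardized scale:
    ``y = beta * z(climate_dist) + u[family_i] + u[family_j] + eps`` with
    ``Var(u) = family_variance`` per side and residual variance chosen so
    the total is 1.  Environmental predictor columns are standardized;
    the response is left on its construction scale (sd approximately 1).
    """
    p = world.params
    rng = np.random.default_rng((p.seed, seed))
    env = environment_rdms(world)
    langs = world.languages
    iu_pairs = RDM(langs, np.zeros((len(langs), len(langs)))).pairs()

    def std(v):
        return (v - v.mean()) / v.std(ddof=1)

    cols = {name: std(rdm.subset(langs).condensed()) for name, rdm in env.items()}
    resid_var = 1.0 - p.planted_beta_climate**2 - 2 * p.family_variance
    u = {f: math.sqrt(p.family_variance) * rng.standard_normal() for f in world.tree.families}
    eps = math.sqrt(resid_var) * rng.standard_normal(len(iu_pairs))
    fam_i = [world.families[a] for a, _ in iu_pairs]
    fam_j = [world.families[b] for _, b in iu_pairs]
    y = (p.planted_beta_climate * cols["climate"]
         + np.array([u[f] for f in fam_i]) + np.array([u[f] for f in fam_j]) + eps)
    df = pd.DataFrame({
        "lang_i": [a for a, _ in iu_pairs],
        "lang_j": [b for _, b in iu_pairs],
        "family_i": fam_i,
        "family_j": fam_j,
        "semantic_distance": y,
        **cols,
    })
    return df
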