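"""Cross-language / cross-subject commonality metrics and permutation nulls.

The central statistic is the inter-language correlation (ILC): for each
concept, the Pearson correlation between two languages' anchor-projected
representation vectors, Fisher r-to-z transformed and averaged over
concepts.  A model's universality is benchmarked against null distributions
built from the random-word and random-dimension control models, with the
one-tailed permutation p-value convention p = (1 + #{null >= observed}) /
(n_iters + 1), which is never exactly zero.

A complementary PCA measure treats languages as features and concept x
dimension cells as samples; the variance explained by the first principal
component of the (correlation-scaled) language matrix estimates the shared
structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .spaces import SemanticSpace, random_dimension_grouping

logger = logging.getLogger("semscape")

#: correlations are clipped to +/-(1 - R_CLIP_EPS) before atanh
R_CLIP_EPS = 1e-7
Z_CLIP = float(np.arctanh(1.0 - R_CLIP_EPS))


def fisher_z(r):
    """Fisher r-to-z (atanh), with r clipped away from +/-1 first."""
    r = np.asarray(r, dtype=float)
    if np.any(np.isnan(r)):
        raise ValueError("NaN correlation passed to fisher_z")
    out = np.arctanh(np.clip(r, -1.0 + R_CLIP_EPS, 1.0 - R_CLIP_EPS))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# inter-language correlation
# ---------------------------------------------------------------------------

@dataclass
class ILCResult:
    mean_z: float
    per_concept_z: pd.Series = field(repr=False)
    n_skipped: int = 0


def _masked_row_correlations(a: np.ndarray, b: np.ndarray, min_cols: int = 3):
    """Row-wise Pearson r between two (n, d) arrays with NaN cells dropped
    pairwise.  Returns (r, n_valid_cols) with NaN where undefined."""
    mask = np.isfinite(a) & np.isfinite(b)
    n = mask.sum(axis=1).astype(float)
    aa = np.where(mask, a, 0.0)
    bb = np.where(mask, b, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ma = aa.sum(1) / n
        mb = bb.sum(1) / n
        da = np.where(mask, a - ma[:, None], 0.0)
        db = np.where(mask, b - mb[:, None], 0.0)
        cov = (da * db).sum(1)
        va = (da * da).sum(1)
        vb = (db * db).sum(1)
        r = cov / np.sqrt(va * vb)
    r[n < min_cols] = np.nan
    return r, n


def ilc(space_a: SemanticSpace | pd.DataFrame, space_b: SemanticSpace | pd.DataFrame) -> ILCResult:
    """Mean Fisher-z ILC between two semantic spaces.

    Concepts are matched on the index intersection and dimensions on the
    column intersection; per concept, cells that are NaN in either language
    (e.g. the self-diagonal of the global model) are dropped pairwise.
    Concepts with fewer than 3 aligned cells or zero variance are skipped,
    with the count reported.
    """
    da = space_a.data if isinstance(space_a, SemanticSpace) else space_a
    db = space_b.data if isinstance(space_b, SemanticSpace) else space_b
    concepts = da.index.intersection(db.index)
    cols = da.columns.intersection(db.columns)
    if len(concepts) < 2:
        raise ValueError("need at least 2 shared concepts")
    if len(cols) < 3:
        raise ValueError("need at least 3 aligned columns")
    a = da.loc[concepts, cols].to_numpy(dtype=float)
    b = db.loc[concepts, cols].to_numpy(dtype=float)
    r, _ = _masked_row_correlations(a, b)
    valid = np.isfinite(r)
    n_skipped = int((~valid).sum())
    if n_skipped:
        logger.debug("ilc: skipped %d concepts (zero variance or too few cells)", n_skipped)
    z = pd.Series(fisher_z(r[valid]), index=concepts[valid])
    if z.empty:
        raise ValueError("no concept yields a defined correlation")
    return ILCResult(float(z.mean()), z, n_skipped)


@dataclass
class ILCMatrix:
    """Pairwise mean Fisher-z values over languages (or participants)."""

    labels: list[str]
    z: np.ndarray = field(repr=False)
    n_concepts: np.ndarray = field(repr=False)

    def pair_values(self) -> pd.Series:
        iu = np.triu_indices(len(self.labels), k=1)
        idx = [f"{self.labels[i]}|{self.labels[j]}" for i, j in zip(*iu)]
        return pd.Series(self.z[iu], index=idx)

    @property
    def mean_z(self) -> float:
        iu = np.triu_indices(len(self.labels), k=1)
        return float(self.z[iu].mean())


def ilc_matrix(spaces: dict[str, SemanticSpace]) -> ILCMatrix:
    labels = list(spaces)
    n = len(labels)
    z = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            res = ilc(spaces[labels[i]], spaces[labels[j]])
            z[i, j] = z[j, i] = res.mean_z
            counts[i, j] = counts[j, i] = len(res.per_concept_z)
    return ILCMatrix(labels, z, counts)


def mean_ilc(spaces: dict[str, SemanticSpace]) -> float:
    """Mean Fisher-z ILC over all unordered language pairs."""
    return ilc_matrix(spaces).mean_z


def local_pair_ilc(pair_frame: pd.DataFrame) -> ILCResult:
    """Symmetrized local-model ILC from a per-concept (r_ab, r_ba) frame.

    Each direction's r is Fisher-z transformed and the two directions
    averaged per concept before averaging over concepts.
    """
    vals = pair_frame.to_numpy(dtype=float)
    valid = np.isfinite(vals).all(axis=1)
    z = np.arctanh(np.clip(vals[valid], -1 + R_CLIP_EPS, 1 - R_CLIP_EPS)).mean(axis=1)
    series = pd.Series(z, index=pair_frame.index[valid])
    return ILCResult(float(series.mean()), series, int((~valid).sum()))


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

@dataclass
class WilcoxonResult:
    statistic: float
    pvalue: float
    n: int
    median_diff: float
    ci_low: float
    ci_high: float


def compare_models(ilc_pairs_a, ilc_pairs_b, n_boot: int = 2000, rng=None) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired per-pair ILC values.

    Uses the exact null distribution for n <= 25 and the normal
    approximation above that.  The median difference is reported with a
    seeded bootstrap percentile 95% CI.
    """
    a = np.asarray(ilc_pairs_a, dtype=float)
    b = np.asarray(ilc_pairs_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    if np.all(d == 0):
        logger.warning("compare_models: all paired differences are zero")
        return WilcoxonResult(0.0, 1.0, len(d), 0.0, 0.0, 0.0)
    method = "exact" if len(d) <= 25 else "approx"
    res = stats.wilcoxon(a, b, alternative="two-sided", method=method)
    rng = np.random.default_rng(rng)
    boots = np.median(rng.choice(d, size=(n_boot, len(d)), replace=True), axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return WilcoxonResult(float(res.statistic), float(res.pvalue), len(d),
                          float(np.median(d)), float(lo), float(hi))


def fdr_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values."""
    from statsmodels.stats.multitest import multipletests
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# PCA universality
# ---------------------------------------------------------------------------

def pca_universality(spaces: dict[str, SemanticSpace], shared_concepts=None) -> float:
    """PC1 explained-variance share with languages as features.

    Each language's concept x dimension matrix (restricted to concepts
    shared by all languages) is reshaped to a vector of samples; language
    columns are centered and unit-scaled (correlation PCA), so fully
    independent languages tend toward a PC1 share of 1/n_languages.
    """
    if len(spaces) < 2:
        raise ValueError("need at least 2 languages")
    frames = {l: (s.data if isinstance(s, SemanticSpace) else s) for l, s in spaces.items()}
    concepts = None
    for df in frames.values():
        concepts = df.index if concepts is None else concepts.intersection(df.index)
    if shared_concepts is not None:
        concepts = concepts.intersection(pd.Index(shared_concepts))
    cols = None
    for df in frames.values():
        cols = df.columns if cols is None else cols.intersection(df.columns)
    mat = np.column_stack([frames[l].loc[concepts, cols].to_numpy(dtype=float).ravel()
                           for l in frames])
    keep = np.isfinite(mat).all(axis=1)
    mat = mat[keep]
    if mat.shape[0] < 2:
        raise ValueError("fewer than 2 usable samples for PCA")
    mat = mat - mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant language column in PCA input")
    mat = mat / sd
    s = np.linalg.svd(mat, compute_uv=False)
    ev = s**2
    return float(ev[0] / ev.sum())


# ---------------------------------------------------------------------------
# permutation nulls
# ---------------------------------------------------------------------------

@dataclass
class NullDistribution:
    model_name: str
    statistic: str
    samples: np.ndarray = field(repr=False)
    observed: float = np.nan

    @property
    def n_iters(self) -> int:
        return len(self.samples)

    @property
    def one_tailed_p(self) -> float:
        return (1 + int(np.sum(self.samples >= self.observed))) / (self.n_iters + 1)

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.samples, q))


def null_benchmark(observed_stat: float, null_generator, n_iters: int, rng,
                   model_name: str = "null", statistic: str = "stat") -> NullDistribution:
    """Build a null distribution by repeated calls to ``null_generator(rng)``."""
    if n_iters < 1:
        raise ValueError("n_iters must be >= 1")
    rng = np.random.default_rng(rng)
    samples = np.array([null_generator(rng) for _ in range(n_iters)], dtype=float)
    return NullDistribution(model_name, statistic, samples, float(observed_stat))


def _standardize_rows_nan(x: np.ndarray) -> np.ndarray:
    """Center rows and scale to unit norm; zero-variance rows become NaN."""
    z = x - x.mean(axis=-1, keepdims=True)
    norm = np.linalg.norm(z, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = z / norm
    z[np.broadcast_to(norm == 0, z.shape)] = np.nan
    return z


def _batch_mean_ilc(stack: np.ndarray) -> float:
    """Mean Fisher-z ILC over language pairs for a (K, N, D) projection stack.

    Rows are standardized per concept; NaN rows (anchor-overlap exclusions or
    zero variance) are dropped per pair via nanmean.
    """
    z = _standardize_rows_nan(stack)
    k = z.shape[0]
    zz = np.nan_to_num(z)
    r = np.einsum("acd,bcd->abc", zz, zz)
    valid = np.isfinite(z).all(axis=-1)
    pair_valid = valid[:, None, :] & valid[None, :, :]
    r = np.where(pair_valid, np.clip(r, -1 + R_CLIP_EPS, 1 - R_CLIP_EPS), np.nan)
    zvals = np.arctanh(r)
    iu = np.triu_indices(k, 1)
    with np.errstate(invalid="ignore"):
        per_pair = np.nanmean(zvals[iu], axis=-1)
    return float(np.nanmean(per_pair))


class _NullEngine:
    """Shared precomputation for the fast anchor-resampling nulls.

    Cosine matrices target x master are computed once per language; each
    iteration then only slices columns, so ten-thousand-iteration null
    distributions stay cheap.
    """

    def __init__(self, tables, targets=None, master=None):
        tables = list(tables)
        shared = set(tables[0].concepts)
        for t in tables[1:]:
            shared &= set(t.concepts)
        self.master = [c for c in (master if master is not None else sorted(shared))
                       if c in shared]
        tgt = targets if targets is not None else self.master
        self.targets = [c for c in tgt if c in shared]
        if len(self.targets) < 2 or len(self.master) < 2:
            raise ValueError("too few shared concepts for null construction")
        self.target_pos = {c: i for i, c in enumerate(self.targets)}
        self.tables = tables
        self.cos = np.stack([
            t.unit_matrix(self.targets) @ t.unit_matrix(self.master).T for t in tables
        ])  # (K, n_targets, n_master)

    def _mask_anchor_targets(self, stack: np.ndarray, anchor_concepts) -> np.ndarray:
        rows = [self.target_pos[c] for c in anchor_concepts if c in self.target_pos]
        if rows:
            stack = stack.copy()
            stack[:, rows, :] = np.nan
        return stack

    def random_word_stat(self, rng, n_anchors: int = 13) -> float:
        idx = rng.choice(len(self.master), size=n_anchors, replace=False)
        stack = self._mask_anchor_targets(self.cos[:, :, idx],
                                          [self.master[i] for i in idx])
        return _batch_mean_ilc(stack)

    def random_dimension_stat(self, rng, reference_index: int = 0,
                              n_words: int = 100, n_clusters: int = 13) -> float:
        grouping = random_dimension_grouping(
            self.tables[reference_index], self.master, n_words, n_clusters, rng)
        words = list(grouping)
        w_idx = [self.master.index(w) for w in words]
        indic = np.zeros((len(words), n_clusters))
        for i, w in enumerate(words):
            indic[i, grouping[w]] = 1.0
        indic /= indic.sum(axis=0, keepdims=True)
        stack = self.cos[:, :, w_idx] @ indic
        stack = self._mask_anchor_targets(stack, words)
        return _batch_mean_ilc(stack)


def random_word_null(tables, targets=None, master=None, n_anchors: int = 13,
                     n_iters: int = 10000, rng=None) -> np.ndarray:
    """Null distribution of mean ILC under the random-word control model."""
    rng = np.random.default_rng(rng)
    eng = _NullEngine(tables, targets, master)
    return np.array([eng.random_word_stat(rng, n_anchors) for _ in range(n_iters)])


def random_dimension_null(tables, targets=None, master=None, reference_index: int = 0,
                          n_words: int = 100, n_clusters: int = 13,
                          n_iters: int = 10000, rng=None) -> np.ndarray:
    """Null distribution of mean ILC under the random-dimension control model."""
    rng = np.random.default_rng(rng)
    eng = _NullEngine(tables, targets, master)
    return np.array([
        eng.random_dimension_stat(rng, reference_index, n_words, n_clusters)
        for _ in range(n_iters)
    ])


# ---------------------------------------------------------------------------
# inter-subject analyses (rating study)
# ---------------------------------------------------------------------------

def _rating_pivot(ratings: pd.DataFrame) -> pd.DataFrame:
    required = {"participant", "language", "concept", "dimension", "rating"}
    if not required.issubset(ratings.columns):
        raise ValueError(f"ratings table needs columns {sorted(required)}")
    return ratings.pivot_table(index="participant", columns=["concept", "dimension"],
                               values="rating", aggfunc="mean")


def intersubject_matrix(ratings: pd.DataFrame) -> pd.DataFrame:
    """Participant x participant Pearson correlation of full rating vectors.

    Raw r (no Fisher transform); missing cells handled pairwise; raters with
    constant vectors are excluded with a warning.
    """
    wide = _rating_pivot(ratings)
    sd = wide.std(axis=1, ddof=0)
    constant = sd[sd == 0].index
    if len(constant):
        logger.warning("intersubject_matrix: excluding %d constant raters", len(constant))
        wide = wide.drop(index=constant)
    return wide.T.corr()


def qc_filter(ratings: pd.DataFrame, threshold: float = 0.5):
    """Exclude raters poorly correlated with their language's mean pattern.

    Single pass: for each language the group mean vector is computed over
    all its participants (including the candidate); participants whose
    rating vector correlates below ``threshold`` with it are excluded.
    Returns (retained participant list, report frame with per-participant r).
    """
    wide = _rating_pivot(ratings)
    lang_of = ratings.drop_duplicates("participant").set_index("participant")["language"]
    rows = []
    for lang, members in lang_of.groupby(lang_of):
        parts = [p for p in members.index if p in wide.index]
        if len(parts) < 2:
            logger.warning("qc_filter: language %s has < 2 participants", lang)
        group_mean = wide.loc[parts].mean(axis=0)
        for p in parts:
            r = wide.loc[p].corr(group_mean)
            rows.append((p, lang, float(r), bool(r >= threshold)))
    report = pd.DataFrame(rows, columns=["participant", "language", "r_with_group", "retained"])
    retained = report.loc[report["retained"], "participant"].tolist()
    n_dropped = len(report) - len(retained)
    if n_dropped:
        logger.info("qc_filter: excluded %d of %d participants", n_dropped, len(report))
    return retained, report


@dataclass
class VarianceComponents:
    universal_share: float
    language_share: float
    residual_share: float
    truncated: bool = False

    def as_tuple(self):
        return (self.universal_share, self.language_share, self.residual_share)


def variance_components(ratings: pd.DataFrame) -> VarianceComponents:
    """Random-effects decomposition of rating variance.

    Model: rating(p, c) = universal pattern m_c + language deviation
    b_{l(p), c} + participant residual.  Estimated by expected mean squares
    on cell-wise one-way ANOVAs (languages as random groups, harmonic mean
    participant count for unbalanced designs), with the universal component
    estimated as the variance of the grand mean pattern over cells,
    de-biased for sampling noise.  Negative estimates are truncated at zero
    and flagged.  Shares sum to 1.
    """
    wide = _rating_pivot(ratings)
    lang_of = ratings.drop_duplicates("participant").set_index("participant")["language"]
    langs = sorted(lang_of.unique())
    if len(langs) < 2:
        raise ValueError("need >= 2 languages")
    groups = {l: wide.loc[[p for p in lang_of[lang_of == l].index if p in wide.index]]
              for l in langs}
    sizes = np.array([len(g) for g in groups.values()], dtype=float)
    if np.any(sizes < 2):
        raise ValueError("need >= 2 participants per language")
    n_h = len(sizes) / np.sum(1.0 / sizes)

    # residual: within-language variance across participants, averaged over cells
    sigma_e = float(np.mean([g.var(axis=0, ddof=1).mean() for g in groups.values()]))
    # language: variance of language mean patterns around the grand pattern,
    # de-biased for participant sampling noise
    lang_means = pd.DataFrame({l: g.mean(axis=0) for l, g in groups.items()}).T
    grand = lang_means.mean(axis=0)
    sigma_b = float(lang_means.var(axis=0, ddof=1).mean()) - sigma_e / n_h
    # universal: variance of the grand pattern over cells, de-biased
    L = len(langs)
    sigma_u = float(grand.var(ddof=1)) - max(sigma_b, 0.0) / L - sigma_e / (L * n_h)

    truncated = sigma_b < 0 or sigma_u < 0
    sigma_b = max(sigma_b, 0.0)
    sigma_u = max(sigma_u, 0.0)
    total = sigma_u + sigma_b + sigma_e
    if total <= 0:
        raise ValueError("degenerate ratings: zero total variance")
    return VarianceComponents(sigma_u / total, sigma_b / total, sigma_e / total, truncated)
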