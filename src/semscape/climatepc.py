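"""Climate PCA and the projection of semantic spaces onto climate axes.

The 19 bioclim variables are z-scored and decomposed by PCA; the first two
components typically separate cold/temperate vs. tropical and oceanic vs.
continental climates.  Each language's semantic space (concept x 13
matrix, per-column z-scored) is weighted by the language's score on a
climate PC and averaged over languages, giving a signed concept x
dimension map per PC: positive values mark semantic relations that are
stronger toward the positive pole of that climate axis.  The association
ratio summarizes the signed mass in each direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spaces import SemanticSpace

logger = logging.getLogger("semscape")


@dataclass
class ClimatePCA:
    loadings: pd.DataFrame = field(repr=False)   # variables x PCs
    scores: pd.DataFrame = field(repr=False)     # languages x PCs
    explained_variance_ratio: np.ndarray = field(repr=False)


def climate_pca(profiles: pd.DataFrame, n_pcs: int = 2) -> ClimatePCA:
    """SVD-based PCA of z-scored climate profiles.

    Constant variables are dropped with a warning.  Sign convention: each
    PC is oriented so that its largest-|loading| variable loads positively
    (PCA signs are otherwise arbitrary).
    """
    if len(profiles) < 3:
        raise ValueError("need >= 3 languages")
    x = profiles.dropna(axis=0).astype(float)
    sd = x.std(axis=0, ddof=1)
    constant = sd[sd == 0].index
    if len(constant):
        logger.warning("climate_pca: dropping constant variables %s", list(constant))
        x = x.drop(columns=constant)
        sd = sd.drop(constant)
    z = (x - x.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
    evr = s**2 / np.sum(s**2)
    n_pcs = min(n_pcs, len(s))
    load = vt[:n_pcs].T.copy()           # variables x PCs
    score = (u[:, :n_pcs] * s[:n_pcs]).copy()
    for k in range(n_pcs):
        imax = np.argmax(np.abs(load[:, k]))
        if load[imax, k] < 0:
            load[:, k] *= -1
            score[:, k] *= -1
    pcs = [f"PC{k + 1}" for k in range(n_pcs)]
    return ClimatePCA(
        pd.DataFrame(load, index=x.columns, columns=pcs),
        pd.DataFrame(score, index=x.index, columns=pcs),
        evr,
    )


def project_semantic(spaces: dict[str, SemanticSpace], pc_scores: pd.Series) -> pd.DataFrame:
    """Signed concept x dimension map along one climate PC.

    Each language's matrix is z-scored per column, multiplied by the
    language's PC score, and averaged across languages.  Languages missing
    from either input are excluded with a report; the map is linear in the
    scores (flipping all scores flips the map).
    """
    frames = {l: (s.data if isinstance(s, SemanticSpace) else s) for l, s in spaces.items()}
    langs = [l for l in frames if l in pc_scores.index]
    skipped = (set(frames) | set(pc_scores.index)) - set(langs)
    if skipped:
        logger.info("project_semantic: excluding %s (missing space or score)", sorted(skipped))
    if not langs:
        raise ValueError("no language present in both spaces and scores")
    concepts = None
    for l in langs:
        concepts = frames[l].index if concepts is None else concepts.intersection(frames[l].index)
    cols = frames[langs[0]].columns
    acc = np.zeros((len(concepts), len(cols)))
    for l in langs:
        m = frames[l].loc[concepts, cols].to_numpy(dtype=float)
        mu = m.mean(axis=0)
        sd = m.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        acc += float(pc_scores[l]) * (m - mu) / sd
    return pd.DataFrame(acc / len(langs), index=concepts, columns=cols)


def association_ratio(projected: pd.DataFrame, direction: str = "positive",
                      subset=None) -> float:
    """Summed |values| in one direction over the total summed |values|.

    ``subset`` restricts to a list of dimensions (columns).  The positive
    and negative ratios sum to 1 exactly.
    """
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    m = projected[list(subset)] if subset is not None else projected
    v = m.to_numpy(dtype=float).ravel()
    pos = np.abs(v[v > 0]).sum()
    neg = np.abs(v[v < 0]).sum()
    total = pos + neg
    if total == 0:
        raise ValueError("association ratio undefined for an all-zero map")
    return float(pos / total) if direction == "positive" else float(neg / total)


def domain_summary(projected: pd.DataFrame, concept_to_domain: dict[str, str]) -> pd.DataFrame:
    """Mean projected value per (domain, dimension) cell.

    Concepts without a domain mapping are excluded with a report.
    """
    mapped = [c for c in projected.index if c in concept_to_domain]
    unmapped = set(projected.index) - set(mapped)
    if unmapped:
        logger.info("domain_summary: excluding %d unmapped concepts", len(unmapped))
    if not mapped:
        raise ValueError("no concept has a domain mapping")
    domains = pd.Series({c: concept_to_domain[c] for c in mapped})
    return projected.loc[mapped].groupby(domains).mean()
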