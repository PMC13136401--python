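"""Environmental distance matrices between languages.

Four predictors enter the representational-similarity regressions:

* **climate** — scaled (z-scored per variable) Euclidean distance over the
  19 bioclim temperature/precipitation descriptors;
* **geography** — great-circle distance in km between language coordinates;
* **linguistic history** — step-counting distance on the family tree;
* **culture** — consumed as a precomputed labeled matrix (its derivation is
  outside this package's scope).

A demographic distance (participant covariates aggregated per language) is
available as a control for the rating study.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .rdm import RDM
from .tree import FamilyTree

logger = logging.getLogger("semscape")

#: mean Earth radius, km (IUGG)
EARTH_RADIUS_KM = 6371.0088

BIOCLIM_VARS = tuple(f"bio{i}" for i in range(1, 20))


def _zscore_cols(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(axis=0, ddof=1)
    sd = sd.replace(0.0, np.nan)
    return (df - df.mean(axis=0)) / sd


def climate_distance(profiles: pd.DataFrame) -> RDM:
    """Scaled Euclidean distance over bioclim profiles (languages x variables).

    Each variable is z-scored across the included languages before the
    Euclidean distance; languages with any missing variable are excluded
    (never imputed) with a report.
    """
    complete = profiles.dropna(axis=0)
    dropped = set(profiles.index) - set(complete.index)
    if dropped:
        logger.info("climate_distance: excluding %s (missing variables)", sorted(dropped))
    if len(complete) < 2:
        raise ValueError("need >= 2 complete climate profiles")
    z = _zscore_cols(complete.astype(float))
    z = z.dropna(axis=1)  # constant variables carry no distance information
    d = squareform(pdist(z.to_numpy(), metric="euclidean"))
    return RDM(list(complete.index), d)


def _check_coords(points: pd.DataFrame) -> pd.DataFrame:
    pts = points[["lat", "lon"]].astype(float)
    if (pts["lat"].abs() > 90).any():
        raise ValueError("latitude out of [-90, 90]")
    if (pts["lon"].abs() > 180).any():
        raise ValueError("longitude out of [-180, 180]")
    return pts


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance between two points, km (spherical Earth)."""
    p1, l1, p2, l2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = np.sin((p2 - p1) / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin((l2 - l1) / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0))))


def geodesic_distance(points: pd.DataFrame, method: str = "haversine") -> RDM:
    """Pairwise great-circle distances (km) from a languages x (lat, lon) table."""
    if method != "haversine":
        raise NotImplementedError("only the spherical haversine distance is provided")
    pts = _check_coords(points)
    lat = np.radians(pts["lat"].to_numpy())
    lon = np.radians(pts["lon"].to_numpy())
    dphi = lat[:, None] - lat[None, :]
    dlmb = lon[:, None] - lon[None, :]
    a = np.sin(dphi / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlmb / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    return RDM(list(points.index), d)


def tree_distance(tree: FamilyTree, a: str, b: str, convention: str = "sum") -> int:
    """Steps on the family tree until the two leaves converge.

    ``sum`` (default) adds the upward steps from both leaves to their lowest
    common ancestor, which is symmetric and a metric; ``max`` takes the
    larger of the two counts.
    """
    if a == b:
        return 0
    pa = tree.path_to_root(a)
    pb = tree.path_to_root(b)
    ancestors_a = {n: i for i, n in enumerate(pa)}
    for j, n in enumerate(pb):
        if n in ancestors_a:
            i = ancestors_a[n]
            return i + j if convention == "sum" else max(i, j)
    raise ValueError(f"{a!r} and {b!r} share no ancestor")


def tree_distance_matrix(tree: FamilyTree, leaves=None, convention: str = "sum") -> RDM:
    leaves = list(leaves) if leaves is not None else sorted(tree.leaves)
    n = len(leaves)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = tree_distance(tree, leaves[i], leaves[j], convention)
    return RDM(leaves, d)


DEMOGRAPHIC_COVARIATES = ("age", "gender", "education", "ses")


def demographic_distance(participants: pd.DataFrame,
                         reference_gender: str = "female") -> RDM:
    """Scaled Euclidean distance between language-level demographic means.

    Gender is coded as the within-language proportion of ``reference_gender``
    before z-scoring; participants missing a covariate are dropped from that
    covariate's mean with a report.
    """
    missing = {c: int(participants[c].isna().sum()) for c in DEMOGRAPHIC_COVARIATES
               if c in participants and participants[c].isna().any()}
    if missing:
        logger.info("demographic_distance: dropping missing values per covariate: %s", missing)
    df = participants.copy()
    if df["gender"].dtype == object:
        df["gender"] = (df["gender"] == reference_gender).astype(float).where(
            participants["gender"].notna())
    means = df.groupby("language")[list(DEMOGRAPHIC_COVARIATES)].mean()
    if len(means) < 2:
        raise ValueError("need >= 2 languages")
    z = _zscore_cols(means).dropna(axis=1)
    d = squareform(pdist(z.to_numpy(), metric="euclidean"))
    return RDM(list(means.index), d)


def aggregate_coordinates(sites: pd.DataFrame) -> pd.DataFrame:
    """Language geographic centers as arithmetic means of site coordinates.

    A language whose sites span more than 180 degrees of longitude straddles
    the antimeridian, where the arithmetic mean is misleading; a warning is
    emitted for such languages.
    """
    if sites.empty:
        raise ValueError("empty site table")
    _check_coords(sites)
    out = sites.groupby("language")[["lat", "lon"]].mean()
    span = sites.groupby("language")["lon"].agg(lambda s: s.max() - s.min())
    wide = span[span > 180].index
    if len(wide):
        logger.warning("aggregate_coordinates: longitude span > 180 deg for %s "
                       "(antimeridian wraparound not handled)", list(wide))
    return out
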