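"""Representational-similarity regression with crossed family intercepts.

The response is the vectorized lower triangle of a dissimilarity matrix
over languages (semantic or neural); the predictors are the lower triangles
of environmental distance matrices.  All variables are standardized and
fitted with a linear mixed model carrying crossed random intercepts for the
language families of both pair members:

    y_ij = b0 + b1*Climate_ij + ... + (1|Family_i) + (1|Family_j) + e_ij

estimated by REML with Wald confidence intervals.  Variance components
estimated at zero (boundary) are permitted and flagged.  The module also
provides per-dimension fits with BH-FDR, per-ROI semantic-to-neural fits,
hierarchical R-squared increments, control models with competing structure
covariates, and commonality variance partitioning with a cluster bootstrap
over languages.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .rdm import RDM
from .spaces import SemanticSpace
from .universality import fdr_bh, fisher_z

logger = logging.getLogger("semscape")

ENV_PREDICTORS = ("climate", "culture", "geography", "linguistic_history")


class DesignError(ValueError):
    """Singular or degenerate fixed-effects design."""


# ---------------------------------------------------------------------------
# RDM construction
# ---------------------------------------------------------------------------

def _frames(spaces) -> dict[str, pd.DataFrame]:
    return {l: (s.data if isinstance(s, SemanticSpace) else s) for l, s in spaces.items()}


def semantic_rdm(spaces: dict[str, SemanticSpace], min_shared_cells: int = 10) -> RDM:
    """Semantic distance 1 - atanh(r) between flattened language matrices.

    r is the Pearson correlation over concept x dimension cells shared by
    the pair (NaN cells dropped pairwise).  The Fisher transform spreads the
    top of the correlation scale; the resulting distance can be negative for
    very similar languages, which is harmless because every RDM is
    standardized before model fitting.  Identical languages sit at the
    matrix minimum 1 - atanh(1 - 1e-7); an r of exactly 0 maps to 1.
    """
    frames = _frames(spaces)
    langs = list(frames)
    concepts = None
    cols = None
    for df in frames.values():
        concepts = df.index if concepts is None else concepts.intersection(df.index)
        cols = df.columns if cols is None else cols.intersection(df.columns)
    flat = {l: frames[l].loc[concepts, cols].to_numpy(dtype=float).ravel() for l in langs}
    n = len(langs)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        a, b = flat[langs[i]], flat[langs[j]]
        mask = np.isfinite(a) & np.isfinite(b)
        if mask.sum() < min_shared_cells:
            raise ValueError(f"pair ({langs[i]}, {langs[j]}): fewer than "
                             f"{min_shared_cells} shared cells")
        r = np.corrcoef(a[mask], b[mask])[0, 1]
        d[i, j] = d[j, i] = 1.0 - fisher_z(r)
    return RDM(langs, d)


def per_dimension_rdms(spaces: dict[str, SemanticSpace],
                       method: str = "correlation") -> dict[str, RDM]:
    """One RDM per model dimension.

    ``correlation`` (default): 1 - Pearson over the concept-length vector of
    that dimension; ``euclidean``: plain Euclidean distance between the two
    languages' dimension vectors.
    """
    frames = _frames(spaces)
    langs = list(frames)
    concepts = None
    for df in frames.values():
        concepts = df.index if concepts is None else concepts.intersection(df.index)
    cols = next(iter(frames.values())).columns
    out = {}
    for dim in cols:
        mat = np.stack([frames[l].loc[concepts, dim].to_numpy(dtype=float) for l in langs])
        if method == "correlation":
            d = 1.0 - np.corrcoef(mat)
        elif method == "euclidean":
            diff = mat[:, None, :] - mat[None, :, :]
            d = np.linalg.norm(diff, axis=-1)
        else:
            raise ValueError(f"unknown method {method!r}")
        np.fill_diagonal(d, 0.0)
        out[str(dim)] = RDM(langs, d)
    return out


def neural_rdm(tmaps: pd.DataFrame, language_of_participant: pd.Series) -> RDM:
    """Language-level neural RDM from participant pattern vectors.

    Participant rows are averaged within language; the distance between two
    languages is 1 - Pearson across voxels of their mean patterns (bounded
    by 2 for perfectly anti-correlated patterns).
    """
    lang = language_of_participant.reindex(tmaps.index)
    if lang.isna().any():
        raise ValueError("every participant row needs a language label")
    means = tmaps.groupby(lang).mean()
    if len(means) < 2:
        raise ValueError("need >= 2 languages with participants")
    d = 1.0 - np.corrcoef(means.to_numpy())
    np.fill_diagonal(d, 0.0)
    return RDM(list(means.index), d)


# ---------------------------------------------------------------------------
# pair table
# ---------------------------------------------------------------------------

def build_pair_table(response: RDM, predictors: dict[str, RDM],
                     family: dict[str, str],
                     standardize_response: bool = True) -> pd.DataFrame:
    """Unordered language-pair table with standardized columns.

    Restricted to languages present in the response, every predictor and the
    family map; predictor columns (and by default the response) are z-scored
    over pairs.
    """
    langs = [l for l in response.labels
             if all(l in p.labels for p in predictors.values()) and l in family]
    if len(langs) < 3:
        raise ValueError("fewer than 3 languages shared by all matrices")
    dropped = set(response.labels) - set(langs)
    if dropped:
        logger.info("build_pair_table: dropping %s (missing predictors/family)", sorted(dropped))
    resp = response.subset(langs)
    pairs = resp.pairs()

    def std(v):
        sd = v.std(ddof=1)
        if sd == 0:
            raise DesignError("constant column in pair table")
        return (v - v.mean()) / sd

    df = pd.DataFrame({
        "lang_i": [a for a, _ in pairs],
        "lang_j": [b for _, b in pairs],
        "family_i": [family[a] for a, _ in pairs],
        "family_j": [family[b] for _, b in pairs],
        "y": std(resp.condensed()) if standardize_response else resp.condensed(),
    })
    for name, rdm in predictors.items():
        df[name] = std(rdm.subset(langs).condensed())
    return df


# ---------------------------------------------------------------------------
# mixed model
# ---------------------------------------------------------------------------

@dataclass
class MixedFitResult:
    params: pd.Series
    bse: pd.Series = field(repr=False)
    conf_int: pd.DataFrame = field(repr=False)
    pvalues: pd.Series = field(repr=False)
    vcomp: dict = field(default_factory=dict)
    resid_var: float = np.nan
    converged: bool = True
    boundary: bool = False
    method: str = "reml-mixed"
    n: int = 0

    def beta(self, name: str) -> float:
        return float(self.params[name])


def _check_design(x: pd.DataFrame) -> None:
    m = np.column_stack([np.ones(len(x)), x.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(m) < m.shape[1]:
        bad = []
        for c in x.columns:
            rest = x.drop(columns=c)
            mm = np.column_stack([np.ones(len(x)), rest.to_numpy(dtype=float)])
            resid = x[c] - mm @ np.linalg.lstsq(mm, x[c].to_numpy(), rcond=None)[0]
            if np.abs(resid).max() < 1e-8:
                bad.append(c)
        raise DesignError(f"singular fixed-effects design; collinear columns: {bad}")


def _pair_t_inference(df: pd.DataFrame, predictors, params: pd.Series,
                      bse: pd.Series):
    """Two-sided t-tests and 95% CIs for pair-level regressions.

    Language pairs are not independent units, so the reference distribution
    uses a conservative df bound of (number of languages - k - 1) rather
    than the normal approximation, whose far tail is anti-conservative on
    this design.
    """
    n_units = pd.concat([df["lang_i"], df["lang_j"]]).nunique() if "lang_i" in df else len(df)
    dof = max(n_units - len(predictors) - 1, 2)
    pvals = pd.Series(2 * stats.t.sf(np.abs(params / bse), dof), index=params.index)
    tcrit = float(stats.t.ppf(0.975, dof))
    ci = pd.DataFrame({"low": params - tcrit * bse, "high": params + tcrit * bse})
    return pvals, ci


def fit_env_model(pair_table: pd.DataFrame, predictors=None,
                  response: str = "y", random_structure: str = "family") -> MixedFitResult:
    """Crossed-random-intercepts regression of a pair response on distances.

    ``random_structure``: ``family`` (default) crosses intercepts for the
    families of both pair members; ``language`` crosses intercepts for the
    languages themselves; ``none`` reduces to OLS.  With both variance
    components estimated at zero the fixed effects coincide with OLS.
    """
    predictors = list(predictors) if predictors is not None else [
        c for c in ENV_PREDICTORS if c in pair_table.columns]
    _check_design(pair_table[predictors])
    df = pair_table.copy()
    df["_one"] = 1
    formula = f"{response} ~ " + " + ".join(predictors)
    if random_structure == "none":
        fit = sm.OLS.from_formula(formula, data=df).fit()
        ci = fit.conf_int()
        ci.columns = ["low", "high"]
        return MixedFitResult(fit.params, fit.bse, ci, fit.pvalues,
                              {}, float(fit.mse_resid), True, False, "ols", len(df))
    if random_structure == "family":
        vc = {"fam_i": "0 + C(family_i)", "fam_j": "0 + C(family_j)"}
    elif random_structure == "language":
        vc = {"lang_i": "0 + C(lang_i)", "lang_j": "0 + C(lang_j)"}
    else:
        raise ValueError(f"unknown random_structure {random_structure!r}")
    if df["family_i"].nunique() < 2 and df["family_j"].nunique() < 2:
        raise ValueError("need >= 2 families for crossed random intercepts")
    model = sm.MixedLM.from_formula(formula, groups="_one", vc_formula=vc,
                                    re_formula="0", data=df)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)
    fixed = list(fit.fe_params.index)
    bad = (not fit.converged) or bool(
        np.isnan(fit.fe_params).any() or np.isnan(fit.bse.loc[fixed]).any())
    if bad:
        # optimizer failure leaves unusable standard errors; the honest
        # fallback is the OLS fit, flagged as such
        logger.warning("fit_env_model: REML fit failed to converge, "
                       "falling back to OLS")
        ols = sm.OLS.from_formula(formula, data=df).fit()
        pvals, ci = _pair_t_inference(df, predictors, ols.params, ols.bse)
        return MixedFitResult(ols.params, ols.bse, ci, pvals, {},
                              float(ols.mse_resid), False, False,
                              "ols-fallback", len(df))
    params = fit.fe_params
    bse = fit.bse.loc[fixed]
    pvals, ci = _pair_t_inference(df, predictors, params, bse)
    vcomp = dict(zip(model.exog_vc.names, np.atleast_1d(fit.vcomp)))
    boundary = any(v < 1e-8 for v in vcomp.values())
    return MixedFitResult(params, bse, ci, pvals, vcomp, float(fit.scale),
                          bool(fit.converged), boundary, "reml-mixed", len(df))


def gls_at_zero_variance(pair_table: pd.DataFrame, predictors=None,
                         response: str = "y",
                         random_structure: str = "family") -> pd.Series:
    """Fixed effects of the mixed model with variance components at zero.

    This is the boundary case of the crossed-intercepts model: with both
    variance components at (numerically) zero the GLS weighting is the
    identity and the fixed effects coincide with ordinary least squares.
    Useful as an engine check against an independent OLS fit.
    """
    predictors = list(predictors) if predictors is not None else [
        c for c in ENV_PREDICTORS if c in pair_table.columns]
    df = pair_table.copy()
    df["_one"] = 1
    if random_structure == "family":
        vc = {"fam_i": "0 + C(family_i)", "fam_j": "0 + C(family_j)"}
    elif random_structure == "language":
        vc = {"lang_i": "0 + C(lang_i)", "lang_j": "0 + C(lang_j)"}
    else:
        raise ValueError(f"unknown random_structure {random_structure!r}")
    model = sm.MixedLM.from_formula(f"{response} ~ " + " + ".join(predictors),
                                    groups="_one", vc_formula=vc, re_formula="0", data=df)
    # exactly-zero components make the inner solver singular and values
    # below statsmodels' internal tolerance are mishandled; 1e-10 sits at
    # the boundary and reproduces OLS to ~1e-9
    fe, _ = model.get_fe_params(np.empty((0, 0)), np.full(len(vc), 1e-10))
    return pd.Series(np.asarray(fe).ravel(), index=["Intercept"] + predictors)


def fit_semantic_to_neural(neural_rdms: dict[str, RDM], semantic: RDM,
                           family: dict[str, str],
                           random_structure: str = "family") -> pd.DataFrame:
    """Per-ROI regression of neural distance on semantic distance, with
    BH-FDR across the ROI family."""
    rows = []
    for roi, rdm in neural_rdms.items():
        table = build_pair_table(rdm, {"semantic_distance": semantic}, family)
        fit = fit_env_model(table, ["semantic_distance"], random_structure=random_structure)
        rows.append({
            "roi": roi,
            "beta": fit.beta("semantic_distance"),
            "ci_low": fit.conf_int.loc["semantic_distance", "low"],
            "ci_high": fit.conf_int.loc["semantic_distance", "high"],
            "p": float(fit.pvalues["semantic_distance"]),
            "converged": fit.converged,
        })
    out = pd.DataFrame(rows).set_index("roi")
    out["q"] = fdr_bh(out["p"])
    return out


def per_dimension_fits(spaces: dict[str, SemanticSpace], predictors: dict[str, RDM],
                       family: dict[str, str], method: str = "correlation",
                       random_structure: str = "family") -> pd.DataFrame:
    """Environmental fits per model dimension with BH-FDR on the climate effect."""
    rdms = per_dimension_rdms(spaces, method)
    rows = []
    for dim, rdm in rdms.items():
        table = build_pair_table(rdm, predictors, family)
        fit = fit_env_model(table, random_structure=random_structure)
        row = {"dimension": dim, "converged": fit.converged}
        for name in predictors:
            row[f"beta_{name}"] = fit.beta(name)
            row[f"p_{name}"] = float(fit.pvalues[name])
        rows.append(row)
    out = pd.DataFrame(rows).set_index("dimension")
    if "p_climate" in out:
        out["q_climate"] = fdr_bh(out["p_climate"])
    return out


# ---------------------------------------------------------------------------
# OLS-side analyses
# ---------------------------------------------------------------------------

def _ols_r2(y: np.ndarray, x: np.ndarray) -> tuple[float, np.ndarray]:
    xx = np.column_stack([np.ones(len(y)), x]) if x.size else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(xx, y, rcond=None)
    fitted = xx @ beta
    ss_res = np.sum((y - fitted) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        return 1.0 - ss_res / ss_tot, fitted


def hierarchical_increment(pair_table: pd.DataFrame, block1_cols, block2_cols,
                           response: str = "y"):
    """OLS R-squared for block 1, increment for block 1 + block 2, and the
    Spearman rho between full-model fitted and observed distances."""
    block1_cols, block2_cols = list(block1_cols), list(block2_cols)
    if set(block1_cols) & set(block2_cols):
        raise ValueError("blocks must be disjoint")
    y = pair_table[response].to_numpy(dtype=float)
    r2_1, _ = _ols_r2(y, pair_table[block1_cols].to_numpy(dtype=float))
    r2_full, fitted = _ols_r2(y, pair_table[block1_cols + block2_cols].to_numpy(dtype=float))
    rho = float(stats.spearmanr(fitted, y).statistic)
    return {"r2_block1": float(r2_1), "r2_full": float(r2_full),
            "delta_r2": float(r2_full - r2_1), "spearman_fitted": rho}


def control_model(pair_table: pd.DataFrame, dv_col: str, control_col: str,
                  climate_col: str = "climate",
                  random_structure: str = "family") -> MixedFitResult:
    """Climate effect on one structure controlling for a competing structure.

    Fits ``dv ~ climate + control`` with crossed family intercepts; call
    twice with the roles swapped for the both-directions comparison.
    """
    return fit_env_model(pair_table, [climate_col, control_col],
                         response=dv_col, random_structure=random_structure)


def peak_distance_control(pair_table: pd.DataFrame, peak_centroids: pd.DataFrame,
                          predictors=None, response: str = "y",
                          random_structure: str = "family") -> MixedFitResult:
    """Re-estimate the climate effect with a peak-location covariate.

    ``peak_centroids``: per-language 3-D activation peak coordinates; their
    pairwise Euclidean distances enter as an extra standardized covariate.
    A constant covariate is dropped with a warning; pairs with a missing
    centroid are dropped with a report.
    """
    predictors = list(predictors) if predictors is not None else [
        c for c in ENV_PREDICTORS if c in pair_table.columns]
    df = pair_table.copy()
    have = set(peak_centroids.dropna().index)
    keep = df["lang_i"].isin(have) & df["lang_j"].isin(have)
    if (~keep).any():
        logger.info("peak_distance_control: dropping %d pairs missing centroids",
                    int((~keep).sum()))
    df = df.loc[keep].copy()
    pts = peak_centroids.to_numpy(dtype=float)
    index = {l: i for i, l in enumerate(peak_centroids.index)}
    d = np.array([
        np.linalg.norm(pts[index[a]] - pts[index[b]])
        for a, b in zip(df["lang_i"], df["lang_j"])
    ])
    if d.std(ddof=1) == 0:
        logger.warning("peak_distance_control: constant peak-distance covariate dropped")
        return fit_env_model(df, predictors, response, random_structure)
    df["peak_distance"] = (d - d.mean()) / d.std(ddof=1)
    return fit_env_model(df, predictors + ["peak_distance"], response, random_structure)


@dataclass
class CommonalityPartition:
    """Explained-variance shares unique to each predictor and common to both.

    Shares are fractions of the full-model R-squared and sum to 1; the
    common component can be negative (suppression), which is flagged.
    """

    unique_semantic: float
    unique_climate: float
    common: float
    r2_full: float
    ci: dict = field(default_factory=dict)
    negative_common: bool = False


def _partition(y, s, c):
    r2_full, _ = _ols_r2(y, np.column_stack([s, c]))
    r2_s, _ = _ols_r2(y, s[:, None])
    r2_c, _ = _ols_r2(y, c[:, None])
    unique_s = r2_full - r2_c
    unique_c = r2_full - r2_s
    common = r2_s + r2_c - r2_full
    return r2_full, unique_s, unique_c, common


def commonality_partition(pair_table: pd.DataFrame, semantic_col: str,
                          climate_col: str, response: str = "y",
                          n_boot: int = 1000, rng=None) -> CommonalityPartition:
    """Commonality analysis of a pair response on semantic + climate distance.

    unique_sem = R2_full - R2_climate_only, unique_clim = R2_full -
    R2_sem_only, common = R2_sem + R2_clim - R2_full; shares are each
    divided by R2_full.  Confidence intervals use a cluster bootstrap that
    resamples languages (not pairs) and rebuilds the pair table, respecting
    the dependence between pairs sharing a language.
    """
    y = pair_table[response].to_numpy(dtype=float)
    s = pair_table[semantic_col].to_numpy(dtype=float)
    c = pair_table[climate_col].to_numpy(dtype=float)
    r2_full, u_s, u_c, common = _partition(y, s, c)
    if not np.isfinite(r2_full) or r2_full <= 0:
        raise ValueError("commonality partition undefined: full-model R2 <= 0")
    shares = (u_s / r2_full, u_c / r2_full, common / r2_full)

    ci: dict = {}
    if n_boot > 0:
        rng = np.random.default_rng(rng)
        langs = sorted(set(pair_table["lang_i"]) | set(pair_table["lang_j"]))
        lookup = {}
        for row in pair_table.itertuples(index=False):
            lookup[(row.lang_i, row.lang_j)] = row
            lookup[(row.lang_j, row.lang_i)] = row
        boots = []
        for _ in range(n_boot):
            sampled = [langs[i] for i in rng.integers(0, len(langs), len(langs))]
            rows = [lookup[(a, b)]
                    for a, b in itertools.combinations(sampled, 2) if a != b]
            if len(rows) < 3:
                continue
            yy = np.array([r.__getattribute__(response) for r in rows])
            ss = np.array([getattr(r, semantic_col) for r in rows])
            cc = np.array([getattr(r, climate_col) for r in rows])
            if yy.std() == 0 or ss.std() == 0 or cc.std() == 0:
                continue
            rf, us, uc, co = _partition(yy, ss, cc)
            if rf > 0:
                boots.append((us / rf, uc / rf, co / rf))
        if boots:
            arr = np.array(boots)
            for i, name in enumerate(("unique_semantic", "unique_climate", "common")):
                lo, hi = np.percentile(arr[:, i], [2.5, 97.5])
                ci[name] = (float(lo), float(hi))
    return CommonalityPartition(shares[0], shares[1], shares[2], float(r2_full),
                                ci, negative_common=common < 0)
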