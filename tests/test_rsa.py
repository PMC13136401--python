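import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from semscape import (RDM, build_pair_table, commonality_partition, control_model,
                      fit_env_model, hierarchical_increment, neural_rdm,
                      peak_distance_control, per_dimension_rdms, semantic_rdm)
from semscape.rsa import DesignError, gls_at_zero_variance
from semscape.universality import Z_CLIP


def random_rdm(labels, rng):
    n = len(labels)
    v = rng.normal(size=n * (n - 1) // 2)
    return RDM.from_condensed(labels, v)


def toy_pair_table(seed=0, n_lang=12, n_fam=4, beta=None):
    """Pair table with iid predictor RDMs and an optional planted response."""
    rng = np.random.default_rng(seed)
    langs = [f"L{i}" for i in range(n_lang)]
    family = {l: f"F{i % n_fam}" for i, l in enumerate(langs)}
    preds = {name: random_rdm(langs, rng)
             for name in ("climate", "culture", "geography", "linguistic_history")}
    if beta is None:
        resp = random_rdm(langs, rng)
    else:
        clim = preds["climate"].condensed()
        clim = (clim - clim.mean()) / clim.std(ddof=1)
        noise = rng.normal(size=len(clim))
        resp = RDM.from_condensed(langs, beta * clim + math.sqrt(1 - beta**2) * noise)
    return build_pair_table(resp, preds, family)


class TestSemanticRDM:
    def test_matches_direct_formula(self):
        rng = np.random.default_rng(1)
        spaces = {l: pd.DataFrame(rng.normal(size=(6, 4)),
                                  index=[f"c{i}" for i in range(6)])
                  for l in ("aa", "bb", "cc")}
        rdm = semantic_rdm(spaces).to_frame()
        for a, b in itertools.combinations(spaces, 2):
            r = stats.pearsonr(spaces[a].to_numpy().ravel(),
                               spaces[b].to_numpy().ravel()).statistic
            assert rdm.loc[a, b] == pytest.approx(1.0 - math.atanh(r), abs=1e-10)

    def test_identical_languages_at_matrix_minimum(self):
        rng = np.random.default_rng(2)
        base = pd.DataFrame(rng.normal(size=(5, 3)), index=[f"c{i}" for i in range(5)])
        spaces = {"aa": base, "bb": base.copy(),
                  "cc": pd.DataFrame(rng.normal(size=(5, 3)), index=base.index)}
        rdm = semantic_rdm(spaces)
        assert rdm.to_frame().loc["aa", "bb"] == pytest.approx(1 - Z_CLIP)
        assert rdm.to_frame().loc["aa", "bb"] == rdm.condensed().min()

    def test_zero_correlation_maps_to_one(self):
        a = pd.DataFrame([[1.0, -1.0], [1.0, -1.0]], index=["c0", "c1"])
        b = pd.DataFrame([[1.0, 1.0], [-1.0, -1.0]], index=["c0", "c1"])
        c = pd.DataFrame([[0.5, 1.0], [-1.0, 0.2]], index=["c0", "c1"])
        rdm = semantic_rdm({"aa": a, "bb": b, "cc": c}, min_shared_cells=4)
        assert rdm.to_frame().loc["aa", "bb"] == pytest.approx(1.0, abs=1e-12)


class TestNeuralRDM:
    def test_matches_correlation_oracle(self):
        rng = np.random.default_rng(3)
        tmaps = pd.DataFrame(rng.normal(size=(8, 20)),
                             index=[f"p{i}" for i in range(8)])
        lang = pd.Series(["A"] * 2 + ["B"] * 2 + ["C"] * 2 + ["D"] * 2, index=tmaps.index)
        rdm = neural_rdm(tmaps, lang).to_frame()
        means = tmaps.groupby(lang).mean()
        for a, b in itertools.combinations(means.index, 2):
            r = stats.pearsonr(means.loc[a], means.loc[b]).statistic
            assert rdm.loc[a, b] == pytest.approx(1 - r, abs=1e-10)

    def test_anticorrelated_patterns_hit_bound(self):
        tmaps = pd.DataFrame([[1.0, -1, 2], [-1.0, 1, -2]], index=["p0", "p1"])
        lang = pd.Series(["A", "B"], index=tmaps.index)
        assert neural_rdm(tmaps, lang).to_frame().loc["A", "B"] == pytest.approx(2.0)


class TestPairTable:
    def test_columns_standardized(self):
        table = toy_pair_table(seed=5)
        for col in ("y", "climate", "culture", "geography", "linguistic_history"):
            assert abs(table[col].mean()) < 1e-10
            assert table[col].std(ddof=1) == pytest.approx(1.0, abs=1e-10)
        assert len(table) == 12 * 11 // 2

    def test_affine_transform_of_raw_rdm_absorbed(self):
        rng = np.random.default_rng(6)
        langs = [f"L{i}" for i in range(8)]
        family = {l: f"F{i % 3}" for i, l in enumerate(langs)}
        resp = random_rdm(langs, rng)
        pred = random_rdm(langs, rng)
        scaled = RDM(langs, 5.0 * pred.values + 7.0 - 7.0 * np.eye(8))
        t1 = build_pair_table(resp, {"climate": pred}, family)
        t2 = build_pair_table(resp, {"climate": scaled}, family)
        f1 = fit_env_model(t1, ["climate"])
        f2 = fit_env_model(t2, ["climate"])
        assert f1.beta("climate") == pytest.approx(f2.beta("climate"), abs=1e-8)


class TestFitEnvModel:
    def test_exact_copy_response_recovers_unit_beta(self):
        table = toy_pair_table(seed=7)
        table["y"] = table["climate"]
        fit = fit_env_model(table)
        assert fit.beta("climate") == pytest.approx(1.0, abs=1e-6)
        for other in ("culture", "geography", "linguistic_history"):
            assert abs(fit.beta(other)) < 1e-6

    def test_gls_at_zero_variance_equals_ols(self):
        table = toy_pair_table(seed=8, beta=0.4)
        ols = fit_env_model(table, random_structure="none")
        gls0 = gls_at_zero_variance(table)
        np.testing.assert_allclose(gls0.to_numpy(), ols.params.to_numpy(), atol=1e-6)

    def test_singular_design_names_collinear_columns(self):
        table = toy_pair_table(seed=9)
        table["culture"] = table["climate"]
        with pytest.raises(DesignError, match="climate"):
            fit_env_model(table)

    def test_ci_brackets_estimate(self):
        table = toy_pair_table(seed=10, beta=0.5)
        fit = fit_env_model(table)
        for name in fit.params.index:
            assert fit.conf_int.loc[name, "low"] <= fit.params[name] <= fit.conf_int.loc[name, "high"]
        assert ((fit.pvalues > 0) & (fit.pvalues <= 1)).all()


class TestPerDimensionRDMs:
    def test_correlation_and_euclidean_methods(self):
        rng = np.random.default_rng(11)
        spaces = {l: pd.DataFrame(rng.normal(size=(10, 3)),
                                  index=[f"c{i}" for i in range(10)],
                                  columns=["d0", "d1", "d2"])
                  for l in ("aa", "bb", "cc")}
        rdms = per_dimension_rdms(spaces, "correlation")
        assert set(rdms) == {"d0", "d1", "d2"}
        r = stats.pearsonr(spaces["aa"]["d1"], spaces["bb"]["d1"]).statistic
        assert rdms["d1"].to_frame().loc["aa", "bb"] == pytest.approx(1 - r, abs=1e-10)
        rdms_e = per_dimension_rdms(spaces, "euclidean")
        expected = math.dist(spaces["aa"]["d0"], spaces["bb"]["d0"])
        assert rdms_e["d0"].to_frame().loc["aa", "bb"] == pytest.approx(expected, abs=1e-10)


class TestHierarchical:
    def test_nested_r2_monotone_and_orthogonal_block_adds_nothing(self):
        rng = np.random.default_rng(12)
        n = 400
        deltas = []
        for _ in range(10):
            table = pd.DataFrame({
                "y": rng.normal(size=n), "demo": rng.normal(size=n),
                "b1": rng.normal(size=n), "b2": rng.normal(size=n),
            })
            res = hierarchical_increment(table, ["demo"], ["b1", "b2"])
            assert res["r2_block1"] <= res["r2_full"]
            deltas.append(res["delta_r2"])
        assert np.mean(deltas) < 0.02

    def test_planted_share_recovered(self):
        rng = np.random.default_rng(13)
        deltas = []
        for _ in range(50):
            n = 400
            b1 = rng.normal(size=n)
            b2 = rng.normal(size=n)
            y = math.sqrt(0.6) * b2 + math.sqrt(0.4) * rng.normal(size=n)
            table = pd.DataFrame({"y": y, "demo": b1, "env": b2})
            deltas.append(hierarchical_increment(table, ["demo"], ["env"])["delta_r2"])
        assert abs(np.mean(deltas) - 0.6) < 0.1

    def test_blocks_must_be_disjoint(self):
        table = toy_pair_table(seed=14)
        with pytest.raises(ValueError, match="disjoint"):
            hierarchical_increment(table, ["climate"], ["climate", "culture"])


class TestControlModels:
    def test_control_equal_to_dv_saturates_climate(self):
        table = toy_pair_table(seed=15, beta=0.5)
        table["competing"] = table["y"] + 1e-9 * np.arange(len(table))
        fit = control_model(table, "y", "competing")
        assert abs(fit.beta("climate")) < 1e-3

    def test_orthogonal_covariate_leaves_beta_unchanged(self):
        table = toy_pair_table(seed=16, beta=0.5)
        rng = np.random.default_rng(0)
        table["competing"] = rng.normal(size=len(table))
        with_cov = control_model(table, "y", "competing")
        without = fit_env_model(table, ["climate"], response="y")
        assert abs(with_cov.beta("climate") - without.beta("climate")) < 1e-2


class TestPeakDistanceControl:
    @staticmethod
    def table_and_centroids(seed=17):
        table = toy_pair_table(seed=seed, beta=0.5)
        langs = sorted(set(table["lang_i"]) | set(table["lang_j"]))
        rng = np.random.default_rng(seed)
        centroids = pd.DataFrame(rng.normal(size=(len(langs), 3)),
                                 index=langs, columns=["x", "y", "z"])
        return table, centroids

    def test_constant_centroids_dropped_beta_unchanged(self):
        table, centroids = self.table_and_centroids()
        centroids.loc[:, :] = 1.0
        fit = peak_distance_control(table, centroids)
        base = fit_env_model(table)
        assert fit.beta("climate") == pytest.approx(base.beta("climate"), abs=1e-10)
        assert "peak_distance" not in fit.params.index

    def test_independent_centroids_barely_move_beta(self):
        table, centroids = self.table_and_centroids()
        fit = peak_distance_control(table, centroids)
        base = fit_env_model(table)
        assert abs(fit.beta("climate") - base.beta("climate")) < 0.02
        assert "peak_distance" in fit.params.index

    def test_missing_centroid_drops_pairs(self):
        table, centroids = self.table_and_centroids()
        centroids.loc[centroids.index[0]] = np.nan
        fit = peak_distance_control(table, centroids)
        n_lang = len(centroids) - 1
        assert fit.n == n_lang * (n_lang - 1) // 2


class TestCommonality:
    @staticmethod
    def planted_table(seed, r_sc=0.0, n_lang=30):
        rng = np.random.default_rng(seed)
        langs = [f"L{i}" for i in range(n_lang)]
        family = {l: f"F{i % 5}" for i, l in enumerate(langs)}
        n = n_lang * (n_lang - 1) // 2
        s = rng.normal(size=n)
        c = r_sc * s + math.sqrt(max(1 - r_sc**2, 0)) * rng.normal(size=n)
        y = 0.5 * s + 0.5 * c + rng.normal(size=n)
        resp = RDM.from_condensed(langs, y)
        preds = {"semantic": RDM.from_condensed(langs, s),
                 "climate": RDM.from_condensed(langs, c)}
        return build_pair_table(resp, preds, family)

    def test_partition_identity_holds_exactly(self):
        table = self.planted_table(seed=1, r_sc=0.5)
        part = commonality_partition(table, "semantic", "climate", n_boot=0)
        total = part.unique_semantic + part.unique_climate + part.common
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_predictors_no_common_variance(self):
        shares = [commonality_partition(self.planted_table(seed=s, r_sc=0.0),
                                        "semantic", "climate", n_boot=0).common
                  for s in range(10)]
        assert abs(np.mean(shares)) < 0.05

    def test_collinear_predictors_all_common(self):
        rng = np.random.default_rng(2)
        langs = [f"L{i}" for i in range(20)]
        family = {l: f"F{i % 4}" for i, l in enumerate(langs)}
        n = len(langs) * 19 // 2
        s = rng.normal(size=n)
        y = 0.7 * s + 0.3 * rng.normal(size=n)
        table = build_pair_table(RDM.from_condensed(langs, y),
                                 {"semantic": RDM.from_condensed(langs, s),
                                  "climate": RDM.from_condensed(langs, s + 1e-9 * rng.normal(size=n))},
                                 family)
        part = commonality_partition(table, "semantic", "climate", n_boot=0)
        assert part.common == pytest.approx(1.0, abs=1e-3)
        assert abs(part.unique_semantic) < 1e-3 and abs(part.unique_climate) < 1e-3

    def test_bootstrap_ci_brackets_estimate(self):
        table = self.planted_table(seed=3, r_sc=0.4)
        part = commonality_partition(table, "semantic", "climate", n_boot=200, rng=1)
        lo, hi = part.ci["common"]
        assert lo <= part.common <= hi

    def test_undefined_for_zero_r2(self):
        rng = np.random.default_rng(4)
        langs = [f"L{i}" for i in range(6)]
        family = {l: "F0" if i < 3 else "F1" for i, l in enumerate(langs)}
        table = build_pair_table(random_rdm(langs, rng),
                                 {"semantic": random_rdm(langs, rng),
                                  "climate": random_rdm(langs, rng)}, family)
        table["y"] = 0.0
        table["y"] = table["y"] + 0  # constant response -> R2 degenerate
        with pytest.raises(ValueError):
            commonality_partition(table, "semantic", "climate", n_boot=0)
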