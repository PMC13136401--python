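import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from semscape import (NullDistribution, compare_models, fisher_z, ilc,
                      ilc_matrix, intersubject_matrix, mean_ilc, null_benchmark,
                      pca_universality, qc_filter, variance_components)
from semscape.universality import Z_CLIP


def frame(rows, concepts=None):
    m = np.asarray(rows, dtype=float)
    concepts = concepts or [f"c{i}" for i in range(m.shape[0])]
    return pd.DataFrame(m, index=concepts, columns=[f"d{j}" for j in range(m.shape[1])])


class TestFisherZ:
    def test_values_and_oddness(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5493061, abs=1e-6)
        assert fisher_z(-0.3) == pytest.approx(-fisher_z(0.3), abs=1e-12)

    def test_clipping_and_nan(self):
        assert fisher_z(1.0) == pytest.approx(Z_CLIP)
        with pytest.raises(ValueError):
            fisher_z(float("nan"))


class TestILC:
    def test_matches_direct_formula(self):
        rng = np.random.default_rng(8)
        a = frame(rng.normal(size=(4, 5)))
        b = frame(rng.normal(size=(4, 5)))
        res = ilc(a, b)
        expected = np.mean([
            math.atanh(np.clip(stats.pearsonr(a.loc[c], b.loc[c]).statistic,
                               -1 + 1e-7, 1 - 1e-7))
            for c in a.index
        ])
        assert res.mean_z == pytest.approx(expected, abs=1e-10)

    def test_identical_spaces_hit_clip_bound(self):
        a = frame(np.random.default_rng(1).normal(size=(5, 6)))
        assert ilc(a, a).mean_z == pytest.approx(Z_CLIP)

    def test_sign_flip_antisymmetry(self):
        a = frame(np.random.default_rng(2).normal(size=(5, 6)))
        assert ilc(a, -a).mean_z == pytest.approx(-ilc(a, a).mean_z, abs=1e-10)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(3)
        a, b = frame(rng.normal(size=(4, 5))), frame(rng.normal(size=(4, 5)))
        assert ilc(a, b).mean_z == pytest.approx(ilc(b, a).mean_z, abs=1e-12)

    def test_zero_variance_concept_skipped(self):
        a = frame([[1, 1, 1, 1], [0.3, -2, 1, 0.5], [1, 2, 3, 4]])
        b = frame(np.random.default_rng(4).normal(size=(3, 4)))
        res = ilc(a, b)
        assert res.n_skipped == 1 and len(res.per_concept_z) == 2

    def test_nan_cells_dropped_pairwise(self):
        rng = np.random.default_rng(5)
        a = frame(rng.normal(size=(3, 6)))
        b = frame(rng.normal(size=(3, 6)))
        a.iloc[0, 0] = np.nan
        res = ilc(a, b)
        manual = stats.pearsonr(a.iloc[0, 1:], b.iloc[0, 1:]).statistic
        assert res.per_concept_z.iloc[0] == pytest.approx(math.atanh(manual), abs=1e-10)


class TestCompareModels:
    def test_equal_vectors_give_p_one(self):
        x = np.arange(10.0)
        res = compare_models(x, x)
        assert res.pvalue == 1.0 and res.median_diff == 0.0

    def test_matches_exhaustive_signed_rank(self):
        rng = np.random.default_rng(11)
        a = rng.normal(size=8)
        b = rng.normal(size=8)
        d = a - b
        ranks = stats.rankdata(np.abs(d))
        v = ranks[d > 0].sum()
        res = compare_models(a, b)
        assert res.statistic == pytest.approx(min(v, ranks.sum() - v))
        # exact two-sided p by enumerating all 2^8 sign assignments
        stats_all = []
        for signs in itertools.product([0, 1], repeat=8):
            w = ranks[np.array(signs, dtype=bool)].sum()
            stats_all.append(min(w, ranks.sum() - w))
        stat_obs = min(v, ranks.sum() - v)
        p_exact = np.mean([s <= stat_obs for s in stats_all])
        assert res.pvalue == pytest.approx(p_exact, abs=1e-10)


class TestPCAUniversality:
    def test_identical_languages_share_one(self):
        a = frame(np.random.default_rng(1).normal(size=(10, 3)))
        assert pca_universality({"x": a, "y": a.copy(), "z": a.copy()}) == pytest.approx(1.0)

    def test_independent_noise_approaches_isotropy(self):
        rng = np.random.default_rng(21)
        shares = []
        for _ in range(10):
            spaces = {l: frame(rng.normal(size=(500, 2))) for l in "abc"}
            shares.append(pca_universality(spaces))
        assert abs(np.mean(shares) - 1 / 3) < 0.05

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(5)
        spaces = {l: frame(rng.normal(size=(4, 6))) for l in "abcd"}
        mat = np.column_stack([spaces[l].to_numpy().ravel() for l in "abcd"])
        corr = np.corrcoef(mat, rowvar=False)
        ev = np.sort(np.linalg.eigvalsh(corr))[::-1]
        # correlation PCA on n samples: eigenvalues scale by (n-1)/n vs SVD
        assert pca_universality(spaces) == pytest.approx(ev[0] / ev.sum(), abs=1e-8)

    def test_invariant_to_relabeling(self):
        rng = np.random.default_rng(6)
        spaces = {l: frame(rng.normal(size=(8, 4))) for l in "abc"}
        relabeled = {"zz": spaces["a"], "yy": spaces["b"], "xx": spaces["c"]}
        perm = np.random.default_rng(0).permutation(8)
        permuted = {l: s.iloc[perm] for l, s in spaces.items()}
        assert pca_universality(spaces) == pytest.approx(pca_universality(relabeled))
        assert pca_universality(spaces) == pytest.approx(pca_universality(permuted), abs=1e-10)


class TestNullBenchmark:
    def test_p_conventions(self):
        null = NullDistribution("m", "s", np.arange(99.0), observed=1000.0)
        assert null.one_tailed_p == pytest.approx(1 / 100)
        null_low = NullDistribution("m", "s", np.arange(99.0), observed=-5.0)
        assert null_low.one_tailed_p == 1.0

    def test_generator_driven(self):
        res = null_benchmark(2.0, lambda rng: rng.normal(), n_iters=200, rng=3)
        assert res.n_iters == 200 and 0 < res.one_tailed_p <= 1


def make_ratings(rng, lang_effect_sd=0.0, noise_sd=0.0, n_lang=3, n_part=4,
                 n_concepts=10, n_dims=3):
    pattern = rng.uniform(0, 6, size=(n_concepts, n_dims))
    rows = []
    pid = 0
    for l in range(n_lang):
        lang_dev = lang_effect_sd * rng.standard_normal(pattern.shape)
        for _ in range(n_part):
            vals = pattern + lang_dev + noise_sd * rng.standard_normal(pattern.shape)
            for ci in range(n_concepts):
                for di in range(n_dims):
                    rows.append((f"p{pid}", f"L{l}", f"c{ci}", f"d{di}", vals[ci, di]))
            pid += 1
    return pd.DataFrame(rows, columns=["participant", "language", "concept",
                                       "dimension", "rating"])


class TestIntersubject:
    def test_matches_pairwise_pearson(self):
        ratings = make_ratings(np.random.default_rng(1), noise_sd=1.0)
        m = intersubject_matrix(ratings)
        wide = ratings.pivot_table(index="participant", columns=["concept", "dimension"],
                                   values="rating")
        r_manual = stats.pearsonr(wide.loc["p0"], wide.loc["p5"]).statistic
        assert m.loc["p0", "p5"] == pytest.approx(r_manual, abs=1e-12)

    def test_duplicate_participant_r_one(self):
        ratings = make_ratings(np.random.default_rng(2), noise_sd=0.5)
        m = intersubject_matrix(ratings)
        assert m.loc["p0", "p0"] == pytest.approx(1.0)


class TestQCFilter:
    def test_noise_rater_excluded_consistent_raters_kept(self):
        rng = np.random.default_rng(7)
        ratings = make_ratings(rng, noise_sd=0.3)
        noise_rows = ratings[ratings.participant == "p0"].copy()
        noise_rows["rating"] = rng.uniform(0, 6, size=len(noise_rows))
        ratings = pd.concat([ratings[ratings.participant != "p0"], noise_rows])
        retained, report = qc_filter(ratings, threshold=0.5)
        assert "p0" not in retained
        assert set(report.loc[report.retained, "participant"]) == set(retained)
        assert len(retained) == 11

    def test_identical_raters_all_kept(self):
        ratings = make_ratings(np.random.default_rng(8), noise_sd=0.0)
        retained, _ = qc_filter(ratings)
        assert len(retained) == 12


class TestVarianceComponents:
    def test_noiseless_no_language_effect_universal_one(self):
        ratings = make_ratings(np.random.default_rng(3))
        vc = variance_components(ratings)
        assert vc.universal_share == pytest.approx(1.0, abs=1e-9)

    def test_language_effect_dominates_residual_when_planted(self):
        rng = np.random.default_rng(4)
        ratings = make_ratings(rng, lang_effect_sd=2.0, noise_sd=1.0,
                               n_lang=6, n_part=8, n_concepts=30)
        vc = variance_components(ratings)
        assert vc.language_share > vc.residual_share

    def test_shares_sum_to_one(self):
        ratings = make_ratings(np.random.default_rng(5), lang_effect_sd=0.5, noise_sd=0.7)
        vc = variance_components(ratings)
        assert sum(vc.as_tuple()) == pytest.approx(1.0, abs=1e-6)
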