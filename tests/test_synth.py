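import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from semscape import (WorldParams, emit_colex_edges, emit_embeddings,
                      emit_neural_rdms, emit_ratings, generate_world,
                      make_family_tree, mean_ilc, neurocognitive_space,
                      planted_pair_table, qc_filter, semantic_truth_rdm,
                      variance_components)
from semscape.rsa import build_pair_table, fit_env_model
from semscape.universality import Z_CLIP
from semscape import envdist


class TestFamilyTree:
    def test_shape(self):
        tree = make_family_tree(3, 2, seed=1)
        assert len(tree.leaves) == 6
        assert len(tree.families) == 3
        for leaf in tree.leaves:
            path = tree.path_to_root(leaf)
            assert path[-2] in tree.families  # family ancestor at depth 1

    def test_single_family_rejected(self):
        with pytest.raises(ValueError):
            make_family_tree(1, 4)

    def test_within_family_distance_below_between(self):
        tree = make_family_tree(3, 5, seed=2)
        fam = tree.family_map()
        for a, b in itertools.combinations(tree.leaves, 2):
            d = envdist.tree_distance(tree, a, b)
            if fam[a] == fam[b]:
                assert d < min(
                    envdist.tree_distance(tree, a, c)
                    for c in tree.leaves if fam[c] != fam[a]
                )


class TestWorldGeneration:
    def test_same_seed_identical_worlds(self):
        p = WorldParams(seed=4, n_families=3, langs_per_family=2,
                        n_target_concepts=10, embed_dim=30, n_idio_dims=10)
        w1, w2 = generate_world(p), generate_world(p)
        pd.testing.assert_frame_equal(w1.loadings, w2.loadings)
        pd.testing.assert_frame_equal(w1.climate, w2.climate)
        pd.testing.assert_frame_equal(w1.scaling, w2.scaling)
        t1 = emit_embeddings(w1)[0]
        t2 = emit_embeddings(w2)[0]
        np.testing.assert_array_equal(t1.vectors["t000"], t2.vectors["t000"])

    def test_rotations_orthogonal(self, small_world):
        for rot in small_world.rotations.values():
            np.testing.assert_allclose(rot.T @ rot, np.eye(rot.shape[0]), atol=1e-8)

    def test_scaling_positive_and_anchor_loadings_concentrated(self, small_world):
        assert (small_world.scaling.to_numpy() > 0).all()
        for dim, anchors in small_world.anchor_spec.items():
            for a in anchors:
                row = small_world.loadings.loc[a]
                assert row.idxmax() == dim

    def test_null_world_semantic_climate_uncorrelated(self):
        rhos = []
        for s in range(30):
            w = generate_world(WorldParams(seed=4000 + s, planted_beta_climate=0.0,
                                           n_families=5, langs_per_family=6))
            pt = planted_pair_table(w)
            rhos.append(stats.spearmanr(pt["semantic_distance"], pt["climate"]).statistic)
        assert abs(np.mean(rhos)) < 0.15


class TestEmbeddings:
    def test_noiseless_shared_structure_gives_perfect_ilc(self):
        p = WorldParams(seed=9, n_families=3, langs_per_family=2,
                        n_target_concepts=12, anchors_per_dim=2, embed_dim=30,
                        n_idio_dims=10, noise_sd=0.0, scaling_beta=0.0,
                        scaling_family_sd=0.0, scaling_noise_sd=0.0,
                        climate_deflection=0.0)
        w = generate_world(p)
        tables = emit_embeddings(w, shared_rotation=True, noise_sd=0.0, idio_scale=0.0)
        spaces = {t.language: neurocognitive_space(t, w.anchor_spec) for t in tables}
        assert mean_ilc(spaces) == pytest.approx(Z_CLIP, abs=1e-6)

    def test_concept_relabeling_invariance(self, small_world):
        tables = emit_embeddings(small_world)
        spaces = {t.language: neurocognitive_space(t, small_world.anchor_spec)
                  for t in tables}
        base = mean_ilc(spaces)
        perm = np.random.default_rng(0).permutation(len(next(iter(spaces.values())).data))
        permuted = {l: s.data.iloc[perm] for l, s in spaces.items()}
        assert mean_ilc(permuted) == pytest.approx(base, abs=1e-12)


class TestColexEmitter:
    def test_vanishing_density_gives_empty_list(self, small_world):
        edges = emit_colex_edges(small_world, density=1e-6)
        assert edges.empty

    def test_identical_loading_rows_rank_high(self):
        p = WorldParams(seed=31, n_families=3, langs_per_family=2,
                        n_target_concepts=30, embed_dim=30, n_idio_dims=10)
        rng = np.random.default_rng(77)
        twin_top = rand_top = 0
        for s in range(20):
            w = generate_world(WorldParams(**{**p.to_dict(), "seed": 31 + s}))
            # plant a twin pair with identical loadings
            w.loadings.loc["t001"] = w.loadings.loc["t000"]
            edges = emit_colex_edges(w, density=0.2, seed=5)
            weights = {}
            for a, b, n in edges.itertuples(index=False):
                weights[frozenset((a, b))] = n
            all_pairs = list(itertools.combinations(w.target_concepts, 2))
            all_w = np.array([weights.get(frozenset(pr), 0) for pr in all_pairs])
            threshold = max(np.quantile(all_w, 0.8), 1)
            twin_top += weights.get(frozenset(("t000", "t001")), 0) >= threshold
            a, b = rng.choice(w.target_concepts, size=2, replace=False)
            rand_top += weights.get(frozenset((a, b)), 0) >= threshold
        # twins land among the top-density edges more often than a random pair
        assert twin_top > rand_top


class TestRatingsEmitter:
    def test_zero_noise_perfect_intersubject_agreement(self, small_world):
        ratings = emit_ratings(small_world, participants_per_language=3,
                               rater_noise_sd=0.0)
        wide = ratings.pivot_table(index="participant",
                                   columns=["concept", "dimension"], values="rating")
        langs = ratings.drop_duplicates("participant").set_index("participant")["language"]
        for lang in langs.unique():
            members = [p for p in langs[langs == lang].index]
            r = np.corrcoef(wide.loc[members].to_numpy())
            assert np.allclose(r, 1.0, atol=1e-10)

    def test_careless_rater_flagged_by_qc(self, small_world):
        ratings = emit_ratings(small_world, participants_per_language=5,
                               rater_noise_sd=0.8, n_careless=1)
        retained, _ = qc_filter(ratings, threshold=0.5)
        assert "p0000" not in retained

    def test_universal_share_monotone_in_rater_noise(self, small_world):
        shares = []
        for noise in (1.5, 1.0, 0.5):
            ratings = emit_ratings(small_world, participants_per_language=5,
                                   rater_noise_sd=noise)
            shares.append(variance_components(ratings).universal_share)
        assert shares[0] < shares[1] < shares[2]

    def test_ratings_on_scale(self, small_world):
        ratings = emit_ratings(small_world, rater_noise_sd=1.0)
        assert ratings["rating"].between(0, 6).all()


class TestNeuralEmitter:
    def test_pure_semantic_signal_gives_unit_beta(self, small_world):
        rdms = emit_neural_rdms(small_world, lambda_sem=1.0, lambda_clim=0.0,
                                noise_sd=0.0)
        sem = semantic_truth_rdm(small_world)
        table = build_pair_table(rdms["r-ATL"], {"semantic": sem},
                                 small_world.families)
        fit = fit_env_model(table, ["semantic"])
        assert fit.beta("semantic") == pytest.approx(1.0, abs=1e-6)

    def test_other_rois_are_noise(self, small_world):
        rdms = emit_neural_rdms(small_world, lambda_sem=1.0, lambda_clim=0.5,
                                noise_sd=0.0, seed=8)
        sem = semantic_truth_rdm(small_world)
        v = rdms["l-IFG"].condensed()
        r = stats.pearsonr(v, sem.condensed()).statistic
        assert abs(r) < 0.9  # no planted structure outside the target ROI
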