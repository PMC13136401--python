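"""End-to-end synthetic pipeline with a reproducibility manifest.

Runs every stage on a generated world: fixture emission, anchor projection,
inter-language correlation with permutation nulls, environmental RDMs, the
crossed-family mixed regression, and the climate-PC projection.  All
randomness derives from the config seed; identical config + seed produces
byte-identical outputs, recorded in a manifest of SHA-256 digests.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import climatepc, envdist, rsa, spaces, synth, universality
from .io import (RunConfig, log_stage, read_embeddings, write_anchor_spec,
                 write_embeddings, write_table)
from .rdm import write_rdm

STAGES = ("synth", "project", "universality", "envdist", "rsa", "climatepc")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the artifact directory.

    Any stage failure aborts with the stage name attached to the exception.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        # ------------------------------------------------------------- synth
        stage = "synth"
        params = synth.WorldParams(
            n_families=config.n_families, langs_per_family=config.langs_per_family,
            n_target_concepts=config.n_target_concepts,
            anchors_per_dim=config.anchors_per_dim, embed_dim=config.embed_dim,
            noise_sd=config.noise_sd, planted_beta_climate=config.planted_beta_climate,
            seed=config.seed,
        )
        world = synth.generate_world(params)
        log_stage(stage, seed=config.seed, n_languages=len(world.languages),
                  n_concepts=len(world.concepts))
        emb_dir = out / "embeddings"
        emb_dir.mkdir(exist_ok=True)
        for t in synth.emit_embeddings(world):
            write_embeddings(t, emb_dir / f"{t.language}.vec")
        write_anchor_spec(world.anchor_spec, out / "anchors.tsv")
        write_table(world.climate, out / "climate.csv")
        write_table(world.coords, out / "coords.csv")
        (out / "world_truth.json").write_text(json.dumps(
            {"params": params.to_dict(),
             "families": world.families,
             "gamma": world.gamma.tolist()}, indent=2, sort_keys=True))

        # ----------------------------------------------------------- project
        stage = "project"
        tables = [read_embeddings(emb_dir / f"{l}.vec") for l in world.languages]
        neuro = {t.language: spaces.neurocognitive_space(t, world.anchor_spec)
                 for t in tables}
        for l, s in neuro.items():
            write_table(s.data, out / f"space_neuro_{l}.csv")
        log_stage(stage, n_languages=len(neuro),
                  shape=next(iter(neuro.values())).data.shape)

        # ------------------------------------------------------ universality
        stage = "universality"
        ilcm = universality.ilc_matrix(neuro)
        write_table(pd.DataFrame(ilcm.z, index=ilcm.labels, columns=ilcm.labels),
                    out / "ilc_matrix.csv")
        rng = np.random.default_rng((config.seed, 11))
        null_rw = universality.random_word_null(
            tables, targets=world.target_concepts,
            n_anchors=config.n_random_anchor_words,
            n_iters=config.n_null_iters, rng=rng)
        null_dist = universality.NullDistribution(
            "random_word", "mean_ILC", null_rw, ilcm.mean_z)
        pc1 = universality.pca_universality(neuro)
        (out / "null_summary.json").write_text(json.dumps({
            "mean_ilc_neurocognitive": ilcm.mean_z,
            "null_random_word_p95": null_dist.percentile(95),
            "one_tailed_p": null_dist.one_tailed_p,
            "n_iters": config.n_null_iters,
            "pc1_share": pc1,
            "seed": config.seed,
        }, indent=2, sort_keys=True))
        log_stage(stage, mean_ilc=round(ilcm.mean_z, 6), p=null_dist.one_tailed_p)

        # ----------------------------------------------------------- envdist
        stage = "envdist"
        env = synth.environment_rdms(world)
        for name, rdm in env.items():
            write_rdm(rdm, out / f"rdm_{name}.csv")
        log_stage(stage, kinds=",".join(env))

        # --------------------------------------------------------------- rsa
        stage = "rsa"
        sem = rsa.semantic_rdm(neuro)
        write_rdm(sem, out / "rdm_semantic.csv")
        table = rsa.build_pair_table(sem, env, world.families)
        fit = rsa.fit_env_model(table)
        fit_frame = pd.DataFrame({
            "beta": fit.params, "se": fit.bse,
            "ci_low": fit.conf_int["low"], "ci_high": fit.conf_int["high"],
            "p": fit.pvalues,
        })
        write_table(fit_frame, out / "fit_env_model.csv")
        log_stage(stage, n_pairs=fit.n, converged=fit.converged)

        # --------------------------------------------------------- climatepc
        stage = "climatepc"
        pca = climatepc.climate_pca(world.climate)
        projected = climatepc.project_semantic(neuro, pca.scores["PC1"])
        write_table(projected, out / "projected_pc1.csv")
        # directional ratio on domain-level summaries (the full map balances
        # exactly because columns are z-scored per language)
        summary = climatepc.domain_summary(projected, synth.concept_domains(world))
        write_table(summary, out / "domain_summary_pc1.csv")
        (out / "climate_pca.json").write_text(json.dumps({
            "explained_variance_ratio": [float(v) for v in pca.explained_variance_ratio[:2]],
            "association_ratio_positive_domains":
                climatepc.association_ratio(summary, "positive"),
        }, indent=2, sort_keys=True))
        log_stage(stage, evr1=float(pca.explained_variance_ratio[0]))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ---------------------------------------------------------------- manifest
    files = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
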