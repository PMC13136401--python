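"""Regressing semantic distance on environmental distances (mixed RSA).

Builds the semantic RDM over languages (1 - Fisher-z Pearson between
flattened concept x dimension matrices), the four environmental RDMs
(climate, culture, geography, linguistic history), and fits the crossed
family-random-intercepts model

    SemDist_ij = b0 + b1*Climate_ij + b2*Culture_ij + b3*Geography_ij
                 + b4*LingHist_ij + (1|Family_i) + (1|Family_j) + e_ij

with all variables standardized.  Also partitions the explained variance of
a planted neural RDM into semantic-unique, climate-unique and common parts.
"""

import semscape as ss
from semscape import rsa

world = ss.generate_world(ss.WorldParams(seed=1))
tables = ss.emit_embeddings(world)
spaces = {t.language: ss.neurocognitive_space(t, world.anchor_spec) for t in tables}

sem = rsa.semantic_rdm(spaces)
env = ss.environment_rdms(world)
table = rsa.build_pair_table(sem, env, world.families)
fit = rsa.fit_env_model(table)

print(f"{fit.n} language pairs, random structure: crossed family intercepts")
for name in ("climate", "culture", "geography", "linguistic_history"):
    lo, hi = fit.conf_int.loc[name]
    print(f"  beta_{name:<19s} {fit.beta(name):+.3f}  95% CI [{lo:+.3f}, {hi:+.3f}]"
          f"  p = {fit.pvalues[name]:.4f}")
print("(the world plants its climate effect through dimension scaling and")
print(" pattern deflection, so climate should carry the largest coefficient)")

neural = ss.emit_neural_rdms(world, lambda_sem=0.6, lambda_clim=0.3, noise_sd=0.6)
t3 = rsa.build_pair_table(neural["r-ATL"],
                          {"semantic": ss.semantic_truth_rdm(world),
                           "climate": env["climate"]}, world.families)
part = rsa.commonality_partition(t3, "semantic", "climate", n_boot=500, rng=4)
print(f"\ncommonality partition of the planted ROI (R2 = {part.r2_full:.3f}):")
print(f"  unique semantic {100 * part.unique_semantic:5.1f}%   "
      f"unique climate {100 * part.unique_climate:5.1f}%   "
      f"common {100 * part.common:5.1f}%")
print("The common share is variance the climate and semantic predictors")
print("explain jointly -- climate-linked semantic structure in the signal.")
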