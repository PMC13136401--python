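"""Climate PCA and projection of semantic spaces onto climate axes.

Decomposes the 19 bioclim-style variables by PCA, then weights each
language's column-standardized semantic space by its PC1 score and averages
across languages: positive map values mark concept-dimension associations
that strengthen toward the positive pole of the climate axis.
"""

import semscape as ss
from semscape import synth

world = ss.generate_world(ss.WorldParams(seed=1))
tables = ss.emit_embeddings(world)
spaces = {t.language: ss.neurocognitive_space(t, world.anchor_spec) for t in tables}

pca = ss.climate_pca(world.climate)
print("climate PCA explained variance: "
      + ", ".join(f"PC{i + 1} {100 * v:.1f}%"
                  for i, v in enumerate(pca.explained_variance_ratio[:2])))

projected = ss.project_semantic(spaces, pca.scores["PC1"])
strength = projected.abs().mean(axis=0).sort_values(ascending=False)
print("\ndimensions most modulated along climate PC1 (mean |projection|):")
print(strength.head(4).round(4).to_string())

summary = ss.domain_summary(projected, synth.concept_domains(world))
ratio = ss.association_ratio(summary, "positive")
print(f"\ndomain-level association ratio, positive direction: {ratio:.3f}")
print("(0.5 = balanced; above 0.5 means semantic relations are stronger")
print(" toward the positive pole of the climate axis)")
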