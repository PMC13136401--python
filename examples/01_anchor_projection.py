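"""Build anchor-projected semantic spaces for a synthetic multilingual world.

Generates a ground-truth world (30 languages, 5 families), emits per-language
embedding tables, and projects every language's concepts onto the 13
neurocognitive dimensions (color ... social) by averaged cosine similarity to
each dimension's anchor words.
"""

import semscape as ss

world = ss.generate_world(ss.WorldParams(seed=1))
tables = ss.emit_embeddings(world)
spaces = {t.language: ss.neurocognitive_space(t, world.anchor_spec) for t in tables}

lang = world.languages[0]
space = spaces[lang]
print(f"{len(spaces)} languages, space shape per language: {space.data.shape}")
print(f"\nFirst concepts of {lang} (rows: concepts, columns: dimensions):")
print(space.data.iloc[:5, :5].round(3))
print("\nEach entry is the mean cosine similarity between the concept's")
print("embedding vector and the anchor vectors of one dimension; values near 1")
print("mean the concept loads strongly on that dimension in this language.")
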