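import logging

import numpy as np
import pytest

from semscape import EmbeddingTable, WorldParams, generate_world

# community-detection warnings etc. are noise in test output
logging.getLogger("semscape").setLevel(logging.ERROR)


def toy_embeddings(language="aa", seed=0, n_concepts=6, dim=4):
    """Small dense embedding table with reproducible random vectors."""
    rng = np.random.default_rng(seed)
    concepts = [f"c{i}" for i in range(n_concepts)]
    return EmbeddingTable(
        language=language, dim=dim,
        vectors={c: rng.normal(size=dim) for c in concepts},
    )


@pytest.fixture
def toy_pair():
    return toy_embeddings("aa", seed=1), toy_embeddings("bb", seed=2)


@pytest.fixture
def small_world():
    """Fast structured world: 6 languages, 20 target concepts."""
    return generate_world(WorldParams(
        n_families=3, langs_per_family=2, n_target_concepts=20,
        anchors_per_dim=2, embed_dim=30, n_idio_dims=10, seed=17))
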