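import numpy as np
import pandas as pd
import pytest

from phylosym.feature_tables import FeatureTable, TaxonomyMap


@pytest.fixture
def small_table() -> FeatureTable:
    counts = pd.DataFrame(
        [[6, 0, 2], [2, 2, 0], [1, 1, 1]],
        index=["s1", "s2", "s3"],
        columns=["f1", "f2", "f3"],
    )
    meta = {"s1": "hostA", "s2": "hostA", "s3": "hostB"}
    return FeatureTable(counts, meta)


@pytest.fixture
def toy_taxonomy() -> TaxonomyMap:
    return TaxonomyMap({
        "f1": ("Bacteria", "P", "C", "O", "FamX", "Corynebacterium", "sp1"),
        "f2": ("Bacteria", "P", "C", "O", "FamX", "Corynebacterium", "sp2"),
        "f3": ("Bacteria", "P", "C", "O", "FamY", "Corynebacterium1", "sp3"),
    })


def random_table(rng: np.random.Generator, n_samples: int = 5,
                 n_features: int = 8, depth: int = 200) -> FeatureTable:
    counts = rng.multinomial(depth, rng.dirichlet(np.ones(n_features)),
                             size=n_samples)
    ids = [f"s{i}" for i in range(n_samples)]
    feats = [f"f{j}" for j in range(n_features)]
    return FeatureTable(pd.DataFrame(counts, index=ids, columns=feats),
                        {s: f"h{i % 2}" for i, s in enumerate(ids)})
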