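import numpy as np
import pandas as pd
import pytest

from microsync.table import OtuTable, TaxonomyMap


@pytest.fixture
def tiny_table() -> OtuTable:
    """3 OTUs x 2 samples with easy hand-checkable counts."""
    return OtuTable(
        pd.DataFrame(
            [[5, 0, 2], [3, 4, 0]],
            index=["Apr.S1", "Apr.S2"],
            columns=["otu1", "otu2", "otu3"],
        )
    )


@pytest.fixture
def tiny_taxonomy() -> TaxonomyMap:
    return TaxonomyMap.from_strings({
        "otu1": "k__Bacteria; p__Actinobacteria; c__Actinobacteria; o__Actinomycetales; f__ACK-M1; g__; s__",
        "otu2": "k__Bacteria; p__Cyanobacteria; c__Chloroplast; o__Chlorophyta; f__; g__; s__",
        "otu3": "k__Bacteria; p__Proteobacteria; c__Betaproteobacteria; o__Burkholderiales; f__Comamonadaceae; g__Limnohabitans; s__",
    })


@pytest.fixture
def random_table():
    """Factory: random count table of a given shape."""

    def make(n_samples=6, n_otus=10, seed=0, max_count=50) -> OtuTable:
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, max_count, size=(n_samples, n_otus))
        return OtuTable(
            pd.DataFrame(
                counts,
                index=[f"s{i+1}" for i in range(n_samples)],
                columns=[f"o{j+1}" for j in range(n_otus)],
            )
        )

    return make


@pytest.fixture
def random_tree():
    """Factory: random rooted tree (skbio TreeNode) over n leaf OTUs."""
    from microsync.simulate import simulate_tree

    def make(n_leaves=10, seed=0):
        otus = [f"o{j+1}" for j in range(n_leaves)]
        return otus, simulate_tree(otus, seed=seed)

    return make
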