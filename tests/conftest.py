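import numpy as np
import pandas as pd
import pytest

from assemblage.core import OtuTable, Phylogeny, SampleMetadata, Taxonomy
from assemblage.simulate import demo_config, simulate_metacommunity


@pytest.fixture
def small_table() -> OtuTable:
    data = pd.DataFrame(
        [[6, 2, 0, 1], [2, 2, 4, 0], [1, 0, 3, 5], [4, 4, 4, 4]],
        index=["s1", "s2", "s3", "s4"],
        columns=["A", "B", "C", "D"],
    )
    return OtuTable(data)


@pytest.fixture
def small_tree() -> Phylogeny:
    return Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def small_metadata() -> SampleMetadata:
    return SampleMetadata(
        pd.DataFrame(
            {
                "latitude": [30.0, 30.5, 31.0, 31.5],
                "longitude": [120.0, 120.0, 120.0, 120.0],
                "season": ["summer", "summer", "winter", "winter"],
                "area": ["north", "north", "south", "south"],
                "temperature": [10.0, 12.0, 14.0, 16.0],
                "salinity": [30.0, 31.0, 32.0, 33.0],
            },
            index=["s1", "s2", "s3", "s4"],
        )
    )


@pytest.fixture
def small_taxonomy() -> Taxonomy:
    return Taxonomy(
        pd.DataFrame(
            {"domain": "Archaea", "clade": ["MG-I", "MG-I", "Woese", "Woese"]},
            index=["A", "B", "C", "D"],
        )
    )


def random_table(
    n_samples: int, n_otus: int, seed: int, depth: int = 1000
) -> OtuTable:
    """Helper: a random long-tailed OTU table."""
    rng = np.random.default_rng(seed)
    p = rng.dirichlet(np.full(n_otus, 0.3))
    counts = rng.multinomial(depth, p, size=n_samples)
    return OtuTable(
        pd.DataFrame(
            counts,
            index=[f"S{i}" for i in range(n_samples)],
            columns=[f"O{i}" for i in range(n_otus)],
        )
    )


def tree_for_table(table: OtuTable, seed: int) -> Phylogeny:
    """A random ultrametric tree whose tips are exactly the table's OTUs."""
    from assemblage.simulate import simulate_phylogeny

    tree = simulate_phylogeny(len(table.otu_ids), seed)
    relabel = dict(zip(tree.tip_labels, table.otu_ids))
    for leaf in tree.tree.leaf_node_iter():
        leaf.taxon.label = relabel[leaf.taxon.label]
    return tree


@pytest.fixture(scope="session")
def demo_dataset():
    """One small synthetic dataset reused by read-only tests."""
    return simulate_metacommunity(demo_config("dispersal_limitation", seed=5))
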