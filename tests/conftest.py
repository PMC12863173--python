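import pytest

from strainpath.graph_model import VariationGraph


@pytest.fixture
def bubble_graph() -> VariationGraph:
    """Two strains sharing a backbone with one biallelic bubble.

    Nodes: 1 = shared prefix, 2/3 = alternative alleles, 4 = shared middle,
    5 = shared suffix. Strain A walks 1-2-4-5, strain B walks 1-3-4-5.
    """
    g = VariationGraph(species_taxid=562)
    g.add_node(1, "ACGTACGT")
    g.add_node(2, "A")
    g.add_node(3, "C")
    g.add_node(4, "GGGG")
    g.add_node(5, "TTTT")
    for a, b in [((1, "+"), (2, "+")), ((1, "+"), (3, "+")),
                 ((2, "+"), (4, "+")), ((3, "+"), (4, "+")),
                 ((4, "+"), (5, "+"))]:
        g.add_edge(a, b)
    g.add_path("strainA", [(1, "+"), (2, "+"), (4, "+"), (5, "+")])
    g.add_path("strainB", [(1, "+"), (3, "+"), (4, "+"), (5, "+")])
    return g


def random_variation_graph(rng, n_paths=None, max_steps=50):
    """A random chain-with-bubbles graph for property tests."""
    import numpy as np

    n_paths = n_paths if n_paths is not None else int(rng.integers(1, 7))
    n_cols = int(rng.integers(3, max_steps + 1))
    g = VariationGraph(species_taxid=int(rng.integers(1, 10_000)))
    next_id = 1
    columns = []  # per column: list of candidate node ids
    for _ in range(n_cols):
        n_alt = int(rng.integers(1, 3))
        ids = []
        for _ in range(n_alt):
            seq = "".join(rng.choice(list("ACGT"),
                                     size=int(rng.integers(1, 6))))
            g.add_node(next_id, seq)
            ids.append(next_id)
            next_id += 1
        columns.append(ids)
    for p in range(n_paths):
        steps = [(int(rng.choice(ids)), "+") for ids in columns]
        g.add_path(f"p{p}", steps, add_missing_edges=True)
    return g
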