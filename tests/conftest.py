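import networkx as nx
import pandas as pd
import pytest

from glianet import SeedSet


@pytest.fixture
def path_graph():
    """A -- B -- C chain."""
    return nx.path_graph(["A", "B", "C"])


@pytest.fixture
def edge_table_file(tmp_path):
    """Scored TSV edge table with a comment line and a duplicate edge."""
    p = tmp_path / "edges.tsv"
    p.write_text(
        "# source: synthetic\n"
        "gene_a\tgene_b\tscore\n"
        "A\tB\t0.8\n"
        "A\tC\t0.7\n"
        "B\tA\t0.95\n"
        "C\tD\t0.9\n"
    )
    return p


@pytest.fixture
def assoc_table_file(tmp_path):
    p = tmp_path / "assoc.tsv"
    p.write_text(
        "trait\tgene\tpvalue\n"
        "ALS\tG1\t1e-8\n"
        "ALS\tG1\t1e-6\n"
        "ALS\tG2\t1e-5\n"
        "sporadic ALS\tG3\t1e-4\n"
        "sporadic ALS\tG2\t1e-9\n"
        "Parkinson\tG9\t1e-12\n"
        "ALS\tG4\t1\n"
    )
    return p


@pytest.fixture
def two_clique_graph():
    """Two 20-node cliques joined by a single bridge edge."""
    g = nx.compose(
        nx.relabel_nodes(nx.complete_graph(20), {i: f"L{i:02d}" for i in range(20)}),
        nx.relabel_nodes(nx.complete_graph(20), {i: f"R{i:02d}" for i in range(20)}),
    )
    g.add_edge("L00", "R00")
    return g


@pytest.fixture
def uniform_seed(path_graph):
    return SeedSet("toy", {"B": 1.0})
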