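import numpy as np
import pytest

from psqc import (
    Alignment,
    DistanceModel,
    SimulationSpec,
    SubstitutionModel,
    parse_newick,
    simulate,
)


def attach_leaf(tree, edge_index, label):
    """Insert a new leaf into the middle of the edge_index-th edge."""
    edges = [n for n in tree.preorder_node_iter() if n.parent_node is not None]
    target = edges[edge_index]
    parent = target.parent_node
    parent.remove_child(target)
    mid = target.__class__()
    mid.add_child(target)
    leaf = target.__class__()
    leaf.taxon = tree.taxon_namespace.new_taxon(label)
    mid.add_child(leaf)
    parent.add_child(mid)
    for node in (mid, leaf):
        node.edge.length = 0.0
        node.edge.support = None
    return tree


def n_edges(tree):
    return sum(1 for n in tree.preorder_node_iter() if n.parent_node is not None)


def random_binary_tree(taxa, rng, min_len=0.1, max_len=1.0):
    from psqc import random_tree

    return random_tree(taxa, seed=rng, min_len=min_len, max_len=max_len)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def toy_alignment():
    return Alignment.from_records(
        [("A", "ACGTACGTAC"), ("B", "ACGTACGTAT"), ("C", "AC-TACGTAC")]
    )


@pytest.fixture(scope="session")
def reference12():
    """12-taxon reference tree used by the congruence tests."""
    return parse_newick(
        "(((A:0.15,B:0.15):0.08,(C:0.15,D:0.15):0.08):0.08,"
        "((E:0.15,F:0.15):0.08,(G:0.15,H:0.15):0.08):0.08,"
        "((I:0.15,J:0.15):0.08,(K:0.15,L:0.15):0.08):0.08);"
    )


@pytest.fixture(scope="session")
def aa_model():
    return SubstitutionModel.homogeneous(n_states=20)


@pytest.fixture(scope="session")
def poisson20():
    return DistanceModel("poisson", n_states=20)


@pytest.fixture(scope="session")
def small_simulated(reference12, aa_model):
    """Six clean genes on the reference tree (module-sized fixture)."""
    sm, truth = simulate(
        SimulationSpec(
            tree=reference12,
            model=aa_model,
            sites_per_gene=500,
            n_genes=6,
            seed=20260919,
        )
    )
    return sm, truth
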