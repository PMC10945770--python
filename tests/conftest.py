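import networkx as nx
import pytest

import evorate as ev


@pytest.fixture
def basic_tree():
    """Three-leaf tree with known path lengths: ((A:1,B:2):0.5,C:1.5);"""
    return ev.read_newick("((A:1,B:2):0.5,C:1.5);")


def random_tree(n_taxa: int, seed: int, cv: float = 0.5):
    """Non-ultrametric random tree: Yule topology with Gamma rate jitter."""
    species = ev.simulate_yule_tree(n_taxa, 1.0, seed=seed)
    return ev.jitter_branch_lengths(species, cv, seed=seed + 1_000_000)


def graph_patristic(tree):
    """Independent patristic oracle: weighted shortest paths on the tree graph."""
    g = nx.Graph()
    labels = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            labels[node.taxon.label if node.taxon else node.label] = id(node)
        if node.parent_node is not None:
            g.add_edge(id(node.parent_node), id(node), weight=node.edge.length or 0.0)
    dist = {}
    for a in labels:
        lengths = nx.single_source_dijkstra_path_length(g, labels[a])
        for b in labels:
            if a < b:
                dist[(a, b)] = lengths[labels[b]]
    return dist


def graph_root_to_tip(tree):
    """Independent root-to-tip oracle via shortest paths from the root node."""
    g = nx.Graph()
    labels = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            labels[node.taxon.label if node.taxon else node.label] = id(node)
        if node.parent_node is not None:
            g.add_edge(id(node.parent_node), id(node), weight=node.edge.length or 0.0)
    lengths = nx.single_source_dijkstra_path_length(g, id(tree.seed_node))
    return {lab: lengths[nid] for lab, nid in labels.items()}
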