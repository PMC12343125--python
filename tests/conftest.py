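import numpy as np
import pytest

from fbdstrata.trees import TreeSample, tree_from_newick


@pytest.fixture
def rng():
    return np.random.default_rng(20250929)


def dated(newick, tip_ages=None):
    return tree_from_newick(newick, tip_ages=tip_ages)


@pytest.fixture
def cherry_plus_one():
    """((A,B),C) with FADs A=10, B=8, C=5: the stratigraphically bad rooting."""
    return dated("((A:1,B:1):1,C:2);")


def random_dated_tree(labels, rng, max_age=10.0):
    """A random rooted binary dated tree with contemporaneous tips."""
    import dendropy

    from fbdstrata.trees import DatedTree, set_edge_lengths_from_ages

    tns = dendropy.TaxonNamespace()
    nodes = []
    for lab in labels:
        nd = dendropy.Node()
        nd.taxon = tns.require_taxon(label=lab)
        nd.age = 0.0
        nodes.append(nd)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.age = max(nodes[i].age, nodes[j].age) + float(rng.uniform(0.1, 3.0))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = nodes[0]
    set_edge_lengths_from_ages(tree)
    return DatedTree(tree)


def sample_of(trees):
    return TreeSample(list(trees))
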