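"""Shared oracles and generators for the test suite (independent of the
implementation paths they check wherever they serve as oracles)."""

import itertools

from conftest import random_dated_tree


def random_trees(n_taxa, n_trees, rng):
    labels = [f"T{i}" for i in range(n_taxa)]
    return [random_dated_tree(labels, rng) for _ in range(n_trees)]


# -- unrooted-topology enumeration (oracle for split information) -----------

def unrooted_topologies(labels):
    """All unrooted binary topologies, encoded as rooted-at-first-leaf tuples."""
    labels = list(labels)
    if len(labels) < 4:
        raise ValueError("need >= 4 leaves for a non-trivial unrooted tree")

    def insert(tree, leaf):
        yield (tree, leaf)
        if isinstance(tree, tuple):
            a, b = tree
            for na in insert(a, leaf):
                yield (na, b)
            for nb in insert(b, leaf):
                yield (a, nb)

    trees = [labels[1]]
    for lab in labels[2:]:
        trees = [t2 for t in trees for t2 in insert(t, lab)]
    return [(labels[0], t) for t in trees]


def topology_splits(tree, labels):
    """Non-trivial bipartitions of a tuple-encoded unrooted tree, as frozensets
    of labels, canonically oriented to contain the first label."""
    universe = frozenset(labels)
    ref = sorted(labels)[0]
    out = set()

    def walk(t):
        if not isinstance(t, tuple):
            return frozenset([t])
        below = frozenset()
        for c in t:
            below |= walk(c)
        side = below if ref in below else universe - below
        if len(side) >= 2 and len(universe - side) >= 2:
            out.add(side)
        return below

    walk(tree)
    return out


def exhaustive_split_containment(side_a, n):
    """Fraction of all unrooted binary n-leaf trees containing a split with
    |side| = side_a, by explicit enumeration."""
    labels = [f"x{i}" for i in range(n)]
    target = frozenset(labels[:side_a])
    ref = sorted(labels)[0]
    canon = target if ref in target else frozenset(labels) - target
    trees = unrooted_topologies(labels)
    hits = sum(1 for t in trees if canon in topology_splits(t, labels))
    return hits / len(trees)


# -- brute-force split matching (oracle for the clustering-info distance) ----

def best_matching_value(score_rows):
    """Maximum-total assignment value by explicit permutation search."""
    n_rows = len(score_rows)
    n_cols = len(score_rows[0]) if n_rows else 0
    k = max(n_rows, n_cols)
    padded = [[score_rows[i][j] if i < n_rows and j < n_cols else 0.0
               for j in range(k)] for i in range(k)]
    best = 0.0
    for perm in itertools.permutations(range(k)):
        best = max(best, sum(padded[i][perm[i]] for i in range(k)))
    return best
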