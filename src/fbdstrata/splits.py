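"""Bitmask split/clade bookkeeping shared by treespace and consensus code.

Taxa are assigned bit positions by sorted label order; bit 0 (the first label)
is the reference taxon. A split is stored canonically as the side containing
the reference taxon. A clade is the rooted descendant set of an internal node.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["Split", "taxon_index", "tree_clades", "tree_splits",
           "canonical_split", "split_sides", "is_trivial"]


def taxon_index(labels) -> dict:
    """Map sorted taxon labels to bit positions."""
    return {lab: i for i, lab in enumerate(sorted(labels))}


def canonical_split(mask: int, n: int) -> int:
    """Orient a bipartition mask so that it contains the reference taxon (bit 0)."""
    full = (1 << n) - 1
    if not mask & 1:
        mask ^= full
    return mask


def split_sides(mask: int, n: int) -> tuple:
    a = mask.bit_count()
    return a, n - a


def is_trivial(mask: int, n: int) -> bool:
    a, b = split_sides(mask, n)
    return a < 2 or b < 2


@dataclass(frozen=True)
class Split:
    """A canonical bipartition of the shared leafset."""

    mask: int
    n_taxa: int

    def __post_init__(self):
        if self.mask == 0 or self.mask == (1 << self.n_taxa) - 1:
            raise ValueError("neither side of a split may be empty")
        if not self.mask & 1:
            raise ValueError("split mask must contain the reference taxon (bit 0)")

    @property
    def sizes(self) -> tuple:
        return split_sides(self.mask, self.n_taxa)

    @property
    def trivial(self) -> bool:
        return is_trivial(self.mask, self.n_taxa)

    def taxa(self, index: dict) -> frozenset:
        rev = {i: lab for lab, i in index.items()}
        return frozenset(rev[i] for i in range(self.n_taxa) if self.mask >> i & 1)


def _node_masks(dt, index: dict) -> dict:
    masks = {}
    for nd in dt.tree.postorder_node_iter():
        if nd.is_leaf():
            masks[nd] = 1 << index[nd.taxon.label]
        else:
            m = 0
            for c in nd.child_nodes():
                m |= masks[c]
            masks[nd] = m
    return masks


def tree_clades(dt, index: dict, nontrivial_only: bool = True) -> set:
    """Rooted clade masks (descendant sets of internal nodes, root excluded)."""
    n = len(index)
    full = (1 << n) - 1
    masks = _node_masks(dt, index)
    out = set()
    for nd, m in masks.items():
        if nd.is_leaf() or m == full:
            continue
        if nontrivial_only and m.bit_count() < 2:
            continue
        out.add(m)
    return out


def tree_splits(dt, index: dict) -> frozenset:
    """Canonical non-trivial bipartitions implied by the tree's internal edges."""
    n = len(index)
    out = set()
    for m in tree_clades(dt, index, nontrivial_only=True):
        cm = canonical_split(m, n)
        if not is_trivial(cm, n):
            out.add(cm)
    return frozenset(out)
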