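"""Consensus trees, split information content, rogue taxa and MCC statistics.

The information content of a split follows the splitwise phylogenetic
information content (SPIC) idea: a split with side sizes a and b is contained
in a fraction P(s) = (2a-3)!!(2b-3)!!/(2n-5)!! of all unrooted binary trees,
so observing it in a summary tree conveys h(s) = -log2 P(s) bits. Splits
separating large clades are rarer and therefore more informative. Two
consensus-information modes are provided: "plain" sums h(s) over the resolved
splits; "support_weighted" discounts each split by its uncertainty,
sum of max(0, p*h(s) - H2(p)) with H2 the binary entropy of the support p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy

from .splits import canonical_split, is_trivial, taxon_index, tree_clades
from .trees import DatedTree, TreeSample

__all__ = [
    "SplitSupport",
    "Consensus",
    "RogueReport",
    "split_frequencies",
    "clade_frequencies",
    "majority_rule_consensus",
    "mcc_tree",
    "split_information",
    "consensus_information",
    "detect_rogues",
]


# ---------------------------------------------------------------------------
# split information
# ---------------------------------------------------------------------------

def _log2_double_factorial(m: int) -> float:
    """log2 of m!! for odd m (m!! = m * (m-2) * ... * 1; (-1)!! = 1!! = 1)."""
    if m < 2:
        return 0.0
    return sum(math.log2(i) for i in range(m, 1, -2))


def split_information(split, n_taxa: int) -> float:
    """Bits conveyed by a split: h(s) = -log2 of its containment fraction.

    ``split`` may be a bitmask over ``n_taxa`` leaves or a (a, b) side-size
    pair. Trivial splits (a singleton side) are present in every tree and
    carry 0 bits.
    """
    if isinstance(split, tuple):
        a, b = split
    else:
        a = int(split).bit_count()
        b = n_taxa - a
    if a + b != n_taxa or a < 1 or b < 1:
        raise ValueError(f"invalid split sides ({a}, {b}) for n={n_taxa}")
    if a < 2 or b < 2:
        return 0.0
    return (_log2_double_factorial(2 * n_taxa - 5)
            - _log2_double_factorial(2 * a - 3)
            - _log2_double_factorial(2 * b - 3))


@dataclass(frozen=True)
class SplitSupport:
    mask: int          # canonical bipartition bitmask
    n_taxa: int
    p: float           # frequency in the sample
    h: float           # information content, bits


# ---------------------------------------------------------------------------
# frequencies
# ---------------------------------------------------------------------------

def clade_frequencies(sample: TreeSample, index=None) -> dict:
    """Rooted clade mask -> frequency across the sample (non-trivial clades)."""
    if index is None:
        index = taxon_index(sample.taxa)
    counts: dict = {}
    for dt in sample:
        for m in tree_clades(dt, index):
            counts[m] = counts.get(m, 0) + 1
    n = len(sample)
    return {m: c / n for m, c in counts.items()}


def split_frequencies(sample: TreeSample, index=None) -> list:
    """Observed non-trivial bipartitions with frequencies and information."""
    if index is None:
        index = taxon_index(sample.taxa)
    n_taxa = len(index)
    counts: dict = {}
    for dt in sample:
        seen = set()
        for m in tree_clades(dt, index):
            cm = canonical_split(m, n_taxa)
            if not is_trivial(cm, n_taxa):
                seen.add(cm)
        for cm in seen:
            counts[cm] = counts.get(cm, 0) + 1
    n = len(sample)
    return sorted(
        (SplitSupport(mask=m, n_taxa=n_taxa, p=c / n,
                      h=split_information(m, n_taxa)) for m, c in counts.items()),
        key=lambda s: (-s.p, s.mask))


# ---------------------------------------------------------------------------
# majority-rule consensus
# ---------------------------------------------------------------------------

@dataclass
class Consensus:
    tree: dendropy.Tree
    index: dict                    # taxon label -> bit
    clade_supports: dict           # rooted clade mask -> frequency (> threshold)
    threshold: float
    node_count: int = field(init=False)

    def __post_init__(self):
        self.node_count = len(self.clade_supports)

    @property
    def n_taxa(self) -> int:
        return len(self.index)

    def splits(self) -> dict:
        """Canonical non-trivial bipartitions of the consensus with supports."""
        n = self.n_taxa
        out: dict = {}
        for m, p in self.clade_supports.items():
            cm = canonical_split(m, n)
            if not is_trivial(cm, n):
                out[cm] = max(out.get(cm, 0.0), p)
        return out


def _tree_from_clades(clade_masks, index: dict) -> dendropy.Tree:
    n = len(index)
    full = (1 << n) - 1
    tns = dendropy.TaxonNamespace()
    rev = {i: lab for lab, i in index.items()}
    nodes = {full: dendropy.Node()}
    for m in sorted(clade_masks, key=lambda x: -x.bit_count()):
        nd = dendropy.Node()
        nodes[m] = nd
        parent = min((pm for pm in nodes if pm != m and (pm & m) == m),
                     key=lambda x: x.bit_count())
        nodes[parent].add_child(nd)
    for i in range(n):
        leaf = dendropy.Node()
        leaf.taxon = tns.require_taxon(label=rev[i])
        bit = 1 << i
        parent = min((pm for pm in nodes if pm & bit), key=lambda x: x.bit_count())
        nodes[parent].add_child(leaf)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = nodes[full]
    return tree


def majority_rule_consensus(sample: TreeSample, threshold: float = 0.5) -> Consensus:
    """Rooted majority-rule consensus: exactly the clades with p > threshold.

    Clades above half-frequency are pairwise compatible (they nest or are
    disjoint), so the consensus always exists. ``threshold`` below 0.5 is
    rejected because compatibility is no longer guaranteed.
    """
    if threshold < 0.5:
        raise ValueError("threshold must be >= 0.5 for a well-defined consensus")
    if threshold >= 1.0:
        raise ValueError("threshold must be < 1.0")
    index = taxon_index(sample.taxa)
    freqs = clade_frequencies(sample, index)
    majority = {m: p for m, p in freqs.items() if p > threshold}
    tree = _tree_from_clades(majority, index)
    return Consensus(tree=tree, index=index, clade_supports=majority,
                     threshold=threshold)


# ---------------------------------------------------------------------------
# MCC tree
# ---------------------------------------------------------------------------

def mcc_tree(sample: TreeSample, criterion: str = "product"):
    """Maximum clade credibility tree from the sample.

    Scores each sampled tree by the product (sum of logs; default) or the sum
    of its non-trivial clades' posterior frequencies; ties broken by earliest
    sample index. Returns ``(DatedTree, sum of clade posteriors over the
    winner's internal nodes)``.
    """
    if criterion not in ("product", "sum"):
        raise ValueError(f"unknown MCC criterion {criterion!r}")
    index = taxon_index(sample.taxa)
    full = (1 << len(index)) - 1
    freqs = clade_frequencies(sample, index)
    best_i, best_score = 0, -math.inf
    for i, dt in enumerate(sample):
        clades = tree_clades(dt, index)
        if criterion == "product":
            score = sum(math.log(freqs[m]) for m in clades)
        else:
            score = sum(freqs[m] for m in clades)
        if score > best_score + 1e-12:
            best_i, best_score = i, score
    winner = sample[best_i]
    total = 0.0
    for nd in winner.tree.preorder_node_iter():
        if nd.is_leaf():
            continue
        mask = 0
        for lf in nd.leaf_iter():
            mask |= 1 << index[lf.taxon.label]
        if mask == full or mask.bit_count() < 2:
            total += 1.0  # root / stem clades are in every rooted tree
        else:
            total += freqs[mask]
    return winner, total


# ---------------------------------------------------------------------------
# consensus information
# ---------------------------------------------------------------------------

def _binary_entropy(p: float) -> float:
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return -(p * math.log2(p) + (1 - p) * math.log2(1 - p))


def consensus_information(consensus: Consensus, mode: str = "plain") -> float:
    """Total information (bits) communicated by a consensus tree's splits."""
    return _information_from_splits(consensus.splits(), consensus.n_taxa, mode)


def _information_from_splits(splits: dict, n_taxa: int, mode: str) -> float:
    if mode == "plain":
        return sum(split_information(m, n_taxa) for m in splits)
    if mode == "support_weighted":
        return sum(max(0.0, p * split_information(m, n_taxa) - _binary_entropy(p))
                   for m, p in splits.items())
    raise ValueError(f"unknown consensus-information mode {mode!r}")


# ---------------------------------------------------------------------------
# rogue detection
# ---------------------------------------------------------------------------

@dataclass
class RogueReport:
    rogues: list                 # removal order
    improvements: list           # per-rogue information gain, bits
    initial_information: float
    final_information: float
    final_taxa: list
    mode: str

    @property
    def mean_improvement(self) -> float:
        return (sum(self.improvements) / len(self.improvements)
                if self.improvements else 0.0)


def _drop_bit(mask: int, bit: int) -> int:
    low = mask & ((1 << bit) - 1)
    high = mask >> (bit + 1)
    return low | (high << bit)


def _majority_split_info(cladesets: list, n_taxa: int, mode: str) -> float:
    n_trees = len(cladesets)
    full = (1 << n_taxa) - 1
    counts: dict = {}
    for cs in cladesets:
        for m in cs:
            counts[m] = counts.get(m, 0) + 1
    splits: dict = {}
    for m, c in counts.items():
        p = c / n_trees
        if p <= 0.5 or m == full or m.bit_count() < 2:
            continue
        cm = canonical_split(m, n_taxa)
        if is_trivial(cm, n_taxa):
            continue
        splits[cm] = max(splits.get(cm, 0.0), p)
    return _information_from_splits(splits, n_taxa, mode)


def detect_rogues(sample: TreeSample, mode: str = "support_weighted",
                  min_taxa: int = 5, tol: float = 1e-9) -> RogueReport:
    """Greedy rogue-taxon search by consensus information gain.

    Repeatedly removes the single taxon whose exclusion most increases the
    majority-rule consensus information on the reduced leafset, until no
    removal gives a strictly positive gain (ties broken by label order).

    The default "support_weighted" information mode discounts each split by
    the binary entropy of its support, so the gain from removing an unstable
    leaf (restored support on the splits it obscured) can outweigh the loss
    from the smaller leafset; under "plain" scoring a smaller leafset always
    lowers every split's information, which makes removals much harder to
    justify and is rarely what rogue screening wants.
    """
    labels = sorted(sample.taxa)
    if len(labels) < min_taxa:
        raise ValueError(f"rogue detection needs >= {min_taxa} taxa")
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    cladesets = [frozenset(tree_clades(dt, index)) for dt in sample]

    current_info = _majority_split_info(cladesets, n, mode)
    initial = current_info
    rogues, gains = [], []
    while n > max(4, min_taxa - 1):
        best_gain, best_bit = tol, None
        for bit in range(n):
            reduced = [frozenset(m2 for m in cs
                                 if (m2 := _drop_bit(m, bit)).bit_count() >= 2
                                 and m2 != (1 << (n - 1)) - 1)
                       for cs in cladesets]
            gain = _majority_split_info(reduced, n - 1, mode) - current_info
            if gain > best_gain + 1e-12 or (best_bit is not None
                                            and abs(gain - best_gain) <= 1e-12
                                            and labels[bit] < labels[best_bit]):
                best_gain, best_bit = gain, bit
        if best_bit is None:
            break
        rogues.append(labels[best_bit])
        gains.append(best_gain)
        cladesets = [frozenset(m2 for m in cs
                               if (m2 := _drop_bit(m, best_bit)).bit_count() >= 2
                               and m2 != (1 << (n - 1)) - 1)
                     for cs in cladesets]
        labels.pop(best_bit)
        n -= 1
        current_info = _majority_split_info(cladesets, n, mode)
    return RogueReport(rogues=rogues, improvements=gains,
                       initial_information=initial,
                       final_information=current_info,
                       final_taxa=list(labels), mode=mode)


def prune_sample(sample: TreeSample, keep) -> TreeSample:
    """Prune every tree in a sample to the same kept leafset."""
    from .trees import prune_to_leafset

    return TreeSample([prune_to_leafset(dt, keep) for dt in sample],
                      provenance=dict(sample.provenance, pruned_to=sorted(keep)))
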