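"""Dated-tree containers and I/O.

Trees are rooted, with node ages measured in millions of years (Ma) before
present: time increases into the past, tips need not sit at age 0 (fossil
tips), and sampled ancestors are represented as zero-length pendant edges so
that standard Newick round-trips them. Node ages are the authoritative
quantity; branch lengths are durations derived as ``parent age - child age``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import dendropy

logger = logging.getLogger(__name__)

__all__ = [
    "DatedTree",
    "TreeSample",
    "tree_from_newick",
    "read_trees",
    "write_trees",
    "prune_to_leafset",
    "subsample_trees",
    "export_constraints",
]


@dataclass
class DatedTree:
    """A rooted tree whose nodes carry an ``age`` attribute (Ma before present).

    ``sampled_ancestors`` lists tip labels that represent fossil samples lying
    on internal lineages (serialized as zero-length pendant edges).
    """

    tree: dendropy.Tree
    sampled_ancestors: frozenset = frozenset()

    def __post_init__(self):
        self.validate()

    # -- basic accessors ---------------------------------------------------
    @property
    def taxa(self) -> frozenset:
        return frozenset(lf.taxon.label for lf in self.tree.leaf_node_iter())

    @property
    def root_age(self) -> float:
        return self.tree.seed_node.age

    def tip_ages(self) -> dict:
        return {lf.taxon.label: lf.age for lf in self.tree.leaf_node_iter()}

    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        labels = []
        for nd in self.tree.preorder_node_iter():
            if not hasattr(nd, "age") or nd.age is None:
                raise ValueError("every node must carry an age")
            if nd.age < -1e-9:
                raise ValueError(f"negative node age {nd.age}")
            if nd.parent_node is not None:
                if nd.parent_node.age < nd.age - 1e-9:
                    raise ValueError(
                        f"parent age {nd.parent_node.age} < child age {nd.age}"
                    )
            if nd.is_leaf():
                if nd.taxon is None or nd.taxon.label is None:
                    raise ValueError("unlabelled tip")
                labels.append(nd.taxon.label)
        if len(labels) != len(set(labels)):
            raise ValueError("tip labels must be unique")

    # -- construction / copies ---------------------------------------------
    def copy(self) -> "DatedTree":
        tns = dendropy.TaxonNamespace()
        new = dendropy.Tree(taxon_namespace=tns)

        def _cp(src, dst):
            dst.age = src.age
            if src.is_leaf():
                dst.taxon = tns.require_taxon(label=src.taxon.label)
            for ch in src.child_nodes():
                _cp(ch, dst.new_child())

        _cp(self.tree.seed_node, new.seed_node)
        set_edge_lengths_from_ages(new)
        return DatedTree(new, self.sampled_ancestors)


@dataclass
class TreeSample:
    """An ordered collection of :class:`DatedTree` over one shared leafset."""

    trees: list
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.trees:
            raise ValueError("TreeSample must contain at least one tree")
        ref = self.trees[0].taxa
        for i, t in enumerate(self.trees):
            if t.taxa != ref:
                raise ValueError(
                    f"tree {i} has a different leafset from tree 0: "
                    f"{sorted(t.taxa ^ ref)}"
                )

    @property
    def taxa(self) -> frozenset:
        return self.trees[0].taxa

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i):
        return self.trees[i]


# ---------------------------------------------------------------------------
# age <-> branch-length bookkeeping
# ---------------------------------------------------------------------------

def set_edge_lengths_from_ages(tree: dendropy.Tree) -> None:
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            nd.edge.length = None
        else:
            nd.edge.length = max(0.0, nd.parent_node.age - nd.age)


def ages_from_lengths(tree: dendropy.Tree, tip_ages: dict | None = None,
                      mismatch_tol: float = 1e-6) -> None:
    """Reconstruct node ages from branch lengths.

    Without ``tip_ages`` the deepest tip is anchored at age 0 (contemporaneous
    assumption); with a tip-age table the root age is anchored so every tip's
    stated age is honoured, and the table wins over branch lengths when they
    disagree beyond ``mismatch_tol`` myr (a warning is logged).
    """
    depth = {tree.seed_node: 0.0}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            bl = nd.edge.length if nd.edge.length is not None else 0.0
            depth[nd] = depth[nd.parent_node] + bl
    leaves = list(tree.leaf_node_iter())
    if tip_ages is None:
        root_age = max(depth[lf] for lf in leaves)
    else:
        missing = [lf.taxon.label for lf in leaves if lf.taxon.label not in tip_ages]
        if missing:
            raise KeyError(f"tip ages missing for taxa: {sorted(missing)}")
        root_age = max(depth[lf] + tip_ages[lf.taxon.label] for lf in leaves)
    for nd in tree.preorder_node_iter():
        nd.age = root_age - depth[nd]
    if tip_ages is not None:
        for lf in leaves:
            stated = tip_ages[lf.taxon.label]
            if abs(lf.age - stated) > mismatch_tol:
                logger.warning(
                    "tip %s: branch-length age %.6f != table age %.6f; "
                    "table wins", lf.taxon.label, lf.age, stated,
                )
            lf.age = stated


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def tree_from_newick(s: str, tip_ages: dict | None = None) -> DatedTree:
    """Parse a single Newick string into a DatedTree.

    Branch lengths are durations in myr; without ``tip_ages`` the deepest tip
    is placed at age 0 and the rest follow from depth arithmetic.
    """
    t = dendropy.Tree.get(data=s, schema="newick", rooting="default-rooted",
                          preserve_underscores=True)
    ages_from_lengths(t, tip_ages=tip_ages)
    return DatedTree(t)


def read_trees(path, format: str = "newick", tip_ages: dict | None = None,
               burnin: float = 0.0) -> TreeSample:
    """Read a Newick or NEXUS tree file into a :class:`TreeSample`.

    ``burnin`` drops that leading fraction of trees before any analysis
    (0.0 = keep all).
    """
    if format not in ("newick", "nexus"):
        raise ValueError(f"unsupported format {format!r}")
    tlist = dendropy.TreeList.get(path=str(path), schema=format,
                                  rooting="default-rooted",
                                  preserve_underscores=True)
    if len(tlist) == 0:
        raise ValueError(f"no trees found in {path}")
    trees = []
    for i, t in enumerate(tlist):
        ages_from_lengths(t, tip_ages=tip_ages)
        trees.append(DatedTree(t))
    ref = trees[0].taxa
    for i, t in enumerate(trees):
        if t.taxa != ref:
            raise ValueError(f"tree {i} in {path} has a mismatching leafset")
    if burnin:
        if not (0.0 <= burnin < 1.0):
            raise ValueError("burnin must be in [0, 1)")
        ndrop = int(len(trees) * burnin)
        trees = trees[ndrop:]
    return TreeSample(trees, provenance={"source": str(path),
                                         "burnin_dropped": burnin})


def write_trees(sample, path, format: str = "newick") -> None:
    """Write a TreeSample (or a single DatedTree) to Newick or NEXUS."""
    if isinstance(sample, DatedTree):
        sample = TreeSample([sample])
    tns = dendropy.TaxonNamespace(sorted(sample.taxa))
    tlist = dendropy.TreeList(taxon_namespace=tns)
    for dt in sample:
        cp = dt.copy()
        set_edge_lengths_from_ages(cp.tree)
        cp.tree.migrate_taxon_namespace(tns)
        tlist.append(cp.tree)
    kwargs = {"suppress_rooting": True, "unquoted_underscores": True,
              "real_value_format_specifier": ".12f"}
    if format == "newick":
        tlist.write(path=str(path), schema="newick", **kwargs)
    elif format == "nexus":
        tlist.write(path=str(path), schema="nexus",
                    translate_tree_taxa=True, **kwargs)
    else:
        raise ValueError(f"unsupported format {format!r}")


# ---------------------------------------------------------------------------
# pruning / subsampling
# ---------------------------------------------------------------------------

def prune_to_leafset(dt: DatedTree, keep) -> DatedTree:
    """Minimal spanning subtree of the kept tips, ages untouched.

    Degree-2 internal nodes are suppressed, so every pairwise MRCA age among
    kept taxa is identical before and after. The result is rooted at the MRCA
    of the kept taxa.
    """
    keep = frozenset(keep)
    missing = keep - dt.taxa
    if missing:
        raise KeyError(f"taxa not in tree: {sorted(missing)}")
    if len(keep) < 2:
        raise ValueError("need at least 2 taxa to prune to")

    tns = dendropy.TaxonNamespace()

    def _walk(nd):
        if nd.is_leaf():
            if nd.taxon.label not in keep:
                return None
            new = dendropy.Node()
            new.age = nd.age
            new.taxon = tns.require_taxon(label=nd.taxon.label)
            return new
        kids = [k for k in (_walk(c) for c in nd.child_nodes()) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        new = dendropy.Node()
        new.age = nd.age
        for k in kids:
            new.add_child(k)
        return new

    root = _walk(dt.tree.seed_node)
    new = dendropy.Tree(taxon_namespace=tns)
    new.seed_node = root
    set_edge_lengths_from_ages(new)
    return DatedTree(new, dt.sampled_ancestors & keep)


def subsample_trees(sample: TreeSample, fraction: float | None = None,
                    count: int | None = None, seed: int | None = None) -> TreeSample:
    """Uniform subsample without replacement, preserving original order."""
    import numpy as np

    n = len(sample)
    if (fraction is None) == (count is None):
        raise ValueError("give exactly one of fraction or count")
    if fraction is not None:
        if not (0.0 < fraction <= 1.0):
            raise ValueError("fraction must be in (0, 1]")
        count = int(round(n * fraction))
    if count > n:
        raise ValueError(f"requested {count} trees from a sample of {n}")
    if count < 1:
        raise ValueError("requested subsample is empty")
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(n, size=count, replace=False).tolist())
    prov = dict(sample.provenance)
    prov["subsampled"] = {"from": n, "to": count, "seed": seed}
    return TreeSample([sample[i] for i in idx], provenance=prov)


# ---------------------------------------------------------------------------
# taxonomic constraints
# ---------------------------------------------------------------------------

def export_constraints(genus_map: dict, ages, morph_taxa,
                       nexus_path, json_path) -> list:
    """Write genus-level monophyly constraints as NEXUS taxsets + JSON.

    ``genus_map`` maps taxon -> genus; ``ages`` is a TaxonAgeTable (or mapping
    taxon -> (max_ma, min_ma)); ``morph_taxa`` flags taxa with morphological
    data. Each genus must contain at least one morphology-bearing member,
    otherwise its taxa cannot be anchored in the tree and the constraint is
    rejected.
    """
    morph_taxa = frozenset(morph_taxa)
    intervals = getattr(ages, "intervals", ages)
    genera: dict = {}
    for taxon, genus in genus_map.items():
        genera.setdefault(genus, []).append(taxon)
    constraints = []
    for genus in sorted(genera):
        members = sorted(genera[genus])
        if not any(m in morph_taxa for m in members):
            raise ValueError(
                f"genus {genus!r} has no member with morphological data; every "
                "monophyly constraint needs at least one morphology-bearing member"
            )
        missing = [m for m in members if m not in intervals]
        if missing:
            raise KeyError(f"no age interval for taxa: {missing}")
        constraints.append({
            "genus": genus,
            "taxa": members,
            "morphology_taxa": sorted(set(members) & morph_taxa),
            "ages": {m: list(intervals[m]) for m in members},
        })
    with open(nexus_path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN SETS;\n")
        for c in constraints:
            taxa = " ".join(c["taxa"])
            fh.write(f"    TAXSET {c['genus']} = {taxa};\n")
        fh.write("END;\n")
    with open(json_path, "w") as fh:
        json.dump(constraints, fh, indent=2, sort_keys=True)
    return constraints
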