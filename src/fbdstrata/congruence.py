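"""Stratigraphic congruence of dated topologies against first appearances.

Given a rooted topology and a first-appearance datum (FAD) per tip, the
minimal node dating assigns every internal node the oldest FAD among its
descendants. The sum of the implied ghost ranges (parent minimal age minus
child minimal age over all non-root branches) is the minimum implied gap
(MIG, myr; lower is better). The gap excess ratio (GER) rescales MIG between
its minimum (Gmin) and maximum (Gmax) over all possible rooted topologies;
the stratigraphic consistency index (SCI) is the proportion of non-root
internal nodes whose clade does not first appear before its sister.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CongruenceResult",
    "node_min_ages",
    "mig",
    "g_min_max",
    "ger",
    "sci",
    "congruence_over_sample",
    "brute_force_extremes",
    "rooted_topologies",
    "mig_of_topology",
]


@dataclass(frozen=True)
class CongruenceResult:
    mig: float
    sci: float
    ger: float | None          # None when Gmax == Gmin
    ger_status: str            # "ok" or "degenerate_range"
    g_min: float
    g_max: float


def _check_fads(dt, fads: dict) -> None:
    missing = [t for t in dt.taxa if t not in fads]
    if missing:
        raise KeyError(f"no FAD for taxa: {sorted(missing)}")


def node_min_ages(dt, fads: dict) -> dict:
    """Minimal dating: each node's age = oldest FAD among its descendant tips."""
    _check_fads(dt, fads)
    ages = {}
    for nd in dt.tree.postorder_node_iter():
        if nd.is_leaf():
            ages[nd] = float(fads[nd.taxon.label])
        else:
            ages[nd] = max(ages[c] for c in nd.child_nodes())
    return ages


def mig(dt, fads: dict) -> float:
    """Minimum implied gap: total ghost range under minimal node dating (myr)."""
    if dt.n_tips() < 2:
        raise ValueError("MIG needs at least 2 tips")
    ages = node_min_ages(dt, fads)
    total = 0.0
    for nd in dt.tree.preorder_node_iter():
        if nd.parent_node is not None:
            total += ages[nd.parent_node] - ages[nd]
    return total


def ghost_ranges(dt, fads: dict) -> dict:
    """Per-branch implied gap (keyed by child node); sums to MIG."""
    ages = node_min_ages(dt, fads)
    return {nd: ages[nd.parent_node] - ages[nd]
            for nd in dt.tree.preorder_node_iter() if nd.parent_node is not None}


def g_min_max(fads) -> tuple:
    """Exact extremes of MIG over all rooted binary topologies.

    Gmin = max(FAD) - min(FAD) (attained by the age-ordered pectinate tree);
    Gmax = sum_i (max(FAD) - FAD_i) (attained when the oldest taxon is sister
    to everything else in turn, forcing every lineage back to the oldest FAD).
    """
    vals = list(fads.values()) if isinstance(fads, dict) else list(fads)
    if len(vals) < 2:
        raise ValueError("need at least 2 taxa")
    top = max(vals)
    g_min = top - min(vals)
    g_max = sum(top - v for v in vals)
    return g_min, g_max


def ger(dt, fads: dict):
    """Gap excess ratio: 1 - (MIG - Gmin)/(Gmax - Gmin); None when degenerate."""
    m = mig(dt, fads)
    g_lo, g_hi = g_min_max({t: fads[t] for t in dt.taxa})
    if g_hi - g_lo <= 0:
        return None
    return 1.0 - (m - g_lo) / (g_hi - g_lo)


def sci(dt, fads: dict) -> float:
    """Stratigraphic consistency index over non-root internal nodes.

    A node is consistent iff the oldest FAD within its clade is not older
    than the oldest FAD within its sister clade(s) (all other children of its
    parent); ties count as consistent. The root has no sister and is skipped.
    """
    ages = node_min_ages(dt, fads)
    consistent = 0
    assessable = 0
    for nd in dt.tree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        sisters = [c for c in nd.parent_node.child_nodes() if c is not nd]
        if not sisters:
            continue  # unifurcation (origin stem)
        assessable += 1
        if ages[nd] <= max(ages[s] for s in sisters):
            consistent += 1
    if assessable == 0:
        raise ValueError("no assessable internal nodes for SCI (need >= 3 tips)")
    return consistent / assessable


def congruence_result(dt, fads: dict) -> CongruenceResult:
    m = mig(dt, fads)
    g_lo, g_hi = g_min_max({t: fads[t] for t in dt.taxa})
    if g_hi - g_lo > 0:
        g = 1.0 - (m - g_lo) / (g_hi - g_lo)
        status = "ok"
    else:
        g, status = None, "degenerate_range"
    return CongruenceResult(mig=m, sci=sci(dt, fads), ger=g,
                            ger_status=status, g_min=g_lo, g_max=g_hi)


def congruence_over_sample(sample, ages, fad_resampling: str = "off",
                           n_reps: int = 1, seed: int | None = None) -> pd.DataFrame:
    """Per-tree congruence metrics for a posterior-like tree sample.

    ``ages`` is a TaxonAgeTable; with ``fad_resampling="uniform"`` each
    replicate draws FADs uniformly within each taxon's interval, otherwise the
    old interval bound is used once (``n_reps`` is ignored).
    """
    if fad_resampling not in ("off", "uniform"):
        raise ValueError(f"unknown fad_resampling {fad_resampling!r}")
    taxa = sample.taxa
    table = ages.subset(taxa)
    rng = np.random.default_rng(seed)
    reps = n_reps if fad_resampling == "uniform" else 1
    rows = []
    for rep in range(reps):
        if fad_resampling == "uniform":
            fads = table.fads(convention="resample", rng=rng)
        else:
            fads = table.fads(convention="old")
        for i, dt in enumerate(sample):
            r = congruence_result(dt, fads)
            rows.append({"tree_index": i, "replicate": rep, "MIG": r.mig,
                         "SCI": r.sci,
                         "GER": math.nan if r.ger is None else r.ger,
                         "ger_status": r.ger_status,
                         "g_min": r.g_min, "g_max": r.g_max})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# enumeration oracle
# ---------------------------------------------------------------------------

def rooted_topologies(labels):
    """All rooted binary topologies over the labels, as nested tuples.

    There are (2n-3)!! of them; bounded at n <= 9 to keep enumeration honest.
    """
    labels = list(labels)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 labels")
    if n > 9:
        raise ValueError(f"enumeration bounded at 9 labels, got {n}")

    def insert(tree, leaf):
        yield (tree, leaf)
        if isinstance(tree, tuple):
            a, b = tree
            for na in insert(a, leaf):
                yield (na, b)
            for nb in insert(b, leaf):
                yield (a, nb)

    trees = [labels[0]]
    for lab in labels[1:]:
        trees = [t2 for t in trees for t2 in insert(t, lab)]
    return trees


def mig_of_topology(tree, fads: dict) -> float:
    """MIG of a tuple-encoded rooted topology under minimal dating."""

    def walk(t):
        if not isinstance(t, tuple):
            return fads[t], 0.0
        parts = [walk(c) for c in t]
        top = max(m for m, _ in parts)
        gaps = sum(s + (top - m) for m, s in parts)
        return top, gaps

    _, total = walk(tree)
    return total


def brute_force_extremes(fads: dict) -> tuple:
    """(min MIG, max MIG) by exhaustive scan over all rooted binary topologies."""
    labels = sorted(fads)
    migs = [mig_of_topology(t, fads) for t in rooted_topologies(labels)]
    return min(migs), max(migs)
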