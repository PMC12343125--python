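"""Synthetic fossilized birth-death (FBD) data generation.

This module emulates everything a two-arm "resolved versus semi-resolved"
comparison needs without any external download:

* a clade evolving under a constant-rate FBD process (speciation rate
  ``lambda_``, extinction rate ``mu``, fossil-recovery rate ``psi``, all in
  events/lineage/myr, started from one lineage at ``t_origin`` Ma, with
  extant sampling probability ``rho``);
* the reconstructed dated tree spanning the sampled taxa, with fossils on
  internal lineages emitted as sampled ancestors (zero-length pendants);
* fossil occurrence tables, genus-level monophyletic groupings, discrete
  character matrices, stage-binned (sometimes deliberately imprecise) age
  intervals, and posterior-like tree distributions with tunable topological
  and node-age noise.

Species concept: speciation is bifurcating and every edge of the complete
tree is a distinct species, so each fossil sample belongs to exactly one
species. The reconstructed tree carries one tip per sampled species, placed
at its youngest fossil sample (or at 0 for a retained extant species); older
samples of the same species remain in the occurrence table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .occurrences import OCCURRENCE_COLUMNS, TaxonAgeTable
from .trees import DatedTree, TreeSample, set_edge_lengths_from_ages

__all__ = [
    "FBDParams",
    "Species",
    "CompleteHistory",
    "ReconstructedTree",
    "Timescale",
    "SimulationError",
    "ConditioningError",
    "simulate_fbd",
    "assign_genera",
    "simulate_characters",
    "select_morph_taxa",
    "bin_occurrence_ages",
    "generate_pseudo_posterior",
]


class SimulationError(RuntimeError):
    pass


class ConditioningError(SimulationError):
    pass


@dataclass(frozen=True)
class FBDParams:
    """Parameters of the constant-rate FBD process."""

    lambda_: float
    mu: float
    psi: float
    t_origin: float
    rho: float = 1.0
    condition: str = "min_samples"
    min_samples: int = 10
    max_lineages: int = 10_000
    max_attempts: int = 1_000
    seed: int | None = None

    def __post_init__(self):
        if self.lambda_ < 0 or self.mu < 0 or self.psi < 0:
            raise ValueError("rates must be non-negative")
        if self.t_origin <= 0:
            raise ValueError("t_origin must be positive")
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must lie in [0, 1]")
        if self.condition not in ("none", "min_samples"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")


@dataclass
class Species:
    """One edge of the complete tree: a species with a time span."""

    id: int
    parent_id: int | None
    start_age: float                  # older end (birth of the species)
    end_age: float | None = None      # younger end (branching/extinction/present)
    fate: str | None = None           # "birth" | "extinct" | "present"
    child_ids: tuple = ()

    @property
    def label(self) -> str:
        return f"S{self.id}"


@dataclass
class CompleteHistory:
    """The latent FBD realization: every lineage, event and fossil sample."""

    params: FBDParams
    species: dict                      # id -> Species
    occurrences: list                  # (occurrence_id, species_id, age)
    retained_extant: frozenset         # species ids alive at 0 and rho-sampled
    n_extant: int                      # alive at 0 before rho thinning
    total_duration: float              # summed alive-lineage duration (myr)
    events: list = field(default_factory=list)

    @property
    def sampled_species(self) -> frozenset:
        fossil = {sid for _, sid, _ in self.occurrences}
        return frozenset(fossil | set(self.retained_extant))

    def true_tree(self) -> DatedTree:
        """The complete dated species tree (tips = terminal species edges)."""
        tns = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=tns)
        root_sp = self.species[0]

        def build(sp: Species, node):
            node.age = sp.end_age
            if sp.fate == "birth":
                for cid in sp.child_ids:
                    build(self.species[cid], node.new_child())
            else:
                node.taxon = tns.require_taxon(label=sp.label)

        seed = tree.seed_node
        seed.age = self.params.t_origin
        build(root_sp, seed.new_child())
        set_edge_lengths_from_ages(tree)
        return DatedTree(tree)


@dataclass
class ReconstructedTree:
    """Dated tree spanning the sampled taxa, with per-tip roles.

    Roles are "extant", "fossil" or "sampled_ancestor" (a fossil species whose
    lineage has sampled descendants, drawn as a zero-length pendant edge).
    """

    tree: DatedTree
    roles: dict

    @property
    def taxa(self) -> frozenset:
        return self.tree.taxa


def _occurrence_frame(occurrences, genus_map=None) -> pd.DataFrame:
    rows = []
    for occ_id, sid, age in occurrences:
        label = f"S{sid}"
        rows.append({
            "occurrence_id": occ_id,
            "taxon": label,
            "rank": "species",
            "genus": genus_map.get(label) if genus_map else None,
            "max_ma": age,
            "min_ma": age,
        })
    return pd.DataFrame(rows, columns=OCCURRENCE_COLUMNS)


def _simulate_once(params: FBDParams, rng) -> CompleteHistory:
    species: dict = {}
    occurrences: list = []
    events: list = []
    next_id = 0

    def new_species(parent_id, start_age) -> int:
        nonlocal next_id
        sid = next_id
        next_id += 1
        species[sid] = Species(id=sid, parent_id=parent_id, start_age=start_age)
        return sid

    alive = [new_species(None, params.t_origin)]
    t = params.t_origin
    per_lineage = params.lambda_ + params.mu + params.psi
    total_duration = 0.0
    occ_counter = 0

    while alive and t > 0:
        n = len(alive)
        if n > params.max_lineages:
            raise SimulationError(
                f"lineage cap exceeded: {n} > max_lineages={params.max_lineages}")
        if per_lineage == 0:
            dt = t  # no events possible; jump to the present
        else:
            dt = rng.exponential(1.0 / (n * per_lineage))
        if dt >= t:
            total_duration += n * t
            t = 0.0
            break
        total_duration += n * dt
        t -= dt
        i = int(rng.integers(n))
        sid = alive[i]
        u = rng.random() * per_lineage
        if u < params.lambda_:
            sp = species[sid]
            sp.end_age, sp.fate = t, "birth"
            c1 = new_species(sid, t)
            c2 = new_species(sid, t)
            sp.child_ids = (c1, c2)
            alive[i] = c1
            alive.append(c2)
            events.append(("birth", t, sid))
        elif u < params.lambda_ + params.mu:
            sp = species[sid]
            sp.end_age, sp.fate = t, "extinct"
            alive.pop(i)
            events.append(("death", t, sid))
        else:
            occurrences.append((occ_counter, sid, t))
            occ_counter += 1
            events.append(("fossil", t, sid))

    retained = set()
    for sid in alive:
        sp = species[sid]
        sp.end_age, sp.fate = 0.0, "present"
        events.append(("present", 0.0, sid))
        if params.rho >= 1.0 or rng.random() < params.rho:
            retained.add(sid)

    return CompleteHistory(params=params, species=species,
                           occurrences=occurrences,
                           retained_extant=frozenset(retained),
                           n_extant=len(alive),
                           total_duration=total_duration, events=events)


def _reconstruct(history: CompleteHistory) -> ReconstructedTree:
    params = history.params
    sampled = history.sampled_species
    if not sampled:
        raise SimulationError("no sampled taxa; reconstructed tree is undefined")
    youngest_fossil: dict = {}
    for _, sid, age in history.occurrences:
        if sid not in youngest_fossil or age < youngest_fossil[sid]:
            youngest_fossil[sid] = age

    tns = dendropy.TaxonNamespace()
    roles: dict = {}

    def leaf(label, age, role):
        nd = dendropy.Node()
        nd.age = age
        nd.taxon = tns.require_taxon(label=label)
        roles[label] = role
        return nd

    def walk(sp: Species):
        """Reconstructed subtree reachable through this species' edge, or None."""
        kids = []
        if sp.fate == "birth":
            kids = [k for k in (walk(history.species[c]) for c in sp.child_ids)
                    if k is not None]
        if len(kids) >= 2:
            below = dendropy.Node()
            below.age = sp.end_age
            for k in kids:
                below.add_child(k)
        elif len(kids) == 1:
            below = kids[0]
        else:
            below = None

        if sp.id in history.retained_extant:
            # terminal edge by construction (fate == "present"), so below is None
            return leaf(sp.label, 0.0, "extant")
        if sp.id in youngest_fossil:
            age = youngest_fossil[sp.id]
            if below is None:
                return leaf(sp.label, age, "fossil")
            attach = dendropy.Node()
            attach.age = age
            attach.add_child(below)
            attach.add_child(leaf(sp.label, age, "sampled_ancestor"))
            return attach
        return below

    spine = walk(history.species[0])
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node.age = params.t_origin
    tree.seed_node.add_child(spine)
    set_edge_lengths_from_ages(tree)
    sa = frozenset(l for l, r in roles.items() if r == "sampled_ancestor")
    return ReconstructedTree(DatedTree(tree, sampled_ancestors=sa), roles)


def simulate_fbd(params: FBDParams):
    """Simulate one FBD realization.

    Returns ``(CompleteHistory, ReconstructedTree, occurrence DataFrame)``.
    Under ``condition="min_samples"`` the forward process is re-drawn (up to
    ``max_attempts`` times) until the reconstructed tree has at least
    ``min_samples`` tips.
    """
    rng = np.random.default_rng(params.seed)
    attempts = params.max_attempts if params.condition == "min_samples" else 1
    last_reason = "no sampled taxa"
    for _ in range(attempts):
        history = _simulate_once(params, rng)
        if not history.sampled_species:
            if params.condition == "none":
                # nothing was sampled; there is no reconstructed tree
                return history, None, _occurrence_frame(history.occurrences)
            continue
        recon = _reconstruct(history)
        if (params.condition == "min_samples"
                and recon.tree.n_tips() < params.min_samples):
            last_reason = (f"reconstructed tree had {recon.tree.n_tips()} tips "
                           f"< min_samples={params.min_samples}")
            continue
        return history, recon, _occurrence_frame(history.occurrences)
    raise ConditioningError(
        f"condition {params.condition!r} not met within "
        f"{params.max_attempts} attempts (last failure: {last_reason})")


# ---------------------------------------------------------------------------
# genus structure
# ---------------------------------------------------------------------------

def assign_genera(history: CompleteHistory, tau_genus: float) -> dict:
    """Map every sampled taxon to a genus.

    Genera are the maximal clades of the true species tree whose stem edge
    crosses the time horizon ``tau_genus`` (an edge spanning [end, start)
    crosses iff ``end <= tau_genus < start``). Sampled species that went
    extinct before ``tau_genus`` sit above every such clade and become
    singleton genera. Each genus is monophyletic on the true tree by
    construction.
    """
    if not (0.0 < tau_genus < history.params.t_origin):
        raise ValueError(
            f"tau_genus must lie in (0, {history.params.t_origin}), got {tau_genus}")
    out = {}
    for sid in sorted(history.sampled_species):
        cur = history.species[sid]
        genus = None
        while cur is not None:
            if cur.end_age <= tau_genus < cur.start_age:
                genus = f"G{cur.id}"
                break
            cur = (history.species[cur.parent_id]
                   if cur.parent_id is not None else None)
        if genus is None:
            genus = f"G{sid}"  # lineage ended before the genus horizon
        out[f"S{sid}"] = genus
    return out


# ---------------------------------------------------------------------------
# character matrices
# ---------------------------------------------------------------------------

def simulate_characters(rtree, n_chars: int, n_states: int = 2,
                        gamma_shape: float = 1.0, missing_frac: float = 0.0,
                        seed: int | None = None, rates=None) -> pd.DataFrame:
    """Simulate a discrete character matrix on a dated tree.

    Characters evolve independently under a symmetric ``n_states``-state
    Markov model (total leaving rate r per character, off-target states
    equiprobable) with per-character rate multipliers drawn from a mean-1
    gamma with shape ``gamma_shape`` (or given explicitly via ``rates``).
    A ``missing_frac`` fraction of cells is masked as "?" uniformly at random.
    """
    dt = rtree.tree if isinstance(rtree, ReconstructedTree) else rtree
    if n_chars < 1:
        raise ValueError("n_chars must be >= 1")
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    if not (0.0 <= missing_frac <= 1.0):
        raise ValueError("missing_frac must lie in [0, 1]")
    leaves = [lf for lf in dt.tree.leaf_node_iter()]
    if not leaves:
        raise ValueError("empty tree")
    rng = np.random.default_rng(seed)
    if rates is None:
        rates = rng.gamma(gamma_shape, 1.0 / gamma_shape, size=n_chars)
    else:
        rates = np.asarray(rates, dtype=float)
        if rates.shape != (n_chars,):
            raise ValueError("rates must have length n_chars")

    k = n_states
    labels = [lf.taxon.label for lf in leaves]
    data = np.empty((len(leaves), n_chars), dtype=int)
    leaf_pos = {lf: i for i, lf in enumerate(leaves)}

    state = {dt.tree.seed_node: rng.integers(k, size=n_chars)}
    for nd in dt.tree.preorder_node_iter():
        if nd.parent_node is None:
            cur = state[nd]
        else:
            t = nd.parent_node.age - nd.age
            # symmetric model: P(change) = (k-1)/k * (1 - exp(-k/(k-1) * r t))
            p_change = (k - 1) / k * (1.0 - np.exp(-k / (k - 1) * rates * t))
            parent = state[nd.parent_node]
            flip = rng.random(n_chars) < p_change
            shift = rng.integers(1, k, size=n_chars)
            cur = np.where(flip, (parent + shift) % k, parent)
            state[nd] = cur
        if nd.is_leaf():
            data[leaf_pos[nd]] = cur

    mat = pd.DataFrame(data, index=labels,
                       columns=[f"c{j + 1:04d}" for j in range(n_chars)])
    if missing_frac > 0:
        mask = rng.random(mat.shape) < missing_frac
        mat = mat.astype(object)
        mat[mask] = "?"
    return mat.sort_index()


# ---------------------------------------------------------------------------
# biased morphology-taxon selection
# ---------------------------------------------------------------------------

def select_morph_taxa(occurrences: pd.DataFrame, k: int, beta: float = 1.0,
                      seed: int | None = None) -> list:
    """Choose the taxa that "get morphology", biased toward abundant taxa.

    Taxa are drawn without replacement with probability proportional to
    (occurrence count)**beta; beta = 0 recovers uniform sampling, large beta
    concentrates on the most-sampled taxa (the sampling bias that violates
    the FBD assumption of uniform fossil recovery).
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    counts = occurrences.groupby("taxon").size().sort_index()
    if k > len(counts):
        raise ValueError(f"k={k} exceeds the {len(counts)} distinct taxa")
    rng = np.random.default_rng(seed)
    w = counts.to_numpy(dtype=float) ** beta
    chosen = rng.choice(counts.index.to_numpy(), size=k, replace=False,
                        p=w / w.sum())
    return sorted(chosen.tolist())


# ---------------------------------------------------------------------------
# stage binning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Timescale:
    """A synthetic geological timescale: stage boundaries in Ma, old to young.

    Stage ``i`` spans [boundaries[i+1], boundaries[i]); an age exactly on an
    internal boundary belongs to the older stage, and the oldest stage is
    closed at the top.
    """

    boundaries: tuple

    def __post_init__(self):
        b = self.boundaries
        if len(b) < 2 or any(b[i] <= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("boundaries must be strictly decreasing, oldest first")

    @classmethod
    def uniform(cls, max_ma: float, n_stages: int, min_ma: float = 0.0) -> "Timescale":
        edges = np.linspace(max_ma, min_ma, n_stages + 1)
        return cls(tuple(float(e) for e in edges))

    @property
    def n_stages(self) -> int:
        return len(self.boundaries) - 1

    @property
    def span(self) -> tuple:
        return self.boundaries[0], self.boundaries[-1]

    def stage_of(self, age: float) -> int:
        b = self.boundaries
        if not (b[-1] <= age <= b[0]):
            raise ValueError(f"age {age} outside timescale span {self.span}")
        for i in range(self.n_stages):
            if b[i + 1] <= age < b[i] or (i == 0 and age == b[0]):
                return i
        return self.n_stages - 1  # age == youngest boundary

    def stage_interval(self, i: int) -> tuple:
        return self.boundaries[i], self.boundaries[i + 1]


def bin_occurrence_ages(occurrences: pd.DataFrame, timescale: Timescale,
                        p_coarse: float = 0.0, widen_max: int | None = 3,
                        seed: int | None = None) -> pd.DataFrame:
    """Replace each occurrence's interval by its containing stage's bounds.

    With probability ``p_coarse`` the interval is widened to a run of adjacent
    stages (up to ``widen_max`` extra stages each side; ``widen_max=None``
    widens to the full timescale), emulating imprecisely correlated records.
    The true age (interval midpoint on input) always lies inside the reported
    interval.
    """
    if not (0.0 <= p_coarse <= 1.0):
        raise ValueError("p_coarse must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = occurrences.copy()
    b = timescale.boundaries
    n = timescale.n_stages
    max_rows = []
    min_rows = []
    for row in occurrences.itertuples():
        age = 0.5 * (row.max_ma + row.min_ma)
        try:
            k = timescale.stage_of(age)
        except ValueError as err:
            raise ValueError(
                f"occurrence_id {row.occurrence_id} ({row.taxon}): {err}") from err
        lo_i, hi_i = k, k
        if p_coarse > 0 and rng.random() < p_coarse:
            if widen_max is None:
                lo_i, hi_i = 0, n - 1
            else:
                lo_i = max(0, k - int(rng.integers(1, widen_max + 1)))
                hi_i = min(n - 1, k + int(rng.integers(1, widen_max + 1)))
        max_rows.append(b[lo_i])
        min_rows.append(b[hi_i + 1])
    out["max_ma"] = max_rows
    out["min_ma"] = min_rows
    return out


# ---------------------------------------------------------------------------
# posterior-like tree samples
# ---------------------------------------------------------------------------

class _ArrayTree:
    """Mutable array-backed rooted tree for fast proposal generation."""

    def __init__(self, dt: DatedTree):
        self.parent: list = []
        self.children: list = []
        self.age: list = []
        self.label: list = []   # None for internal nodes
        self.orig_age: list = []

        def add(nd, parent_idx):
            i = len(self.parent)
            self.parent.append(parent_idx)
            self.children.append([])
            self.age.append(nd.age)
            self.orig_age.append(nd.age)
            self.label.append(nd.taxon.label if nd.is_leaf() else None)
            if parent_idx >= 0:
                self.children[parent_idx].append(i)
            for c in nd.child_nodes():
                add(c, i)
            return i

        add(dt.tree.seed_node, -1)
        self.n = len(self.parent)
        self.leaves = [i for i in range(self.n) if self.label[i] is not None]

    def postorder(self) -> list:
        order, stack = [], [0]
        while stack:
            i = stack.pop()
            order.append(i)
            stack.extend(self.children[i])
        return order[::-1]

    def copy_shape(self):
        return ([list(c) for c in self.children], list(self.parent), list(self.age))


def _random_nni(children, parent, rng) -> None:
    """One rooted nearest-neighbour interchange, in place."""
    n = len(parent)
    candidates = [v for v in range(n)
                  if children[v] and parent[v] >= 0 and len(children[parent[v]]) >= 2]
    if not candidates:
        return
    v = candidates[int(rng.integers(len(candidates)))]
    p = parent[v]
    sibs = [s for s in children[p] if s != v]
    s = sibs[int(rng.integers(len(sibs)))]
    c = children[v][int(rng.integers(len(children[v])))]
    children[v].remove(c)
    children[p].remove(s)
    children[v].append(s)
    children[p].append(c)
    parent[s] = v
    parent[c] = p


def _postorder_of(children) -> list:
    order, stack = [], [0]
    while stack:
        i = stack.pop()
        order.append(i)
        stack.extend(children[i])
    return order[::-1]


def _mig_arrays(children, parent, leaf_fad) -> float:
    n = len(parent)
    m = [0.0] * n
    for i in _postorder_of(children):
        if not children[i]:
            m[i] = leaf_fad[i]
        else:
            m[i] = max(m[c] for c in children[i])
    return sum(m[parent[i]] - m[i] for i in range(n) if parent[i] >= 0)


def _to_dated_tree(at: _ArrayTree, children, age) -> DatedTree:
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)

    def build(i, nd):
        nd.age = age[i]
        if not children[i]:
            nd.taxon = tns.require_taxon(label=at.label[i])
        for c in children[i]:
            build(c, nd.new_child())

    build(0, tree.seed_node)
    set_edge_lengths_from_ages(tree)
    return DatedTree(tree)


def generate_pseudo_posterior(true_tree, n_trees: int, nni_rate: float = 1.0,
                              age_jitter_sd: float = 0.05,
                              congruence_weight: float = 0.0,
                              ages: TaxonAgeTable | None = None,
                              seed: int | None = None,
                              max_tries: int = 50) -> TreeSample:
    """Generate a posterior-like tree sample around a known true tree.

    Each tree is the true tree perturbed by Poisson(``nni_rate``) random
    nearest-neighbour interchanges plus multiplicative lognormal jitter
    (sd ``age_jitter_sd`` on the log scale) on internal node ages, applied
    root-to-tip with clamping so parent age >= child age while tips keep
    their sampled ages. With ``congruence_weight`` gamma > 0, proposals are
    accepted with probability min(1, exp(-gamma * (MIG - MIG_true))) —
    rejection resampling toward stratigraphically congruent topologies,
    emulating the way tip-age information makes incongruent regions of
    treespace implausible. The true tree's own MIG anchors the acceptance
    scale (the absolute minimum over all topologies is typically unattainable
    from local perturbations, which would drive every acceptance probability
    to zero and reduce the sampler to an extreme-value draw). After
    ``max_tries`` rejections the lowest-MIG proposal seen is kept, so the
    bias direction is preserved even for extreme gamma.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if nni_rate < 0 or age_jitter_sd < 0 or congruence_weight < 0:
        raise ValueError("nni_rate, age_jitter_sd, congruence_weight must be >= 0")
    dt = true_tree.tree if isinstance(true_tree, ReconstructedTree) else true_tree
    if congruence_weight > 0 and ages is None:
        raise ValueError("congruence_weight > 0 requires an age table")

    at = _ArrayTree(dt)
    rng = np.random.default_rng(seed)
    leaf_fad = [0.0] * at.n
    mig_anchor = 0.0
    if ages is not None:
        fads = ages.subset({at.label[i] for i in at.leaves}).fads("old")
        for i in at.leaves:
            leaf_fad[i] = fads[at.label[i]]
        mig_anchor = _mig_arrays(at.children, at.parent, leaf_fad)

    def propose():
        children, parent, age = at.copy_shape()
        for _ in range(rng.poisson(nni_rate)):
            _random_nni(children, parent, rng)
        # max descendant tip age per node (lower bound for clamping)
        floor = [0.0] * at.n
        post = _postorder_of(children)
        for i in post:
            if not children[i]:
                floor[i] = at.age[i]
            else:
                floor[i] = max(floor[c] for c in children[i])
        # pre-order jitter with clamping: each node sees its parent's final age
        for i in reversed(post):
            if not children[i]:
                continue  # tips keep their sampled ages
            prop = at.orig_age[i]
            if age_jitter_sd > 0:
                prop *= math.exp(rng.normal(0.0, age_jitter_sd))
            hi = age[parent[i]] if parent[i] >= 0 else math.inf
            age[i] = min(max(prop, floor[i]), hi)
        return children, parent, age

    out = []
    for _ in range(n_trees):
        if congruence_weight == 0:
            children, parent, age = propose()
        else:
            best, best_mig = None, math.inf
            accepted = None
            for _ in range(max_tries):
                cand = propose()
                m = _mig_arrays(cand[0], cand[1], leaf_fad)
                if m < best_mig:
                    best, best_mig = cand, m
                if rng.random() < min(1.0, math.exp(
                        -congruence_weight * (m - mig_anchor))):
                    accepted = cand
                    break
            children, parent, age = accepted if accepted is not None else best
        out.append(_to_dated_tree(at, children, age))
    return TreeSample(out, provenance={"generator": "pseudo_posterior",
                                       "nni_rate": nni_rate,
                                       "age_jitter_sd": age_jitter_sd,
                                       "congruence_weight": congruence_weight,
                                       "seed": seed})
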