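"""Treespace construction: tree distances, ordination, congruence landscape.

Two distances are provided over trees on a shared leafset: the classic
Robinson-Foulds distance (size of the symmetric difference of non-trivial
split sets) and the clustering-information distance, in which each split is
scored by the entropy of the two-block partition it induces and two trees are
compared by an optimal matching of their splits under mutual clustering
information — the distance is the information not shared. The pairwise matrix
is embedded by classical principal coordinates analysis (PCoA), and per-tree
congruence values are draped over the embedding as an inverse-distance
weighted "landscape", alongside per-group kernel density maps and spread
statistics.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import Delaunay, QhullError
from scipy.stats import gaussian_kde

from .splits import split_sides, taxon_index, tree_splits

logger = logging.getLogger(__name__)

__all__ = [
    "TreespaceEmbedding",
    "Landscape",
    "rf_distance",
    "clustering_info_distance",
    "distance_matrix",
    "pcoa_embed",
    "landscape",
    "density_map",
    "spread_stats",
]


# ---------------------------------------------------------------------------
# tree distances
# ---------------------------------------------------------------------------

def _shared_index(t1, t2):
    if t1.taxa != t2.taxa:
        raise ValueError("trees must share an identical leafset")
    return taxon_index(t1.taxa)


def rf_distance(t1, t2) -> int:
    """Robinson-Foulds: |symmetric difference| of non-trivial split sets."""
    index = _shared_index(t1, t2)
    return len(tree_splits(t1, index) ^ tree_splits(t2, index))


def _split_entropy(mask: int, n: int) -> float:
    a, b = split_sides(mask, n)
    p, q = a / n, b / n
    return -(p * math.log2(p) + q * math.log2(q))


def _mutual_clustering_info(m1: int, m2: int, n: int) -> float:
    full = (1 << n) - 1
    mi = 0.0
    for s1 in (m1, m1 ^ full):
        for s2 in (m2, m2 ^ full):
            nij = (s1 & s2).bit_count()
            if nij == 0:
                continue
            pij = nij / n
            pi = s1.bit_count() / n
            qj = s2.bit_count() / n
            mi += pij * math.log2(pij / (pi * qj))
    return mi


def clustering_info_distance(t1, t2) -> float:
    """Clustering-information distance in bits (0 iff identical split sets).

    Splits of the two trees are matched by maximum total mutual clustering
    information (optimal assignment); the distance is the summed split
    entropy of both trees minus twice the matched information.
    """
    index = _shared_index(t1, t2)
    n = len(index)
    s1 = sorted(tree_splits(t1, index))
    s2 = sorted(tree_splits(t2, index))
    h1 = sum(_split_entropy(m, n) for m in s1)
    h2 = sum(_split_entropy(m, n) for m in s2)
    if not s1 or not s2:
        return h1 + h2
    k = max(len(s1), len(s2))
    score = np.zeros((k, k))
    for i, a in enumerate(s1):
        for j, b in enumerate(s2):
            score[i, j] = _mutual_clustering_info(a, b, n)
    ri, ci = linear_sum_assignment(-score)
    shared = score[ri, ci].sum()
    return max(0.0, h1 + h2 - 2.0 * shared)


_METRICS = {"rf": rf_distance, "cid": clustering_info_distance}


def distance_matrix(sample, metric: str = "cid") -> np.ndarray:
    """Exact pairwise distance matrix over a TreeSample."""
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_METRICS)}")
    index = taxon_index(sample.taxa)
    n = len(index)
    splitsets = [tree_splits(t, index) for t in sample]
    m = len(sample)
    D = np.zeros((m, m))
    if metric == "rf":
        for i in range(m):
            for j in range(i + 1, m):
                D[i, j] = D[j, i] = len(splitsets[i] ^ splitsets[j])
        return D
    ent = {s: _split_entropy(s, n) for s in set().union(*splitsets)} if splitsets else {}
    h = [sum(ent[s] for s in ss) for ss in splitsets]
    sorted_sets = [sorted(ss) for ss in splitsets]
    for i in range(m):
        for j in range(i + 1, m):
            if splitsets[i] == splitsets[j]:
                continue
            a, b = sorted_sets[i], sorted_sets[j]
            if a and b:
                k = max(len(a), len(b))
                score = np.zeros((k, k))
                for x, ma in enumerate(a):
                    for y, mb in enumerate(b):
                        score[x, y] = _mutual_clustering_info(ma, mb, n)
                ri, ci = linear_sum_assignment(-score)
                shared = score[ri, ci].sum()
            else:
                shared = 0.0
            D[i, j] = D[j, i] = max(0.0, h[i] + h[j] - 2.0 * shared)
    return D


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

@dataclass
class TreespaceEmbedding:
    """PCoA coordinates of a set of trees plus the full eigenvalue spectrum."""

    coords: np.ndarray          # (n_trees, k), k = retained positive axes
    eigenvalues: np.ndarray     # full spectrum, non-increasing
    metric: str = "cid"
    groups: list | None = None  # per-tree group label
    values: np.ndarray | None = None  # per-tree congruence value

    def axes2(self) -> np.ndarray:
        """First two axes, zero-padded when fewer are available."""
        xy = np.zeros((self.coords.shape[0], 2))
        k = min(2, self.coords.shape[1])
        xy[:, :k] = self.coords[:, :k]
        return xy


def pcoa_embed(D: np.ndarray, k: int | None = None, metric: str = "cid",
               groups=None, values=None) -> TreespaceEmbedding:
    """Classical principal coordinates via double-centering + eigendecomposition.

    Axes with negative eigenvalues (non-Euclidean part of the distance) are
    dropped with a logged warning; the full spectrum is always reported.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("D must be symmetric")
    m = D.shape[0]
    J = np.eye(m) - np.ones((m, m)) / m
    B = -0.5 * J @ (D ** 2) @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-12, 1e-10 * max(abs(eigval[0]), 1.0)) if m else 0.0
    n_neg = int(np.sum(eigval < -tol))
    if n_neg:
        logger.warning("PCoA: dropping %d negative-eigenvalue axes "
                       "(non-Euclidean distances)", n_neg)
    pos = eigval > tol
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    if k is not None:
        coords = coords[:, :k]
    if coords.size == 0:
        coords = np.zeros((m, 1))
    return TreespaceEmbedding(coords=coords, eigenvalues=eigval, metric=metric,
                              groups=list(groups) if groups is not None else None,
                              values=(np.asarray(values, dtype=float)
                                      if values is not None else None))


# ---------------------------------------------------------------------------
# landscape / density / spread
# ---------------------------------------------------------------------------

def idw(points: np.ndarray, values: np.ndarray, query: np.ndarray,
        power: float = 2.0) -> np.ndarray:
    """Inverse-distance-weighted interpolation, exact at the data points."""
    points = np.atleast_2d(points)
    query = np.atleast_2d(query)
    out = np.empty(len(query))
    for qi, q in enumerate(query):
        d = np.linalg.norm(points - q, axis=1)
        hit = d < 1e-12
        if hit.any():
            out[qi] = values[hit][0]
            continue
        w = 1.0 / d ** power
        out[qi] = float(np.dot(w, values) / w.sum())
    return out


@dataclass
class Landscape:
    grid_x: np.ndarray
    grid_y: np.ndarray
    grid_z: np.ndarray        # NaN outside the convex hull
    points: np.ndarray
    values: np.ndarray
    power: float = 2.0

    def interpolate(self, xy) -> np.ndarray:
        return idw(self.points, self.values, np.atleast_2d(xy), self.power)


def landscape(embedding: TreespaceEmbedding, values=None, resolution: int = 101,
              power: float = 2.0) -> Landscape:
    """Congruence landscape: per-point values + IDW surface over the hull."""
    if values is None:
        values = embedding.values
    if values is None:
        raise ValueError("no per-tree values supplied")
    values = np.asarray(values, dtype=float)
    xy = embedding.axes2()
    gx = np.linspace(xy[:, 0].min(), xy[:, 0].max(), resolution)
    gy = np.linspace(xy[:, 1].min(), xy[:, 1].max(), resolution)
    GX, GY = np.meshgrid(gx, gy)
    Q = np.column_stack([GX.ravel(), GY.ravel()])
    Z = idw(xy, values, Q, power)
    try:
        tri = Delaunay(xy)
        inside = tri.find_simplex(Q) >= 0
        Z = np.where(inside, Z, np.nan)
    except QhullError:
        pass  # degenerate configurations keep the full grid
    return Landscape(grid_x=gx, grid_y=gy, grid_z=Z.reshape(GX.shape),
                     points=xy, values=values, power=power)


def density_map(embedding: TreespaceEmbedding, groups=None,
                resolution: int = 101, margin_bw: float = 5.0) -> dict:
    """Per-group 2-D Gaussian KDE on the first two embedding axes.

    Returns group -> (grid_x, grid_y, density). Each surface integrates to 1
    over its grid (within ~1% when the grid covers the support). Degenerate
    all-identical groups yield a single-cell spike with a warning.
    """
    if groups is None:
        groups = embedding.groups
    if groups is None:
        groups = ["all"] * embedding.coords.shape[0]
    xy = embedding.axes2()
    out = {}
    for g in sorted(set(groups)):
        pts = xy[[i for i, gg in enumerate(groups) if gg == g]]
        if len(pts) < 2:
            raise ValueError(f"group {g!r} needs >= 2 points for a density map")
        span = np.ptp(pts, axis=0)
        pad = np.maximum(span * 0.5, 1e-6) * margin_bw / 5.0
        gx = np.linspace(pts[:, 0].min() - pad[0], pts[:, 0].max() + pad[0], resolution)
        gy = np.linspace(pts[:, 1].min() - pad[1], pts[:, 1].max() + pad[1], resolution)
        GX, GY = np.meshgrid(gx, gy)
        try:
            kde = gaussian_kde(pts.T, bw_method="scott")
            Z = kde(np.vstack([GX.ravel(), GY.ravel()])).reshape(GX.shape)
        except np.linalg.LinAlgError:
            warnings.warn(f"group {g!r}: degenerate point cloud; "
                          "returning a delta-like density")
            Z = np.zeros(GX.shape)
            cx = np.argmin(np.abs(gx - pts[0, 0]))
            cy = np.argmin(np.abs(gy - pts[0, 1]))
            dx = gx[1] - gx[0] if len(gx) > 1 else 1.0
            dy = gy[1] - gy[0] if len(gy) > 1 else 1.0
            Z[cy, cx] = 1.0 / (dx * dy)
        out[g] = (gx, gy, Z)
    return out


def spread_stats(embedding, groups=None) -> dict:
    """Per-group spread: sum of (population) variances across axes, sum of
    per-axis ranges, and mean Euclidean distance to the group centroid."""
    coords = embedding.coords if isinstance(embedding, TreespaceEmbedding) \
        else np.asarray(embedding, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    if groups is None:
        groups = (embedding.groups if isinstance(embedding, TreespaceEmbedding)
                  and embedding.groups is not None
                  else ["all"] * coords.shape[0])
    out = {}
    for g in sorted(set(groups)):
        pts = coords[[i for i, gg in enumerate(groups) if gg == g]]
        if len(pts) == 0:
            raise ValueError(f"group {g!r} is empty")
        centroid = pts.mean(axis=0)
        out[g] = {
            "sum_of_variances": float(pts.var(axis=0, ddof=0).sum()),
            "sum_of_ranges": float(np.ptp(pts, axis=0).sum()),
            "mean_centroid_distance": float(
                np.linalg.norm(pts - centroid, axis=1).mean()),
        }
    return out
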