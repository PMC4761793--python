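"""Dice genetic distances, NJ / UPGMA tree building and locus-bootstrap support.

Distances live in :class:`skbio.DistanceMatrix`; trees in
:class:`skbio.TreeNode` (Newick-ready).  Both algorithms are written for
determinism: agglomeration ties are always broken toward the lowest input
index, so the same matrix yields the same tree on every run and platform.
"""

from __future__ import annotations

import warnings

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .markers import MarkerMatrix

__all__ = [
    "dice_distance",
    "neighbor_joining",
    "upgma",
    "bootstrap_support",
    "bipartitions",
]


def dice_distance(m: MarkerMatrix) -> DistanceMatrix:
    """Pairwise Dice (Sorensen) dissimilarity between individuals.

    For a pair, over loci scored in both: a = shared band presences and b, c
    the presences unique to each; D = 1 - 2a / (2a + b + c).  A pair with no
    shared scored locus is an error (downstream matrices must be complete);
    a pair with a = b = c = 0 (both all-absent) gets D = 0 with a warning.
    """
    if m.n_individuals < 2:
        raise ValueError("need at least two individuals")
    X = m.values()
    obs = ~np.isnan(X)
    P = np.where(obs, X, 0.0)  # presence indicator, 0 where missing
    A = np.where(obs, 1.0 - X, 0.0)  # absence indicator
    a = P @ P.T  # shared presences
    b_plus_c = P @ A.T + A @ P.T  # discordant among jointly scored
    n_shared = obs.astype(float) @ obs.astype(float).T
    if (n_shared == 0).any():
        i, j = np.argwhere(n_shared == 0)[0]
        raise ValueError(
            f"individuals {m.individuals[i]!r} and {m.individuals[j]!r} share no scored loci"
        )
    denom = 2 * a + b_plus_c
    if np.any((denom == 0) & ~np.eye(len(denom), dtype=bool)):
        warnings.warn("pair(s) with no band presences at jointly scored loci: D set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        D = 1.0 - np.where(denom > 0, 2 * a / np.where(denom > 0, denom, 1.0), 1.0)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0  # exact symmetry against float jitter
    return DistanceMatrix(D, ids=m.individuals)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; deterministic lowest-index tie-breaking.

    Returns an unrooted tree represented with a trifurcating root.  Negative
    branch-length estimates are clamped to zero with the deficit moved to the
    sister edge, preserving the path length between the joined pair.
    """
    n = dm.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    d = dm.data.astype(float).copy()
    nodes = [TreeNode(name=str(i)) for i in dm.ids]
    order = list(range(n))  # original insertion rank for tie-breaking

    while len(nodes) > 3:
        k = len(nodes)
        r = d.sum(axis=1)
        q = (k - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index pair among minimal Q
        i, j = min(
            map(tuple, np.argwhere(q == q.min())),
            key=lambda ij: (order[ij[0]], order[ij[1]]),
        )
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (k - 2))
        lj = d[i, j] - li
        li, lj = _clamp_pair(li, lj)
        new = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        # replace i by the new node, drop j
        d[i, :] = dnew
        d[:, i] = dnew
        d[i, i] = 0.0
        keep = [x for x in range(k) if x != j]
        d = d[np.ix_(keep, keep)]
        nodes[i] = new
        del nodes[j]
        order[i] = min(order[i], order[j])
        del order[j]

    # final 3-star: pendant lengths via the three-point formulas
    l0 = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    l1 = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    l2 = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    for node, ln in zip(nodes, (l0, l1, l2)):
        node.length = max(ln, 0.0)
    return TreeNode(children=list(nodes))


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li = max(li + lj, 0.0)
        lj = 0.0
    return li, lj


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def upgma(dm: DistanceMatrix) -> TreeNode:
    """Average-linkage agglomeration producing a rooted ultrametric tree.

    Node heights are half the merge distance, so root-to-leaf path lengths
    are equal.  The linkage update is size-weighted, i.e. cluster distances
    remain arithmetic means over the original leaf pairs (the "unweighted"
    pair-group method).  Ties break toward the lowest input index.
    """
    n = dm.shape[0]
    if n < 2:
        raise ValueError("upgma needs at least 2 labels")
    d = dm.data.astype(float).copy()
    nodes = [TreeNode(name=str(i)) for i in dm.ids]
    sizes = [1] * n
    heights = [0.0] * n
    order = list(range(n))

    while len(nodes) > 1:
        k = len(nodes)
        dd = d.copy()
        np.fill_diagonal(dd, np.inf)
        i, j = min(
            map(tuple, np.argwhere(dd == dd.min())),
            key=lambda ij: (order[ij[0]], order[ij[1]]),
        )
        if i > j:
            i, j = j, i
        h = d[i, j] / 2.0
        new = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = max(h - heights[i], 0.0)
        nodes[j].length = max(h - heights[j], 0.0)
        si, sj = sizes[i], sizes[j]
        dnew = (si * d[i, :] + sj * d[j, :]) / (si + sj)
        d[i, :] = dnew
        d[:, i] = dnew
        d[i, i] = 0.0
        keep = [x for x in range(k) if x != j]
        d = d[np.ix_(keep, keep)]
        nodes[i] = new
        sizes[i] = si + sj
        heights[i] = h
        order[i] = min(order[i], order[j])
        del nodes[j], sizes[j], heights[j], order[j]
    return nodes[0]


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions of an (un)rooted tree, in canonical form.

    Each internal edge splits the leaves in two; the split is represented by
    the lexicographically smaller side so rooted and unrooted encodings of
    the same topology compare equal.
    """
    leaves = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return out


def bootstrap_support(
    m: MarkerMatrix,
    method: str = "nj",
    n_reps: int = 1000,
    seed: int = 0,
) -> TreeNode:
    """Locus-bootstrap branch support on the point-estimate tree.

    Marker columns are resampled with replacement ``n_reps`` times; the
    support of each internal edge of the point-estimate tree is the
    percentage of replicate trees containing the same leaf bipartition.
    Support values are stored as internal node names (Newick convention).
    """
    if method != "nj":
        raise ValueError(f"unsupported method {method!r}")
    poly = [
        mk for mk, f in m.presence_frequencies().items() if not np.isnan(f) and 0 < f < 1
    ]
    if len(poly) < 2:
        raise ValueError("need at least 2 polymorphic loci for bootstrapping")
    tree = neighbor_joining(dice_distance(m))
    target = {bp: 0 for bp in bipartitions(tree)}
    rng = np.random.default_rng(seed)
    markers = np.asarray(m.markers)
    for _ in range(n_reps):
        cols = markers[rng.integers(0, len(markers), size=len(markers))]
        rep_calls = m.calls[list(cols)]  # duplicated columns keep their multiplicity
        rep_calls.columns = [f"c{i}" for i in range(len(cols))]
        rep_m = MarkerMatrix(rep_calls, m.group_labels, m.region_labels)
        rep_tree = neighbor_joining(dice_distance(rep_m))
        rep_bps = bipartitions(rep_tree)
        for bp in target:
            if bp in rep_bps:
                target[bp] += 1
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        leaves = frozenset(t.name for t in tree.tips())
        key = min(side, leaves - side, key=lambda s: (len(s), sorted(s)))
        if key in target:
            node.name = f"{100.0 * target[key] / n_reps:g}"
    return tree
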