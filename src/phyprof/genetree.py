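"""Desk-scale gene trees: corrected distances, NJ, nonparametric bootstrap.

Distances are Poisson-corrected p-distances; trees are built with the
Saitou–Nei neighbor-joining agglomeration.  Full ML tree inference is
deliberately out of scope — trees from this module are used for family
monophyly checks and transfer-donor placement only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .taxa import Node, TaxonomyTree

logger = logging.getLogger(__name__)

SATURATION_CAP = 0.95

__all__ = [
    "DistanceMatrix",
    "pdistance",
    "poisson_correct",
    "distance_matrix",
    "neighbor_joining",
    "splits",
    "bootstrap",
]


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite distances")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("nonzero diagonal")
        asym = np.abs(self.values - self.values.T)
        if asym.max(initial=0.0) > 1e-9:
            raise ValueError(f"asymmetric matrix (max deviation {asym.max():g})")
        if np.any(self.values < 0):
            raise ValueError("negative distances")

    def triangle_violations(self) -> list[tuple[str, str, str]]:
        """Triples violating the triangle inequality (reported, not fixed)."""
        d = self.values
        n = len(self.ids)
        out = []
        for i in range(n):
            for j in range(i + 1, n):
                for k in range(n):
                    if k in (i, j):
                        continue
                    if d[i, j] > d[i, k] + d[k, j] + 1e-12:
                        out.append((self.ids[i], self.ids[j], self.ids[k]))
        return out


def pdistance(a: str, b: str) -> tuple[float, int]:
    """(mismatch proportion, comparable sites) over non-gap columns."""
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal lengths")
    sites = 0
    diffs = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        sites += 1
        if x != y:
            diffs += 1
    if sites == 0:
        raise ZeroDivisionError("no comparable (non-gap) sites")
    return diffs / sites, sites


def poisson_correct(p: float, cap: float = SATURATION_CAP) -> float:
    """d = -ln(1 - p), with saturated pairs capped at ``cap``."""
    if p < 0:
        raise ValueError("p-distance cannot be negative")
    if p > cap:
        logger.info("p-distance %.3f capped at %.2f", p, cap)
        p = cap
    return -math.log(1.0 - p)


def distance_matrix(alignment: list[tuple[str, str]],
                    cap: float = SATURATION_CAP) -> DistanceMatrix:
    ids = [name for name, _ in alignment]
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p, _ = pdistance(alignment[i][1], alignment[j][1])
            d[i, j] = d[j, i] = poisson_correct(p, cap)
    return DistanceMatrix(ids, d)


def neighbor_joining(dm: DistanceMatrix) -> TaxonomyTree:
    """Saitou–Nei agglomeration; returns an unrooted tree (trifurcate root).

    Negative branch-length estimates are clamped to zero and logged.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")

    nodes: list[Node] = [Node(label) for label in dm.ids]
    d = dm.values.astype(float).copy()
    active = list(range(n))

    def clamp(x: float) -> float:
        if x < 0:
            logger.info("clamped negative NJ branch length %.4g to 0", x)
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        ai, aj = np.unravel_index(np.argmin(q), q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        parent = Node()
        nodes[i].length = clamp(li)
        nodes[j].length = clamp(lj)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # distances from the new node to the remaining ones
        new_row = np.zeros(d.shape[0] + 1)
        for ak, k in enumerate(active):
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    # connect the last three through a central node (three-point formulas)
    i, j, k = active
    root = Node()
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for idx, length in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = clamp(length)
        root.add_child(nodes[idx])
    return TaxonomyTree(root)


def splits(tree: TaxonomyTree) -> set[frozenset[str]]:
    """Nontrivial bipartitions, canonicalized to the side without the
    lexicographically first leaf."""
    all_leaves = frozenset(tree.leaf_labels)
    anchor = min(all_leaves)
    out: set[frozenset[str]] = set()
    for node in tree.preorder():
        if node.parent is None or node.is_leaf:
            continue
        side = frozenset(l.label for l in node.leaves())
        if anchor in side:
            side = all_leaves - side
        if 1 < len(side) < len(all_leaves) - 1:
            out.add(side)
        elif len(side) > 1:  # side of size n-1: still nontrivial for polytomy roots
            pass
    return out


def bootstrap(alignment: list[tuple[str, str]], n_reps: int, seed: int,
              cap: float = SATURATION_CAP) -> dict[frozenset[str], float]:
    """Per-split support of the point-estimate NJ tree.

    Columns are resampled with replacement per replicate; support is
    the fraction of replicate trees containing each split.  Bit-identical
    across runs for a fixed seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    point = neighbor_joining(distance_matrix(alignment, cap))
    target = splits(point)
    if not target:
        return {}
    counts = {s: 0 for s in target}
    rng = np.random.default_rng(seed)
    ids = [name for name, _ in alignment]
    seqs = [seq for _, seq in alignment]
    length = len(seqs[0])
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        resampled = ["".join(seq[c] for c in cols) for seq in seqs]
        rep_tree = neighbor_joining(
            distance_matrix(list(zip(ids, resampled)), cap))
        rep_splits = splits(rep_tree)
        for s in target:
            if s in rep_splits:
                counts[s] += 1
    return {s: counts[s] / n_reps for s in target}
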