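"""Neighbor-joining trees with locus-resampling bootstrap support.

Standard Saitou-Nei neighbor joining on a symmetric distance matrix, with
two deterministic conventions: ties in the Q matrix are broken toward the
lowest-index pair, and a negative branch length is clamped to zero with
the deficit transferred to its sister branch (the pair's summed length is
preserved).  The result is an unrooted tree represented with a
trifurcating root node; on additive distances NJ recovers the generating
topology and branch lengths exactly.

Bootstrap support resamples loci with replacement, rebuilds the
individual-level Nei D_A matrix and the NJ tree per replicate, and scores
each internal edge of the reference tree by the fraction of replicate
trees containing the same leaf bipartition.
"""

from __future__ import annotations

import numpy as np

from .containers import GenotypeMatrix
from .diversity import individual_distance_matrix


class TreeNode:
    """Minimal phylogenetic tree node: leaf (name) or internal (children)."""

    __slots__ = ("name", "children")

    def __init__(self, name=None, children=None):
        self.name = name
        self.children = children or []  # list of (TreeNode, branch_length)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self):
        if self.is_leaf():
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def newick(self, support=None) -> str:
        """Newick string; internal nodes labeled with bootstrap support if given."""
        all_leaves = frozenset(self.leaves())

        def fmt(node):
            if node.is_leaf():
                return str(node.name)
            s = "(" + ",".join(f"{fmt(c)}:{ln:.6f}" for c, ln in node.children) + ")"
            if support is not None:
                side = _canonical_side(frozenset(node.leaves()), all_leaves)
                if side in support:
                    s += f"{support[side]:.3f}"
            return s

        return fmt(self) + ";"

    def bipartitions(self) -> set:
        """Canonical internal-edge bipartitions (non-trivial splits)."""
        all_leaves = frozenset(self.leaves())
        out = set()

        def walk(node):
            if node.is_leaf():
                return frozenset([node.name])
            below = frozenset()
            for child, _ in node.children:
                side = walk(child)
                if 2 <= len(side) <= len(all_leaves) - 2:
                    out.add(_canonical_side(side, all_leaves))
                below = below | side
            return below

        walk(self)
        return out


def _canonical_side(side: frozenset, all_leaves: frozenset) -> frozenset:
    """Orientation-free bipartition key: the side not holding the min leaf."""
    anchor = min(all_leaves, key=str)
    return frozenset(all_leaves - side) if anchor in side else side


def nj_tree(distance_matrix, taxa=None) -> TreeNode:
    """Neighbor-joining tree from a symmetric zero-diagonal matrix (>= 3 taxa)."""
    D = np.array(distance_matrix, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or n < 3:
        raise ValueError("need a square matrix over >= 3 taxa")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if taxa is None:
        taxa = [f"t{i}" for i in range(n)]
    nodes = [TreeNode(name=t) for t in taxa]
    active = list(range(n))
    D = D.copy()
    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        R = sub.sum(axis=1)
        best = None
        for a in range(r):
            for b in range(a + 1, r):
                q = (r - 2) * sub[a, b] - R[a] - R[b]
                if best is None or q < best[0] - 1e-12:
                    best = (q, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        d_ij = sub[a, b]
        vi = 0.5 * d_ij + (R[a] - R[b]) / (2 * (r - 2))
        vj = d_ij - vi
        # clamp negatives, preserving vi + vj
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        vi, vj = max(vi, 0.0), max(vj, 0.0)
        new = TreeNode(children=[(nodes[i], vi), (nodes[j], vj)])
        # distances from the new node to every other active node
        new_row = np.zeros(D.shape[0] + 1)
        for c in range(r):
            k = active[c]
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (D[i, k] + D[j, k] - d_ij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [D.shape[0] - 1]
    # final three-way join (closed form)
    i, j, k = active
    vi = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    vj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    vk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    root = TreeNode(
        children=[
            (nodes[i], max(vi, 0.0)),
            (nodes[j], max(vj, 0.0)),
            (nodes[k], max(vk, 0.0)),
        ]
    )
    return root


def bootstrap_tree(G: GenotypeMatrix, n_reps: int = 1000, seed: int = 0):
    """Reference NJ tree plus per-edge bootstrap supports.

    Loci are the resampling unit (with replacement).  Returns
    ``(tree, supports)`` where supports maps each internal bipartition of
    the reference tree (a frozenset of individual ids) to the fraction of
    replicate trees containing it.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    D = individual_distance_matrix(G)
    ref = nj_tree(D, taxa=G.individuals)
    ref_parts = ref.bipartitions()
    hits = {part: 0 for part in ref_parts}
    for _ in range(n_reps):
        idx = rng.integers(0, G.n_loci, size=G.n_loci)
        Gb = G.subset_loci(idx)
        Db = individual_distance_matrix(Gb)
        parts = nj_tree(Db, taxa=G.individuals).bipartitions()
        for part in ref_parts:
            if part in parts:
                hits[part] += 1
    supports = {part: h / n_reps for part, h in hits.items()}
    return ref, supports
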