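"""Neighbor-joining trees from K2P distance matrices.

NJ (Saitou & Nei 1987, with the Studier & Keppler Q-criterion) serves as the
deterministic in-package replacement for maximum-likelihood inference: the
uses made of trees here - cluster membership and divergence visualisation -
depend only on topology and path lengths, both of which NJ recovers exactly
for additive (tree-like) distance matrices.

Negative branch-length estimates, which NJ can produce on noisy matrices,
are clamped to zero and the deficit is transferred to the sibling branch so
that path lengths through the joined pair are preserved (Kuhner &
Felsenstein's convention).  Branch lengths are in substitutions per site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distances import DistanceMatrix


@dataclass
class PhyloTree:
    """An unrooted tree: newick text plus an adjacency map for path queries."""

    newick: str
    adjacency: dict[str, dict[str, float]]
    leaves: list[str]

    def path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths on the unique a-b path (BFS)."""
        if a == b:
            return 0.0
        seen = {a: 0.0}
        frontier = [a]
        while frontier:
            nxt = []
            for u in frontier:
                for v, w in self.adjacency[u].items():
                    if v not in seen:
                        seen[v] = seen[u] + w
                        if v == b:
                            return seen[v]
                        nxt.append(v)
            frontier = nxt
        raise KeyError(f"no path between {a!r} and {b!r}")

    def leaf_distance_matrix(self) -> DistanceMatrix:
        n = len(self.leaves)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = self.path_length(self.leaves[i], self.leaves[j])
        return DistanceMatrix(list(self.leaves), d)


def _clamp(li: float, lj: float) -> tuple[float, float]:
    # move any negative deficit onto the sibling branch
    if li < 0.0:
        lj += li
        li = 0.0
    if lj < 0.0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def nj_tree(m: DistanceMatrix) -> PhyloTree:
    """Canonical neighbor-joining on a complete distance matrix.

    Raises ``ValueError`` for fewer than 3 leaves or a matrix with missing
    (NaN) entries, listing the offending pairs.
    """
    if len(m) < 3:
        raise ValueError("neighbor-joining needs at least 3 leaves")
    if not m.complete:
        missing = ", ".join(f"{a}/{b}" for a, b in m.missing_pairs())
        raise ValueError(f"incomplete distance matrix; missing pairs: {missing}")

    labels = list(m.ids)
    D = m.d.astype(float).copy()
    adjacency: dict[str, dict[str, float]] = {lab: {} for lab in labels}
    active = list(range(len(labels)))
    names = {i: labels[i] for i in active}
    next_internal = 0

    def connect(a: str, b: str, w: float) -> None:
        adjacency.setdefault(a, {})[b] = w
        adjacency.setdefault(b, {})[a] = w

    children: dict[str, list[tuple[str, float]]] = {}

    while len(active) > 3:
        n = len(active)
        r = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best, pair = None, None
        for ai in range(n):
            for aj in range(ai + 1, n):
                i, j = active[ai], active[aj]
                q = (n - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best - 1e-15:
                    best, pair = q, (i, j)
        i, j = pair
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = D[i, j] - li
        li, lj = _clamp(li, lj)
        u = f"_nj{next_internal}"
        next_internal += 1
        connect(u, names[i], li)
        connect(u, names[j], lj)
        children[u] = [(names[i], li), (names[j], lj)]
        # distances from the new node to the remaining taxa
        for k in active:
            if k in (i, j):
                continue
            D[i, k] = D[k, i] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        names[i] = u
        active.remove(j)

    a, b, c = active
    # three-point formulas for the final star
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = f"_nj{next_internal}"
    for node, length in ((names[a], la), (names[b], lb), (names[c], lc)):
        connect(root, node, max(length, 0.0))
    children[root] = [(names[a], max(la, 0.0)), (names[b], max(lb, 0.0)),
                      (names[c], max(lc, 0.0))]

    def newick(node: str) -> str:
        if node not in children:
            return node
        inner = ",".join(f"{newick(ch)}:{w:.10g}" for ch, w in children[node])
        return f"({inner})"

    return PhyloTree(
        newick=newick(root) + ";",
        adjacency=adjacency,
        leaves=list(m.ids),
    )
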