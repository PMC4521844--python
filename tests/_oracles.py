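"""Independent oracles used by the test suite.

These deliberately avoid the library's own algorithms: finger detection is
re-done by exhaustive combination enumeration, and NJ results are checked
against least-squares fits over explicitly enumerated topologies and
against path-length additivity.
"""

from __future__ import annotations

import itertools

import numpy as np

# ---------------------------------------------------------------------------
# Brute-force Zn-finger enumeration
# ---------------------------------------------------------------------------


def brute_force_fingers(seq: str, pattern, relax) -> set[tuple[int, ...]]:
    """All ligand octets satisfying the relaxed bounds, by exhaustive
    enumeration of candidate-position combinations."""
    universes = [relax.ligand_universe(pattern, s) for s in range(8)]
    any_lig = frozenset().union(*universes)
    cands = [i + 1 for i, ch in enumerate(seq) if ch in any_lig]
    bounds = relax.gap_bounds(pattern)
    octets = set()
    for combo in itertools.combinations(cands, 8):
        ok = all(seq[p - 1] in universes[s] for s, p in enumerate(combo))
        if not ok:
            continue
        for k in range(7):
            gap = combo[k + 1] - combo[k] - 1
            lo, hi = bounds[k]
            if not (lo <= gap <= hi):
                ok = False
                break
        if ok:
            octets.add(combo)
    return octets


# ---------------------------------------------------------------------------
# Topologies, least squares, additive matrices
# ---------------------------------------------------------------------------


class SimpleTree:
    """Unrooted tree as an undirected weighted edge list over node ids;
    leaves are ids 0..n-1."""

    def __init__(self, n: int, edges: list[tuple[int, int, float]]):
        self.n = n
        self.edges = edges

    def adjacency(self):
        adj: dict[int, list[tuple[int, float]]] = {}
        for a, b, w in self.edges:
            adj.setdefault(a, []).append((b, w))
            adj.setdefault(b, []).append((a, w))
        return adj

    def path_matrix(self) -> np.ndarray:
        adj = self.adjacency()
        D = np.zeros((self.n, self.n))
        for s in range(self.n):
            dist = {s: 0.0}
            stack = [s]
            while stack:
                u = stack.pop()
                for v, w in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            for t in range(self.n):
                D[s, t] = dist[t]
        return D

    def splits(self, labels: list[str]) -> set[frozenset[str]]:
        adj = self.adjacency()
        anchor = min(labels)
        out = set()
        for a, b, _ in self.edges:
            # leaves on b's side when edge (a,b) removed
            side = set()
            stack = [b]
            seen = {a, b}
            while stack:
                u = stack.pop()
                if u < self.n:
                    side.add(labels[u])
                for v, _w in adj[u]:
                    if v not in seen:
                        seen.add(v)
                        stack.append(v)
            names = side if anchor not in side else set(labels) - side
            if 2 <= len(names) <= self.n - 2:
                out.add(frozenset(names))
        return out


def enumerate_topologies(n: int) -> list[SimpleTree]:
    """Every unrooted binary leaf-labelled topology on n >= 3 leaves (unit
    branch lengths), built by stepwise insertion."""
    base = SimpleTree(n, [(0, n, 1.0), (1, n, 1.0), (2, n, 1.0)])
    trees = [base]
    next_internal = n + 1
    for leaf in range(3, n):
        new_trees = []
        for t in trees:
            for idx in range(len(t.edges)):
                a, b, _ = t.edges[idx]
                mid = next_internal + leaf  # unique enough per level
                edges = [e for j, e in enumerate(t.edges) if j != idx]
                edges += [(a, mid, 1.0), (b, mid, 1.0), (leaf, mid, 1.0)]
                new_trees.append(SimpleTree(n, edges))
        trees = new_trees
    return trees


def ls_fit(topology: SimpleTree, D: np.ndarray) -> tuple[float, np.ndarray]:
    """Least-squares branch lengths for a fixed topology; returns (residual
    sum of squares, fitted pairwise path matrix)."""
    n = topology.n
    edges = topology.edges
    adj = topology.adjacency()
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    A = np.zeros((len(pairs), len(edges)))
    edge_index = {}
    for k, (a, b, _) in enumerate(edges):
        edge_index[(a, b)] = k
        edge_index[(b, a)] = k
    for r, (i, j) in enumerate(pairs):
        # path from i to j
        prev = {i: None}
        stack = [i]
        while stack:
            u = stack.pop()
            if u == j:
                break
            for v, _w in adj[u]:
                if v not in prev:
                    prev[v] = u
                    stack.append(v)
        u = j
        while prev[u] is not None:
            A[r, edge_index[(prev[u], u)]] = 1.0
            u = prev[u]
    d = np.array([D[i, j] for i, j in pairs])
    x, *_ = np.linalg.lstsq(A, d, rcond=None)
    resid = float(((A @ x - d) ** 2).sum())
    fitted = SimpleTree(n, [(a, b, x[k]) for k, (a, b, _) in enumerate(edges)])
    return resid, fitted.path_matrix()


def random_additive_tree(
    n: int, rng: np.random.Generator, min_len: float = 0.1, max_len: float = 1.0
) -> SimpleTree:
    """Random unrooted binary topology with uniform branch lengths."""
    topos = None
    edges = [(0, n, 0.0), (1, n, 0.0), (2, n, 0.0)]
    t = SimpleTree(n, edges)
    internal = n + 1
    for leaf in range(3, n):
        idx = int(rng.integers(0, len(t.edges)))
        a, b, _ = t.edges[idx]
        mid = internal
        internal += 1
        es = [e for j, e in enumerate(t.edges) if j != idx]
        es += [(a, mid, 0.0), (b, mid, 0.0), (leaf, mid, 0.0)]
        t = SimpleTree(n, es)
    t.edges = [
        (a, b, float(rng.uniform(min_len, max_len))) for a, b, _ in t.edges
    ]
    return t
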