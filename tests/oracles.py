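"""Independent reference implementations used to cross-check the package.

Everything here is deliberately naive (enumeration / recursion / brute force)
and shares no code with vdjloci's implementations.
"""

from __future__ import annotations

import functools
import itertools

import numpy as np


def brute_global_score(a: str, b: str, match=2.0, mismatch=-1.0,
                       gap_open=-4.0, gap_extend=-1.0) -> float:
    """Optimal global alignment score by exhaustive recursion over edit
    operations, with affine gaps costing open + k*extend for a k-long run."""

    @functools.lru_cache(maxsize=None)
    def rec(i: int, j: int, last: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = -np.inf
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + rec(i + 1, j + 1, "M"))
        if i < len(a):
            cost = gap_extend if last == "A" else gap_open + gap_extend
            best = max(best, cost + rec(i + 1, j, "A"))
        if j < len(b):
            cost = gap_extend if last == "B" else gap_open + gap_extend
            best = max(best, cost + rec(i, j + 1, "B"))
        return best

    return rec(0, 0, "M")


def brute_fit_score(query: str, reference: str, **kw) -> float:
    """Fit alignment score: best global score of the query against any
    substring of the reference (empty substring included)."""
    best = -np.inf
    n = len(reference)
    for i in range(n + 1):
        for j in range(i, n + 1):
            sub = reference[i:j]
            if not sub:
                k = len(query)
                go = kw.get("gap_open", -4.0)
                ge = kw.get("gap_extend", -1.0)
                score = go + k * ge if k else 0.0
            else:
                score = brute_global_score(query, sub, **kw)
            best = max(best, score)
    return best


def brute_tm_window(aa: str, scale: dict[str, float], window: int) -> tuple[int, float]:
    """Leftmost window with maximal mean hydropathy, by direct search."""
    best_start, best_mean = 0, -np.inf
    for i in range(len(aa) - window + 1):
        mean = sum(scale[c] for c in aa[i : i + window]) / window
        if mean > best_mean + 1e-12:
            best_start, best_mean = i, mean
    return best_start, best_mean


# --- exhaustive unrooted topology search for additive distance matrices ----


def _all_topologies(n: int):
    """All unrooted leaf-labelled binary topologies on leaves 0..n-1, as edge
    lists over nodes (leaves 0..n-1, internal nodes n, n+1, ...)."""
    assert n >= 3
    trees = [[(0, n), (1, n), (2, n)]]
    next_internal = n + 1
    for leaf in range(3, n):
        new_trees = []
        for edges in trees:
            for k, (u, v) in enumerate(edges):
                mid = next_internal + (leaf - 3)  # fresh internal node id
                new = edges[:k] + edges[k + 1 :] + [(u, mid), (v, mid), (leaf, mid)]
                new_trees.append(new)
        trees = new_trees
    return trees


def _paths(edges, n: int) -> dict[tuple[int, int], list[int]]:
    adj: dict[int, list[tuple[int, int]]] = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))
    out = {}
    for a in range(n):
        stack = [(a, None, [])]
        seen = {a}
        while stack:
            node, _, path = stack.pop()
            if node < n and node != a:
                out[(a, node)] = path
            for nb, eidx in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append((nb, eidx, path + [eidx]))
    return out

def best_topology_by_least_squares(dist: np.ndarray):
    """Exhaustively fit every unrooted topology to the distance matrix by
    least-squares branch lengths; return (edges, sse, bipartitions) of the
    best fit. For an additive matrix the true topology fits with sse == 0."""
    n = dist.shape[0]
    pairs = list(itertools.combinations(range(n), 2))
    best = None
    for edges in _all_topologies(n):
        paths = _paths(edges, n)
        A = np.zeros((len(pairs), len(edges)))
        y = np.array([dist[a, b] for a, b in pairs])
        for row, (a, b) in enumerate(pairs):
            for eidx in paths[(a, b)]:
                A[row, eidx] = 1.0
        x, *_ = np.linalg.lstsq(A, y, rcond=None)
        sse = float(((A @ x) - y) ** 2 @ np.ones(len(pairs)))
        if best is None or sse < best[1]:
            best = (edges, sse, topology_bipartitions(edges, n))
    return best


def topology_bipartitions(edges, n: int) -> set[frozenset]:
    """Non-trivial bipartitions (smaller/lexicographic side) of a topology."""
    out = set()
    for k, _ in enumerate(edges):
        adj: dict[int, list[int]] = {}
        for idx, (u, v) in enumerate(edges):
            if idx == k:
                continue
            adj.setdefault(u, []).append(v)
            adj.setdefault(v, []).append(u)
        u0 = edges[k][0]
        seen = {u0}
        stack = [u0]
        while stack:
            node = stack.pop()
            for nb in adj.get(node, []):
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        side = frozenset(x for x in seen if x < n)
        other = frozenset(range(n)) - side
        if len(side) < 2 or len(other) < 2:
            continue
        out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return out


def tree_distance_matrix(edges, lengths: dict, n: int) -> np.ndarray:
    """Leaf-to-leaf path-length matrix of a weighted topology."""
    paths = _paths(edges, n)
    d = np.zeros((n, n))
    for (a, b), es in paths.items():
        d[a, b] = sum(lengths[e] for e in es)
    return d
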