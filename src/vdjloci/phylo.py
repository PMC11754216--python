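"""Distance-based phylogenetics: p-distances, neighbor joining, bootstrap.

The neighbor-joining implementation follows the classic Saitou–Nei
agglomeration (Q-matrix minimization, standard branch-length formulas,
negative branch lengths clamped to zero). Tie-breaking is deterministic: when
several pairs minimize Q, the pair whose (lexicographically sorted)
representative leaf names sort first is joined. Trees are held as scikit-bio
``TreeNode`` objects, which also provide Newick serialization.

Distances default to uncorrected p-distance with pairwise deletion (only
columns where both rows are non-gap are compared); a Poisson correction
``-ln(1 - p)`` is available for deeper divergences.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skbio import TreeNode

from .seq_core import SeqRecord


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")
        self.values = v


@dataclass
class PhyloTree:
    """Unrooted tree (trifurcating root) with optional bootstrap supports.

    ``supports`` maps an internal bipartition — the frozenset of leaf names on
    its smaller side (ties broken lexicographically) — to percent support.
    """

    tree: TreeNode
    supports: dict[frozenset, float] | None = None

    def leaf_names(self) -> set[str]:
        return {t.name for t in self.tree.tips()}


def p_distance(msa: list[SeqRecord], correction: str | None = None) -> DistanceMatrix:
    """Pairwise mismatch fraction over columns where both rows are non-gap."""
    if len(msa) < 2:
        raise ValueError("need at least two taxa")
    lengths = {len(r.seq) for r in msa}
    if len(lengths) != 1:
        raise ValueError("alignment rows must have equal length")
    ids = [r.id for r in msa]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate taxon ids")
    arr = np.array([list(r.seq) for r in msa])
    gap = arr == "-"
    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~gap[i] & ~gap[j]
            comparable = int(both.sum())
            if comparable == 0:
                raise ValueError(f"taxa {ids[i]!r} and {ids[j]!r} share no comparable columns")
            p = float((arr[i][both] != arr[j][both]).sum()) / comparable
            if correction == "poisson":
                if p >= 1.0:
                    raise ValueError("Poisson correction undefined at p = 1")
                p = -np.log(1.0 - p)
            elif correction is not None:
                raise ValueError(f"unknown correction {correction!r}")
            values[i, j] = values[j, i] = p
    return DistanceMatrix(ids=ids, values=values)


def _nj_tree(ids: list[str], dist: np.ndarray) -> TreeNode:
    """Saitou–Nei neighbor joining; returns an unrooted TreeNode."""
    nodes = [TreeNode(name=name) for name in ids]
    # representative = lexicographically smallest leaf under each node (tie-break key)
    reps = list(ids)
    d = dist.copy().astype(float)
    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                if np.isclose(q[i, j], qmin):
                    key = tuple(sorted((reps[i], reps[j])))
                    if best is None or key < best[0]:
                        best = (key, i, j)
        _, i, j = best
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (n - 2))
        lj = d[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = max(0.0, float(li))
        child_j.length = max(0.0, float(lj))
        parent = TreeNode(children=[child_i, child_j])
        new_d = (d[i] + d[j] - d[i, j]) / 2.0
        keep = [k for k in range(n) if k not in (i, j)]
        d = np.vstack([np.column_stack([d[np.ix_(keep, keep)], new_d[keep, None]]),
                       np.append(new_d[keep], 0.0)[None, :]])
        nodes = [nodes[k] for k in keep] + [parent]
        reps = [reps[k] for k in keep] + [min(reps[i], reps[j])]
    if len(nodes) == 3:
        dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
        lens = ((dab + dac - dbc) / 2, (dab + dbc - dac) / 2, (dac + dbc - dab) / 2)
        for node, ln in zip(nodes, lens):
            node.length = max(0.0, float(ln))
        root = TreeNode(children=list(nodes))
    elif len(nodes) == 2:
        nodes[0].length = nodes[1].length = max(0.0, float(d[0, 1] / 2))
        root = TreeNode(children=list(nodes))
    else:
        root = nodes[0]
    return root


def nj(matrix: DistanceMatrix) -> PhyloTree:
    if len(matrix.ids) < 3:
        raise ValueError("neighbor joining requires at least three taxa")
    return PhyloTree(tree=_nj_tree(matrix.ids, matrix.values))


def _bipartitions(tree: TreeNode, all_names: frozenset) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree, each canonicalized to the
    smaller side (lexicographic order breaks even splits)."""
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = all_names - side
        if len(side) < 2 or len(other) < 2:
            continue
        if (len(side), sorted(side)) <= (len(other), sorted(other)):
            out.add(side)
        else:
            out.add(other)
    return out


def bootstrap(
    msa: list[SeqRecord],
    n_reps: int = 1000,
    seed: int = 0,
    correction: str | None = None,
) -> PhyloTree:
    """NJ tree of the full alignment with column-resampling bootstrap supports.

    Support of an internal bipartition of the full-data tree is the percent of
    replicate trees (columns resampled with replacement) containing it.
    """
    full = nj(p_distance(msa, correction))
    names = frozenset(r.id for r in msa)
    target = _bipartitions(full.tree, names)
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    n_cols = len(msa[0].seq)
    rows = [r.seq for r in msa]
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep = [
            SeqRecord(id=r.id, seq="".join(r.seq[c] for c in cols), moltype=r.moltype)
            for r in msa
        ]
        rep_tree = nj(p_distance(rep, correction))
        rep_bps = _bipartitions(rep_tree.tree, names)
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
    supports = {bp: 100.0 * c / n_reps for bp, c in counts.items()}
    # annotate internal nodes with their support for Newick output
    for node in full.tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = names - side
        key = side if side in supports else other
        if key in supports:
            node.name = f"{supports[key]:g}"
    full.supports = supports
    return full


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    tree.tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> PhyloTree:
    return PhyloTree(tree=TreeNode.read(str(path), format="newick"))
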