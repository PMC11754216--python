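"""Percent-identity matrix over V segments and gene-family clustering.

V gene families are defined by pairwise nucleotide identity at a threshold
(80% by the usual immunogenetics convention). Identity comes from global
affine-gap alignment of the coding-strand sequences, counted over columns
where both rows are non-gap. Clustering is single-linkage by default (the
weakest reading of "sharing >= threshold identity"): families are the
connected components of the graph with an edge wherever identity >= threshold.
Complete-linkage is available for users who want every within-family pair to
meet the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform

from .seq_core import global_align


@dataclass
class IdentityMatrix:
    """Symmetric percent-identity matrix with a fixed id order (5'→3')."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(v, v.T):
            raise ValueError("identity matrix must be symmetric")
        if not np.allclose(np.diag(v), 100.0):
            raise ValueError("identity matrix diagonal must be 100")
        if v.min() < 0 or v.max() > 100:
            raise ValueError("identities must lie in [0, 100]")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_long(self) -> pd.DataFrame:
        """Long format (id_a, id_b, identity), one row per unordered pair."""
        rows = [
            (self.ids[i], self.ids[j], self.values[i, j])
            for i in range(len(self.ids))
            for j in range(i + 1, len(self.ids))
        ]
        return pd.DataFrame(rows, columns=["id_a", "id_b", "identity"])


@dataclass
class FamilyAssignment:
    """Segment name → family number (contiguous from 1, ordered by the
    family's 5'-most member)."""

    mapping: dict[str, int]
    threshold: float

    def n_families(self) -> int:
        return len(set(self.mapping.values()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(name, fam) for name, fam in self.mapping.items()],
            columns=["segment", "family"],
        )


def identity_matrix(named_seqs: list[tuple[str, str]], **align_kwargs) -> IdentityMatrix:
    """All-pairs global-alignment identity.

    *named_seqs* is a list of (name, coding-strand nucleotide sequence) in
    5'→3' locus order; inverted segments must be reverse-complemented by the
    caller (the annotator stores coding-strand sequence already).
    """
    if not named_seqs:
        raise ValueError("need at least one sequence")
    ids = [name for name, _ in named_seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("segment names must be unique")
    n = len(ids)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pct = global_align(named_seqs[i][1], named_seqs[j][1], **align_kwargs).identity_pct
            values[i, j] = values[j, i] = pct
    return IdentityMatrix(ids=ids, values=values)


def cluster_families(
    matrix: IdentityMatrix, threshold: float = 80.0, method: str = "single"
) -> FamilyAssignment:
    """Group segments into families at the identity threshold.

    ``method='single'`` takes connected components of the >=threshold graph;
    ``method='complete'`` cuts a complete-linkage dendrogram so that every
    within-family pair satisfies the threshold. Labels are renumbered by the
    position of each family's first (5'-most) member, so the assignment is
    invariant to input order up to that canonical relabeling.
    """
    n = len(matrix.ids)
    if method == "single":
        adjacency = csr_matrix(matrix.values >= threshold)
        _, labels = connected_components(adjacency, directed=False)
    elif method == "complete":
        if n == 1:
            labels = np.zeros(1, dtype=int)
        else:
            dist = squareform(100.0 - matrix.values, checks=False)
            labels = fcluster(linkage(dist, method="complete"), t=100.0 - threshold,
                              criterion="distance")
    else:
        raise ValueError(f"unknown linkage method {method!r}")
    relabel: dict[int, int] = {}
    mapping: dict[str, int] = {}
    for name, raw in zip(matrix.ids, labels):
        if raw not in relabel:
            relabel[raw] = len(relabel) + 1
        mapping[name] = relabel[raw]
    return FamilyAssignment(mapping=mapping, threshold=threshold)
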