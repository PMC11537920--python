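"""Vietoris-Rips persistent homology of a bounded dissimilarity matrix.

Two independent routes are provided:

``vr_persistence``
    The production path.  H0 comes from Kruskal union-find (finite dim-0
    deaths are exactly the minimum-spanning-tree edge weights); H1 from
    column reduction of the triangle boundary matrix of the flag complex
    over GF(2), columns processed in filtration order.

``brute_force_persistence``
    A deliberately naive oracle: enumerate every simplex up to dimension 2,
    build the full boundary matrix, and run the textbook left-to-right
    reduction with no optimizations.  Guarded to n <= 12 nodes.

Both routes share the same output conventions: dim-0 classes are all born
at 0 and every node contributes a dim-0 pair (one of them essential, with
infinite death); dim-1 pairs with zero lifetime (death == birth, a cycle
filled the instant it appears) are dropped.  The filtration runs to the
largest off-diagonal entry, beyond which the flag complex is complete and
nothing changes.

Simplices with equal filtration value are ordered by (value, dimension,
lexicographic vertex tuple) so the reduction is deterministic.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "PersistenceDiagram",
    "VietorisRipsPersistence",
    "adaptive_max_threshold",
    "vr_persistence",
    "brute_force_persistence",
]


@dataclasses.dataclass
class PersistenceDiagram:
    """Multiset of (birth, death, dim) triples from one filtration.

    ``pairs`` is an (m, 3) float array; essential classes carry
    ``death = inf``.  ``max_filtration`` is the adaptive filtration maximum
    (largest off-diagonal dissimilarity); ``n_nodes`` the number of
    vertices, which always equals the number of dim-0 pairs.
    """

    pairs: np.ndarray
    n_nodes: int
    max_filtration: float

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=float).reshape(-1, 3)

    def of_dim(self, dim: int, finite_only: bool = False) -> np.ndarray:
        """(k, 2) birth/death array of the requested dimension."""
        sel = self.pairs[self.pairs[:, 2] == dim][:, :2]
        if finite_only:
            sel = sel[np.isfinite(sel[:, 1])]
        return sel

    @property
    def finite_pairs(self) -> np.ndarray:
        return self.pairs[np.isfinite(self.pairs[:, 1])]

    def sorted_pairs(self) -> np.ndarray:
        """Rows sorted by (dim, birth, death) — a canonical multiset order."""
        idx = np.lexsort((self.pairs[:, 1], self.pairs[:, 0], self.pairs[:, 2]))
        return self.pairs[idx]

    def __eq__(self, other) -> bool:  # multiset equality
        if not isinstance(other, PersistenceDiagram):
            return NotImplemented
        a, b = self.sorted_pairs(), other.sorted_pairs()
        return a.shape == b.shape and bool(np.array_equal(a, b))


def _as_matrix(D) -> np.ndarray:
    M = D.D if hasattr(D, "D") else np.asarray(D, dtype=float)
    M = np.asarray(M, dtype=float)
    n = M.shape[0]
    if M.ndim != 2 or M.shape[1] != n:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(M, M.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be symmetric")
    if M.min() < 0:
        raise ValueError("dissimilarities must be non-negative")
    return M


def adaptive_max_threshold(D) -> float:
    """Smallest filtration value at which the flag complex is complete.

    Past the largest off-diagonal dissimilarity every pair is connected and
    the complex stops changing, so the filtration is run on [0, that value].
    """
    M = _as_matrix(D)
    n = M.shape[0]
    if n < 2:
        return 0.0
    off = M[~np.eye(n, dtype=bool)]
    return float(off.max())


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def vr_persistence(D, max_dim: int = 1) -> PersistenceDiagram:
    """H0/H1 persistence of the Vietoris-Rips filtration of ``D``."""
    if max_dim not in (0, 1):
        raise ValueError("max_dim must be 0 or 1")
    M = _as_matrix(D)
    n = M.shape[0]
    max_filt = adaptive_max_threshold(M)

    # edges in filtration order: (value, i, j) with i < j
    edges = sorted(
        ((M[i, j], i, j) for i in range(n) for j in range(i + 1, n)),
        key=lambda e: (e[0], e[1], e[2]),
    )

    pairs: list[tuple[float, float, int]] = []
    uf = _UnionFind(n)
    creator_edges: list[int] = []  # indices (into `edges`) of non-tree edges
    for idx, (w, i, j) in enumerate(edges):
        if uf.union(i, j):
            pairs.append((0.0, w, 0))  # a component dies
        else:
            creator_edges.append(idx)  # a 1-cycle is born
    pairs.append((0.0, np.inf, 0))  # the surviving component

    if max_dim >= 1 and n >= 3:
        edge_index = {(i, j): idx for idx, (_, i, j) in enumerate(edges)}
        triangles = sorted(
            (
                (max(M[i, j], M[i, k], M[j, k]), i, j, k)
                for i, j, k in itertools.combinations(range(n), 3)
            ),
            key=lambda t: (t[0], t[1], t[2], t[3]),
        )
        # reduce the triangle boundary matrix over the edge basis
        pivot_of: dict[int, frozenset[int]] = {}
        for w, i, j, k in triangles:
            col = {edge_index[(i, j)], edge_index[(i, k)], edge_index[(j, k)]}
            while col:
                piv = max(col)
                if piv not in pivot_of:
                    break
                col ^= pivot_of[piv]
            if col:
                piv = max(col)
                pivot_of[piv] = frozenset(col)
                birth = edges[piv][0]
                if w > birth:
                    pairs.append((birth, w, 1))
        # essential 1-cycles: creator edges never paired with a triangle.
        # The complete flag complex has trivial H1, so none survive here,
        # but the bookkeeping is kept for generality.
        for idx in creator_edges:
            if idx not in pivot_of:
                pairs.append((edges[idx][0], np.inf, 1))

    return PersistenceDiagram(pairs=np.array(pairs), n_nodes=n, max_filtration=max_filt)


def brute_force_persistence(D, max_dim: int = 1) -> PersistenceDiagram:
    """Oracle persistence by full boundary-matrix reduction; n <= 12 only."""
    if max_dim not in (0, 1):
        raise ValueError("max_dim must be 0 or 1")
    M = _as_matrix(D)
    n = M.shape[0]
    if n > 12:
        raise ValueError("brute-force oracle refuses n > 12 nodes")
    max_filt = adaptive_max_threshold(M)

    # enumerate all simplices up to dim 2 with their filtration values
    simplices: list[tuple[float, int, tuple[int, ...]]] = []
    for v in range(n):
        simplices.append((0.0, 0, (v,)))
    for i, j in itertools.combinations(range(n), 2):
        simplices.append((M[i, j], 1, (i, j)))
    if max_dim >= 1:
        for i, j, k in itertools.combinations(range(n), 3):
            simplices.append((max(M[i, j], M[i, k], M[j, k]), 2, (i, j, k)))
    simplices.sort(key=lambda s: (s[0], s[1], s[2]))
    position = {verts: idx for idx, (_, _, verts) in enumerate(simplices)}

    columns: list[set[int]] = []
    for _, dim, verts in simplices:
        if dim == 0:
            columns.append(set())
        else:
            columns.append(
                {position[tuple(f)] for f in itertools.combinations(verts, len(verts) - 1)}
            )

    # textbook left-to-right reduction over GF(2)
    low_of: dict[int, int] = {}  # pivot row -> column index
    paired: dict[int, int] = {}  # creator index -> destroyer index
    for j, col in enumerate(columns):
        while col:
            piv = max(col)
            if piv not in low_of:
                break
            col ^= columns[low_of[piv]]
        if col:
            low_of[max(col)] = j
            paired[max(col)] = j

    pairs: list[tuple[float, float, int]] = []
    for idx, (value, dim, _) in enumerate(simplices):
        if columns[idx]:
            continue  # destroyer column, not a creator
        if idx in paired:
            death_value = simplices[paired[idx]][0]
            if dim == 0:
                pairs.append((0.0, death_value, 0))
            elif dim == 1 and death_value > value:
                pairs.append((value, death_value, 1))
        else:
            if dim <= max_dim:
                pairs.append((0.0 if dim == 0 else value, np.inf, dim))

    return PersistenceDiagram(pairs=np.array(pairs), n_nodes=n, max_filtration=max_filt)


class VietorisRipsPersistence(BaseEstimator, TransformerMixin):
    """sklearn-style transformer from dissimilarity matrices to diagrams.

    ``transform`` maps a single square array (or a sequence of them) to the
    corresponding :class:`PersistenceDiagram` (or list thereof).
    """

    def __init__(self, max_dim: int = 1):
        self.max_dim = max_dim

    def fit(self, X=None, y=None):
        if self.max_dim not in (0, 1):
            raise ValueError("max_dim must be 0 or 1")
        return self

    def transform(self, X):
        if (isinstance(X, np.ndarray) and X.ndim == 2) or hasattr(X, "D"):
            return vr_persistence(X, max_dim=self.max_dim)
        return [vr_persistence(x, max_dim=self.max_dim) for x in X]
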