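"""Connectivity-profile similarity and the minimally connected kNN graph.

The connectivity profile of a seed vertex is its row of streamline
visitation counts over target voxels.  Pairwise profile similarity is
measured with the eta-squared (η²) coefficient — the fraction of the
total variance of two profiles explained by their point-wise mean — and
the resulting similarity matrix is turned into a weighted k-nearest-
neighbour graph, with k the minimum value yielding a single connected
component.  The graph Laplacian of that graph is the input to the
spectral embedding producing connectopic maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components


# --------------------------------------------------------------------------
# Containers
# --------------------------------------------------------------------------

@dataclass
class ConnectivityMatrix:
    """Seed-vertex × target-voxel streamline visitation counts.

    Parameters
    ----------
    counts : (n_seed, n_target) non-negative integer array.
    seed_ids : (n_seed,) vertex indices on the seed surface.
    target_ijk : (n_target, 3) voxel grid coordinates of the targets.
    grid_shape : shape of the target voxel grid.
    per_seed_total : nominal number of streamlines seeded per vertex
        (the denominator of the 1%-visitation rule).
    """

    counts: np.ndarray
    seed_ids: np.ndarray
    target_ijk: np.ndarray
    grid_shape: tuple[int, int, int]
    per_seed_total: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if sparse.issparse(self.counts):  # pragma: no cover - defensive
            self.counts = self.counts.toarray()
        self.seed_ids = np.asarray(self.seed_ids, dtype=np.int64)
        self.target_ijk = np.asarray(self.target_ijk, dtype=np.int64)
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D seed × target matrix")
        if np.any(self.counts < 0):
            raise ValueError("visitation counts must be non-negative")
        n_seed, n_target = self.counts.shape
        if self.seed_ids.shape != (n_seed,):
            raise ValueError(
                f"seed_ids length {self.seed_ids.shape} inconsistent with "
                f"{n_seed} count rows"
            )
        if self.target_ijk.shape != (n_target, 3):
            raise ValueError(
                f"target_ijk shape {self.target_ijk.shape} inconsistent with "
                f"{n_target} count columns"
            )
        if int(self.per_seed_total) <= 0:
            raise ValueError("per_seed_total must be positive")
        self.per_seed_total = int(self.per_seed_total)
        zero_rows = np.flatnonzero(self.counts.sum(axis=1) == 0)
        if zero_rows.size:
            raise ValueError(
                "all-zero connectivity profile for seed vertices "
                f"{self.seed_ids[zero_rows[:10]].tolist()}; such rows must be "
                "removed before analysis"
            )

    @property
    def n_seed(self) -> int:
        return self.counts.shape[0]

    @property
    def n_target(self) -> int:
        return self.counts.shape[1]


@dataclass
class SimilarityMatrix:
    """Symmetric η² profile-similarity matrix with unit diagonal."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError("similarity values must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class NeighbourGraph:
    """Weighted, symmetric kNN graph over seed vertices.

    ``k_used`` is the smallest neighbour count whose union-symmetrized
    graph is a single connected component.
    """

    weights: sparse.csr_matrix
    k_used: int
    degree: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        w = sparse.csr_matrix(self.weights)
        if (abs(w - w.T) > 1e-12).nnz:
            raise ValueError("graph weights must be symmetric")
        if w.diagonal().any():
            raise ValueError("graph must have a zero diagonal")
        self.weights = w
        self.degree = np.asarray(w.sum(axis=1)).ravel()

    @property
    def n(self) -> int:
        return self.weights.shape[0]


# --------------------------------------------------------------------------
# η² similarity
# --------------------------------------------------------------------------

def eta2_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """η² similarity between two connectivity profiles.

    With per-element means ``m_i = (a_i + b_i)/2`` and grand mean ``M``
    of the ``m_i``::

        eta2 = 1 - [sum (a_i - m_i)^2 + (b_i - m_i)^2]
                 / [sum (a_i - M)^2   + (b_i - M)^2]

    i.e. one minus the within-pair over total variance ratio.  Equal to
    1 for identical (non-constant) profiles and 0 when the profiles'
    deviations cancel exactly.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"profile length mismatch: {a.size} vs {b.size}")
    m = 0.5 * (a + b)
    grand = m.mean()
    num = np.sum((a - m) ** 2 + (b - m) ** 2)
    den = np.sum((a - grand) ** 2 + (b - grand) ** 2)
    if den == 0.0:
        # Both profiles constant and equal: zero within- and total variance.
        warnings.warn(
            "eta2_similarity: both profiles constant and equal; returning 1.0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 1.0
    return float(1.0 - num / den)


def similarity_matrix(cm: ConnectivityMatrix) -> SimilarityMatrix:
    """All-pairs η² similarity between the rows of a connectivity matrix.

    Vectorised via the identity that both η² sums reduce to row norms,
    row means and the Gram matrix of the count rows.
    """
    x = cm.counts.astype(float)
    n, p = x.shape
    if n == 1:
        return SimilarityMatrix(np.ones((1, 1)))
    s2 = np.einsum("ij,ij->i", x, x)            # sum of squares per row
    mu = x.mean(axis=1)                          # row means
    gram = x @ x.T
    # numerator: sum (a-m)^2 + (b-m)^2 = ||a-b||^2 / 2
    num = 0.5 * (s2[:, None] + s2[None, :] - 2.0 * gram)
    # denominator: S2_i + S2_j - p * ((mu_i+mu_j)/2)^2 * 2
    den = s2[:, None] + s2[None, :] - 0.5 * p * (mu[:, None] + mu[None, :]) ** 2
    sim = np.ones((n, n))
    bad = den <= 0
    np.fill_diagonal(bad, True)
    off_bad = bad.copy()
    np.fill_diagonal(off_bad, False)
    if off_bad.any():
        i, j = np.nonzero(np.triu(off_bad, 1))
        warnings.warn(
            "similarity_matrix: constant-equal profile pairs "
            f"{list(zip(cm.seed_ids[i].tolist(), cm.seed_ids[j].tolist()))[:5]}; "
            "η² set to 1.0 by convention",
            RuntimeWarning,
            stacklevel=2,
        )
    ok = ~bad
    sim[ok] = 1.0 - num[ok] / den[ok]
    sim = np.clip(0.5 * (sim + sim.T), 0.0, 1.0)  # enforce exact symmetry
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(sim)


# --------------------------------------------------------------------------
# Minimal-k neighbour graph and its Laplacian
# --------------------------------------------------------------------------

def _neighbour_ranking(sim: np.ndarray) -> np.ndarray:
    """Per-node neighbour order: descending similarity, ties by ascending index.

    Returns an (n, n-1) array of neighbour indices (self excluded).
    """
    n = sim.shape[0]
    order = np.empty((n, n - 1), dtype=np.int64)
    idx = np.arange(n)
    for i in range(n):
        others = idx[idx != i]
        # lexsort: last key is primary → sort by -similarity, ties by index
        rank = np.lexsort((others, -sim[i, others]))
        order[i] = others[rank]
    return order


def _knn_adjacency(sim: np.ndarray, order: np.ndarray, k: int) -> sparse.csr_matrix:
    """Union-symmetrized kNN adjacency, zero-similarity edges dropped."""
    n = sim.shape[0]
    rows = np.repeat(np.arange(n), k)
    cols = order[:, :k].ravel()
    w = sim[rows, cols]
    keep = w > 0
    rows, cols, w = rows[keep], cols[keep], w[keep]
    adj = sparse.coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()
    return adj.maximum(adj.T)

def minimal_k_graph(sim: SimilarityMatrix) -> NeighbourGraph:
    """Weighted kNN graph at the minimum k giving one connected component.

    Each node is linked to its ``k`` most similar other nodes (union
    symmetrization, edge weight = similarity).  Edges of zero similarity
    are dropped; if even the complete graph minus zero-weight edges is
    disconnected, no k can connect it and an error is raised.
    """
    s = sim.values
    n = sim.n
    if n < 2:
        raise ValueError("need at least 2 nodes to build a neighbour graph")
    order = _neighbour_ranking(s)
    for k in range(1, n):
        adj = _knn_adjacency(s, order, k)
        n_comp, _ = connected_components(adj, directed=False)
        if n_comp == 1:
            return NeighbourGraph(weights=adj, k_used=k)
    raise ValueError(
        "graph cannot be connected at any k: zero-similarity edges "
        "leave some nodes unreachable"
    )


def graph_laplacian(g: NeighbourGraph) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalised graph Laplacian ``L = D - W`` and degree matrix ``D``.

    Returns dense arrays (the seed ROIs here are small enough that the
    generalized eigenproblem is solved densely downstream).  ``L`` is
    symmetric positive semi-definite with ``L @ 1 = 0``.
    """
    w = g.weights.toarray()
    deg = w.sum(axis=1)
    if np.any(deg == 0):
        raise ValueError(
            f"isolated nodes (zero degree) at indices "
            f"{np.flatnonzero(deg == 0)[:10].tolist()}"
        )
    d = np.diag(deg)
    lap = d - w
    return lap, d
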