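"""Laplacian-eigenmap connectopic mapping.

Connectopic maps express smooth, overlapping modes of change in a
region's connectivity.  They are obtained by a generalised eigen-
decomposition of the similarity-graph Laplacian, ``L v = λ D v``,
discarding the trivial constant eigenvector (zero eigenvalue) and
retaining the next ``m`` eigenvectors by ascending eigenvalue.  The
number of modes ``m`` common to a cohort is chosen with the
Levina–Bickel maximum-likelihood intrinsic-dimensionality estimator.
Each retained eigenvector is affinely normalised to [1, 10]; individual
maps are sign-aligned to a reference subject by flipping about the
midpoint 5.5 whenever the Pearson correlation with the reference falls
below 0.75, then averaged into group maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.spatial.distance import pdist, squareform

from .similarity_graph import (
    ConnectivityMatrix,
    NeighbourGraph,
    SimilarityMatrix,
    graph_laplacian,
    minimal_k_graph,
    similarity_matrix,
)

#: Pearson-correlation threshold below which a map is flipped about 5.5
#: during alignment to the reference subject.
ALIGNMENT_THRESHOLD = 0.75

#: Midpoint of the [1, 10] normalisation range used by the flip rule.
FLIP_MIDPOINT = 5.5


@dataclass
class ConnectopicMap:
    """Per-vertex gradient values in [1, 10] for ``m`` modes.

    ``values[:, j]`` is mode ``j`` (g1 = column 0); ``eigenvalues`` are
    the corresponding non-trivial generalized eigenvalues, ascending.
    """

    values: np.ndarray
    eigenvalues: np.ndarray
    subject_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] == 1 and self.values.shape[1] > 1:
            self.values = self.values.T
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float).ravel()
        if self.values.shape[1] != self.eigenvalues.size:
            raise ValueError("one eigenvalue required per retained mode")
        if np.any(self.eigenvalues <= 0):
            raise ValueError("retained eigenvalues must be strictly positive")
        if np.any(np.diff(self.eigenvalues) < 0):
            raise ValueError("eigenvalues must be non-decreasing")
        vmin = self.values.min(axis=0)
        vmax = self.values.max(axis=0)
        if not (np.allclose(vmin, 1.0, atol=1e-9) and np.allclose(vmax, 10.0, atol=1e-9)):
            raise ValueError("each mode must be normalised to min 1, max 10")

    @property
    def n_vertices(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def mode(self, index: int) -> np.ndarray:
        """Values of one gradient (0-based mode index)."""
        return self.values[:, index]


@dataclass
class DimensionalityEstimate:
    """Per-subject intrinsic-dimensionality estimates and the common m."""

    per_subject: np.ndarray
    common_m: int

    def __post_init__(self) -> None:
        self.per_subject = np.asarray(self.per_subject, dtype=float).ravel()
        if self.common_m < 1:
            raise ValueError("common_m must be at least 1")
        if self.common_m > int(np.floor(self.per_subject.min())) and self.common_m != 1:
            raise ValueError("common_m exceeds the floor of the minimum estimate")


# --------------------------------------------------------------------------
# Intrinsic dimensionality (Levina–Bickel MLE)
# --------------------------------------------------------------------------

def estimate_intrinsic_dimension(
    points: SimilarityMatrix | np.ndarray,
    k_min: int = 8,
    k_max: int = 20,
) -> float:
    """Levina–Bickel maximum-likelihood intrinsic dimensionality.

    The data manifold's dimension is estimated from nearest-neighbour
    distance ratios: for a point ``x`` with sorted neighbour distances
    ``T_1 <= ... <= T_k``,

        m_hat_k(x) = [ (1/(k-1)) * sum_{j<k} ln(T_k(x)/T_j(x)) ]^-1

    and the final estimate averages ``m_hat_k(x)`` over points and then
    over ``k`` in ``[k_min, k_max]``.  When called on a
    :class:`SimilarityMatrix`, its rows are the points, under Euclidean
    distance.  Scale-invariant by construction (only ratios enter).

    Duplicate points contribute ``T_j = 0`` terms, which are skipped
    with a warning; inputs where all points coincide are rejected.
    """
    if isinstance(points, SimilarityMatrix):
        x = points.values
    else:
        x = np.asarray(points, dtype=float)
    n = x.shape[0]
    if not (2 <= k_min <= k_max <= n - 1):
        raise ValueError(
            f"need n > k_max >= k_min >= 2; got n={n}, k_min={k_min}, k_max={k_max}"
        )
    dist = squareform(pdist(x))
    # sorted neighbour distances per point, self (0) excluded
    t = np.sort(dist, axis=1)[:, 1:]
    if np.all(t[:, k_max - 1] == 0):
        raise ValueError("all points coincide; intrinsic dimension undefined")
    skipped = False
    per_k = []
    for k in range(k_min, k_max + 1):
        tk = t[:, k - 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            logratio = np.log(tk[:, None]) - np.log(t[:, : k - 1])
        valid = np.isfinite(logratio)
        if not valid.all():
            skipped = True
        point_ok = (tk > 0) & (valid.sum(axis=1) > 0)
        mean_log = np.where(
            point_ok,
            np.nansum(np.where(valid, logratio, np.nan), axis=1)
            / np.maximum(valid.sum(axis=1), 1),
            np.nan,
        )
        est = 1.0 / mean_log[point_ok & (mean_log > 0)]
        if est.size:
            per_k.append(est.mean())
    if skipped:
        warnings.warn(
            "estimate_intrinsic_dimension: duplicate points produced zero "
            "neighbour distances; those log terms were skipped",
            RuntimeWarning,
            stacklevel=2,
        )
    if not per_k:
        raise ValueError("no valid neighbour-distance ratios; degenerate input")
    return float(np.mean(per_k))


def common_dimension(estimates: list[float] | np.ndarray) -> int:
    """Largest integer dimension supported by every subject's estimate.

    The floor of the minimum per-subject estimate, clipped below at 1.
    """
    est = np.asarray(estimates, dtype=float).ravel()
    if est.size == 0:
        raise ValueError("empty estimate list")
    if np.any(est <= 0):
        raise ValueError("estimates must be positive")
    return max(1, int(np.floor(est.min())))


# --------------------------------------------------------------------------
# Generalised eigendecomposition
# --------------------------------------------------------------------------

def laplacian_eigenmaps(
    lap: np.ndarray, deg: np.ndarray, m: int
) -> tuple[np.ndarray, np.ndarray]:
    """Solve ``L v = λ D v`` and return the ``m`` non-trivial eigenpairs.

    Eigenpairs are sorted by ascending eigenvalue; the first (constant
    eigenvector, zero eigenvalue) is discarded.  Returned eigenvectors
    are D-orthonormal and sign-canonicalised so that the entry of
    largest magnitude is positive, making the output deterministic.
    """
    lap = np.asarray(lap, dtype=float)
    deg = np.asarray(deg, dtype=float)
    n = lap.shape[0]
    if not 1 <= m <= n - 1:
        raise ValueError(f"m must be in [1, n-1]; got m={m}, n={n}")
    try:
        vals, vecs = linalg.eigh(lap, deg)
    except linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise RuntimeError(
            f"generalised eigendecomposition failed on a graph with n={n}, "
            f"degree range [{deg.diagonal().min():.3g}, {deg.diagonal().max():.3g}]: {exc}"
        ) from exc
    order = np.argsort(vals, kind="stable")
    vals, vecs = vals[order], vecs[:, order]
    first = vecs[:, 0]
    if np.ptp(first) > 1e-6 * max(1.0, np.abs(first).max()):
        raise RuntimeError(
            "first eigenvector is not constant: the graph appears "
            "disconnected or the Laplacian is malformed"
        )
    sel_vals = vals[1 : m + 1].copy()
    sel_vecs = vecs[:, 1 : m + 1].copy()
    for j in range(sel_vecs.shape[1]):
        pivot = np.argmax(np.abs(sel_vecs[:, j]))
        if sel_vecs[pivot, j] < 0:
            sel_vecs[:, j] *= -1.0
    return sel_vecs, sel_vals


def normalize_map(v: np.ndarray) -> np.ndarray:
    """Affine rescaling of a gradient to the range [1, 10]."""
    v = np.asarray(v, dtype=float).ravel()
    rng = np.ptp(v)
    if rng == 0:
        raise ValueError("cannot normalise a constant map")
    return 1.0 + 9.0 * (v - v.min()) / rng


def align_to_reference(ref: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Sign-align a normalised gradient to a reference gradient.

    Eigenvectors are defined only up to sign, so an individual's map may
    be the mirror image of the reference's.  If the Pearson correlation
    between the two [1, 10]-normalised maps is below
    :data:`ALIGNMENT_THRESHOLD`, the target is flipped about
    :data:`FLIP_MIDPOINT` (i.e. ``11 - target``); otherwise it is
    returned unchanged.
    """
    ref = np.asarray(ref, dtype=float).ravel()
    target = np.asarray(target, dtype=float).ravel()
    if ref.shape != target.shape:
        raise ValueError("reference and target must have equal length")
    if np.ptp(ref) == 0 or np.ptp(target) == 0:
        raise ValueError("alignment requires non-constant maps")
    r = float(np.corrcoef(ref, target)[0, 1])
    if r < ALIGNMENT_THRESHOLD:
        return 2.0 * FLIP_MIDPOINT - target
    return target


def align_map(ref: ConnectopicMap, target: ConnectopicMap) -> ConnectopicMap:
    """Mode-wise alignment of a whole map to a reference map."""
    if ref.values.shape != target.values.shape:
        raise ValueError("maps must share vertex count and mode count")
    aligned = np.column_stack(
        [
            align_to_reference(ref.mode(j), target.mode(j))
            for j in range(target.m)
        ]
    )
    return ConnectopicMap(
        values=aligned,
        eigenvalues=target.eigenvalues,
        subject_id=target.subject_id,
        session_id=target.session_id,
    )


def group_average(maps: list[ConnectopicMap]) -> ConnectopicMap:
    """Vertex-wise mean of aligned maps, re-normalised to [1, 10]."""
    if not maps:
        raise ValueError("no maps to average")
    shape = maps[0].values.shape
    if any(m.values.shape != shape for m in maps):
        raise ValueError("all maps must share vertex count and mode count")
    mean = np.mean([m.values for m in maps], axis=0)
    normed = np.column_stack([normalize_map(mean[:, j]) for j in range(shape[1])])
    eig = np.mean([m.eigenvalues for m in maps], axis=0)
    return ConnectopicMap(values=normed, eigenvalues=eig, subject_id="group")


# --------------------------------------------------------------------------
# Single-subject pipeline step
# --------------------------------------------------------------------------

def fit_connectopic_map(
    cm: ConnectivityMatrix,
    m: int,
    subject_id: str = "",
    session_id: str = "",
    profile_transform: str = "raw",
) -> tuple[ConnectopicMap, SimilarityMatrix, NeighbourGraph]:
    """Connectivity matrix → similarity → minimal-k graph → connectopic map.

    ``profile_transform`` optionally applies ``log1p`` or per-row
    normalisation (``row-norm``) to the count profiles before the η²
    similarity; the default uses raw counts.
    """
    if profile_transform == "raw":
        sim = similarity_matrix(cm)
    elif profile_transform == "log1p":
        sim = similarity_matrix(_transformed(cm, np.log1p(cm.counts.astype(float))))
    elif profile_transform == "row-norm":
        counts = cm.counts.astype(float)
        sim = similarity_matrix(_transformed(cm, counts / counts.sum(axis=1, keepdims=True)))
    else:
        raise ValueError(f"unknown profile_transform {profile_transform!r}")
    graph = minimal_k_graph(sim)
    lap, deg = graph_laplacian(graph)
    vecs, vals = laplacian_eigenmaps(lap, deg, m)
    values = np.column_stack([normalize_map(vecs[:, j]) for j in range(m)])
    cmap = ConnectopicMap(
        values=values, eigenvalues=vals, subject_id=subject_id, session_id=session_id
    )
    return cmap, sim, graph


def _transformed(cm: ConnectivityMatrix, counts: np.ndarray) -> ConnectivityMatrix:
    out = ConnectivityMatrix.__new__(ConnectivityMatrix)
    out.counts = counts
    out.seed_ids = cm.seed_ids
    out.target_ijk = cm.target_ijk
    out.grid_shape = cm.grid_shape
    out.per_seed_total = cm.per_seed_total
    return out
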