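"""Synthetic tractography cohorts with planted connectivity gradients.

The generator emulates the statistical structure the connectopic-mapping
pipeline assumes, with known ground truth at every stage:

* a regular triangulated sheet stands in for the seed surface;
* up to three smooth, mutually orthogonal latent fields on the sheet
  are the planted "modes of connectivity" the pipeline should recover;
* target voxels are clustered into named "tracts", each occupying a
  distinct region of latent space;
* a seed vertex's expected connectivity profile follows a Gaussian
  tuning kernel of the distance between its latent coordinate and each
  target voxel's tract centre, scaled to an expected per-vertex
  streamline count and realised as Poisson counts;
* subject- and session-level variability enter as additive Gaussian
  perturbations of the latent fields, the subject term shared across
  that subject's sessions — so session noise < subject noise yields
  between-session reliability above between-subject reliability.

Everything is reproducible from a single seed via named substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import connected_components

from ._rng import (
    STREAM_COUNTS,
    STREAM_SESSION,
    STREAM_SUBJECT,
    STREAM_TARGETS,
    STREAM_TERMS,
    substream,
)
from .functional_decoding import TermMapLibrary, rank_deciles
from .projection_tracts import TractAtlas
from .similarity_graph import ConnectivityMatrix

#: Planted tract centres in latent space [0, 1]^3, truncated to the
#: number of planted gradients.  Axis 0 mimics the inferior–superior
#: ordering of temporal tracts (ILF/IFOF/UF low, AF intermediate,
#: MdLF/AR high); axis 1 separates AF from the rest; axis 2 mimics an
#: anterior–posterior ordering with UF most anterior.  The spread of
#: the centres shrinks from axis to axis (0.88, 0.30, 0.24) so the
#: planted modes explain strictly decreasing connectivity variance —
#: mirroring the dominant-to-minor ordering of empirical gradients —
#: which keeps the eigenvalue order of the recovered modes stable.
TRACT_LATENT_CENTRES: dict[str, tuple[float, float, float]] = {
    "ILF": (0.06, 0.50, 0.45),
    "IFOF": (0.236, 0.446, 0.45),
    "UF": (0.412, 0.446, 0.38),
    "AF": (0.588, 0.65, 0.58),
    "MdLF": (0.764, 0.50, 0.60),
    "AR": (0.94, 0.35, 0.62),
}


# --------------------------------------------------------------------------
# Seed mesh
# --------------------------------------------------------------------------

@dataclass
class SeedMesh:
    """Triangulated seed surface (a regular rectangular sheet).

    ``sheet_shape`` records the (n_u, n_v) grid the sheet was built
    from, used to embed vertices into a voxel grid.
    """

    vertex_coords: np.ndarray
    triangles: np.ndarray
    sheet_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.vertex_coords = np.asarray(self.vertex_coords, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        n = self.n_vertices
        if self.triangles.size and self.triangles.max() >= n:
            raise ValueError("triangle index exceeds vertex count")
        if self.triangles.min(initial=0) < 0:
            raise ValueError("negative triangle index")
        # single connected component over triangle edges
        tri = self.triangles
        edges = np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [0, 2]]])
        adj = sparse.coo_matrix(
            (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(n, n)
        )
        n_comp, _ = connected_components(adj, directed=False)
        if n_comp != 1:
            raise ValueError(f"mesh must be a single connected component; got {n_comp}")

    @property
    def n_vertices(self) -> int:
        return self.vertex_coords.shape[0]


def make_seed_mesh(n_u: int, n_v: int, spacing: float = 1.0) -> SeedMesh:
    """Regular triangulated n_u × n_v sheet with 2(n_u-1)(n_v-1) triangles."""
    if n_u < 2 or n_v < 2 or n_u * n_v < 4:
        raise ValueError(f"sheet needs n_u, n_v >= 2 (got {n_u} x {n_v})")
    uu, vv = np.meshgrid(np.arange(n_u), np.arange(n_v), indexing="ij")
    coords = np.column_stack(
        [uu.ravel() * spacing, vv.ravel() * spacing, np.zeros(n_u * n_v)]
    )
    tris = []
    for i in range(n_u - 1):
        for j in range(n_v - 1):
            a = i * n_v + j
            b = a + 1
            c = a + n_v
            d = c + 1
            tris.append((a, b, c))
            tris.append((b, d, c))
    return SeedMesh(
        vertex_coords=coords,
        triangles=np.asarray(tris, dtype=np.int64),
        sheet_shape=(n_u, n_v),
    )


# --------------------------------------------------------------------------
# Ground truth
# --------------------------------------------------------------------------

@dataclass
class LatentTruth:
    """Planted gradients and tract geometry in latent space."""

    m_true: int
    latent_fields: np.ndarray          # (n_vertices, m_true), each column in [0, 1]
    tract_centres: dict[str, np.ndarray]
    mesh: SeedMesh
    rng_seed: int = 0
    tract_of_voxel: np.ndarray | None = None  # filled once a target space exists

    def __post_init__(self) -> None:
        f = np.asarray(self.latent_fields, dtype=float)
        if f.ndim == 1:
            f = f[:, None]
        self.latent_fields = f
        if f.shape[1] != self.m_true:
            raise ValueError("one latent field per planted gradient required")
        centred = f - f.mean(axis=0)
        for a in range(self.m_true):
            for b in range(a + 1, self.m_true):
                denom = np.linalg.norm(centred[:, a]) * np.linalg.norm(centred[:, b])
                cos = abs(centred[:, a] @ centred[:, b]) / denom
                if cos >= 0.05:
                    raise ValueError(
                        f"latent fields {a} and {b} are not quasi-orthogonal "
                        f"(|cos| = {cos:.3f})"
                    )


def plant_gradients(mesh: SeedMesh, m_true: int, rng_seed: int = 0) -> LatentTruth:
    """Plant up to three smooth, mutually orthogonal latent fields.

    Field 1 is the normalised sheet u-coordinate, field 2 the normalised
    v-coordinate, and field 3 the normalised radial distance from the
    sheet centre — chosen because on a regular sheet its centred cosine
    with both axis fields vanishes by symmetry.  Each field spans [0, 1].
    """
    if not 1 <= m_true <= 3:
        raise ValueError(
            f"m_true must be in [1, 3] (orthogonality is only guaranteed for "
            f"up to three fields on a sheet); got {m_true}"
        )
    xy = mesh.vertex_coords[:, :2]
    fields = []
    u = xy[:, 0]
    fields.append((u - u.min()) / max(np.ptp(u), 1e-300))
    if m_true >= 2:
        v = xy[:, 1]
        fields.append((v - v.min()) / max(np.ptp(v), 1e-300))
    if m_true == 3:
        centre = 0.5 * (xy.min(axis=0) + xy.max(axis=0))
        r = np.linalg.norm(xy - centre, axis=1)
        fields.append((r - r.min()) / max(np.ptp(r), 1e-300))
    centres = {
        name: np.asarray(c[:m_true], dtype=float)
        for name, c in TRACT_LATENT_CENTRES.items()
    }
    return LatentTruth(
        m_true=m_true,
        latent_fields=np.column_stack(fields),
        tract_centres=centres,
        mesh=mesh,
        rng_seed=rng_seed,
    )


@dataclass
class CohortSpec:
    """Study-level simulation parameters.

    Defaults mirror a two-session test–retest cohort of 42 subjects
    with 10,000 streamlines seeded per vertex; session-level latent
    perturbations are smaller than subject-level ones, so maps are more
    reproducible within than between subjects.  ``tau`` is the Gaussian
    tuning width in latent units: small tau gives sharply tract-specific
    profiles, large tau washes the gradients out.
    """

    n_subjects: int = 42
    n_sessions: int = 2
    depth: float = 10_000.0
    sigma_subject: float = 0.03
    sigma_session: float = 0.008
    tau: float = 0.30
    perturbation_smoothness: float = 2.5
    local_mass: float = 0.03
    local_decay: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_sessions < 1:
            raise ValueError("need at least one subject and one session")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.tau <= 0:
            raise ValueError("degenerate tuning width: tau must be positive")
        if self.sigma_subject < 0 or self.sigma_session < 0:
            raise ValueError("perturbation scales must be non-negative")
        if not 0 <= self.local_mass < 1:
            raise ValueError("local_mass must lie in [0, 1)")
        if self.local_decay <= 0:
            raise ValueError("local_decay must be positive")

    @property
    def subjects(self) -> list[str]:
        return [f"sub-{i:03d}" for i in range(1, self.n_subjects + 1)]

    @property
    def sessions(self) -> list[str]:
        return [f"ses-{i}" for i in range(1, self.n_sessions + 1)]


@dataclass
class TargetSpace:
    """Fixed target-voxel geometry shared by a whole cohort.

    Every target voxel belongs to one tract; its effective latent
    position is the tract centre plus a per-voxel jitter drawn once per
    cohort, so all subjects and sessions see identical targets.
    """

    tract_names: list[str]
    tract_of_voxel: np.ndarray     # (n_target,) tract name per voxel
    centre_of_voxel: np.ndarray    # (n_target, m) latent position incl. jitter
    target_ijk: np.ndarray         # (n_target, 3) grid coordinates
    grid_shape: tuple[int, int, int]

    @property
    def n_target(self) -> int:
        return self.target_ijk.shape[0]

    def tract_atlas(self) -> TractAtlas:
        """Binary voxel mask per tract on the cohort grid."""
        masks = {}
        for name in self.tract_names:
            mask = np.zeros(self.grid_shape, dtype=bool)
            ijk = self.target_ijk[self.tract_of_voxel == name]
            mask[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = True
            masks[name] = mask
        return TractAtlas(masks=masks)


def make_target_space(
    truth: LatentTruth,
    n_targets_per_tract: int,
    spec: CohortSpec,
) -> TargetSpace:
    """Lay out jittered tract target voxels on a shared grid.

    The grid hosts the seed sheet at z = 0 (one voxel per vertex) and
    each tract's voxels on its own z-slab, filled row-major.  Voxel
    jitter is N(0, (tau/2)^2) per latent axis, drawn from the cohort's
    target substream so the geometry is fixed across subjects/sessions.
    """
    if n_targets_per_tract < 1:
        raise ValueError("need at least one target voxel per tract")
    if truth.mesh.sheet_shape is None:
        raise ValueError("target layout requires a sheet mesh")
    n_u, n_v = truth.mesh.sheet_shape
    names = list(truth.tract_centres)
    m = truth.m_true
    rng = substream(spec.rng_seed, STREAM_TARGETS)
    gx = max(n_u, int(np.ceil(np.sqrt(n_targets_per_tract))))
    gy = max(n_v, int(np.ceil(n_targets_per_tract / gx)))
    grid_shape = (gx, gy, 1 + len(names))
    tract_of_voxel, centres, ijk = [], [], []
    for t, name in enumerate(names):
        c = truth.tract_centres[name]
        delta = rng.normal(0.0, spec.tau / 2.0, size=(n_targets_per_tract, m))
        centres.append(c[None, :] + delta)
        tract_of_voxel.extend([name] * n_targets_per_tract)
        flat = np.arange(n_targets_per_tract)
        ijk.append(np.column_stack([flat // gy, flat % gy, np.full_like(flat, t + 1)]))
    ts = TargetSpace(
        tract_names=names,
        tract_of_voxel=np.asarray(tract_of_voxel),
        centre_of_voxel=np.vstack(centres),
        target_ijk=np.vstack(ijk),
        grid_shape=grid_shape,
    )
    truth.tract_of_voxel = ts.tract_of_voxel
    return ts


def vertex_to_voxel(mesh: SeedMesh) -> np.ndarray:
    """Map each sheet vertex to its voxel (u, v, 0) in the cohort grid."""
    if mesh.sheet_shape is None:
        raise ValueError("vertex embedding requires a sheet mesh")
    n_u, n_v = mesh.sheet_shape
    uu, vv = np.meshgrid(np.arange(n_u), np.arange(n_v), indexing="ij")
    return np.column_stack([uu.ravel(), vv.ravel(), np.zeros(n_u * n_v, dtype=int)])


# --------------------------------------------------------------------------
# Connectivity simulation
# --------------------------------------------------------------------------

def expected_profiles(
    latent: np.ndarray,
    target_space: TargetSpace,
    depth: float,
    tau: float,
    local_mass: float = 0.03,
    local_decay: float = 1.0,
) -> np.ndarray:
    """Expected visitation counts given vertex latent coordinates.

    Two components, mixed with weight ``local_mass`` and row-normalised
    so every vertex emits ``depth`` expected streamline visits:

    * a diffuse Gaussian tuning kernel
      ``K_ij = exp(-||g_i - c_j||^2 / (2 tau^2))`` over the jittered
      tract centres ``c_j`` — the smooth gradient signal;
    * a proximal component concentrated on each vertex's few nearest
      target voxels, decaying as ``exp(-rank / local_decay)`` with the
      distance rank — emulating the stem of a vertex's own streamline
      paths, which nearly all of its streamlines traverse.  This is
      what lets a vertex's top voxels clear a visitation threshold
      expressed as a fraction of the streamlines seeded, independent of
      how crowded latent space is.
    """
    if tau <= 0:
        raise ValueError("degenerate tuning width: tau must be positive")
    g = np.atleast_2d(np.asarray(latent, dtype=float))
    diff = g[:, None, :] - target_space.centre_of_voxel[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    k = np.exp(-d2 / (2.0 * tau**2))
    k /= k.sum(axis=1, keepdims=True)
    if local_mass > 0:
        ranks = np.argsort(np.argsort(d2, axis=1, kind="stable"), axis=1, kind="stable")
        local = np.exp(-ranks / local_decay)
        local /= local.sum(axis=1, keepdims=True)
        k = (1.0 - local_mass) * k + local_mass * local
    return depth * k


def _smooth_field(
    rng: np.random.Generator,
    shape: tuple[int, int],
    n_fields: int,
    sigma: float,
    smoothness: float,
) -> np.ndarray:
    """Spatially smooth Gaussian random fields on the sheet, SD ``sigma``.

    White noise on the vertex grid is Gaussian-filtered with width
    ``smoothness`` (in vertices) and rescaled to the requested standard
    deviation — individual anatomy varies smoothly across the cortex,
    so perturbations must not destroy the local profile similarity the
    embedding relies on.
    """
    white = rng.normal(0.0, 1.0, size=(n_fields,) + shape)
    if smoothness > 0:
        smooth = np.stack([ndimage.gaussian_filter(w, smoothness) for w in white])
    else:
        smooth = white
    sd = smooth.std(axis=(1, 2), keepdims=True)
    sd[sd == 0] = 1.0
    return (sigma * smooth / sd).reshape(n_fields, -1).T


def perturbed_latent(
    truth: LatentTruth, spec: CohortSpec, subject: int, session: int
) -> np.ndarray:
    """Latent fields plus subject- and session-level smooth perturbations.

    The subject perturbation depends only on (seed, subject) and is
    therefore shared by that subject's sessions; the session term is
    drawn per (subject, session).  Both are smooth random fields on the
    sheet (see :func:`_smooth_field`).
    """
    if truth.mesh.sheet_shape is None:
        raise ValueError("latent perturbations require a sheet mesh")
    shape = truth.mesh.sheet_shape
    g = truth.latent_fields.copy()
    m = g.shape[1]
    if spec.sigma_subject > 0:
        rng_sub = substream(spec.rng_seed, STREAM_SUBJECT, subject)
        g = g + _smooth_field(
            rng_sub, shape, m, spec.sigma_subject, spec.perturbation_smoothness
        )
    if spec.sigma_session > 0:
        rng_ses = substream(spec.rng_seed, STREAM_SESSION, subject, session)
        g = g + _smooth_field(
            rng_ses, shape, m, spec.sigma_session, spec.perturbation_smoothness
        )
    return g


def simulate_connectivity(
    truth: LatentTruth,
    n_targets_per_tract: int,
    spec: CohortSpec,
    subject: int,
    session: int,
    target_space: TargetSpace | None = None,
) -> ConnectivityMatrix:
    """One session's seed × target visitation-count matrix.

    Counts are Poisson with the kernel profile as mean; bit-identical
    for identical ``(rng_seed, subject, session)``.
    """
    if target_space is None:
        target_space = make_target_space(truth, n_targets_per_tract, spec)
    g = perturbed_latent(truth, spec, subject, session)
    lam = expected_profiles(
        g, target_space, spec.depth, spec.tau,
        local_mass=spec.local_mass, local_decay=spec.local_decay,
    )
    rng = substream(spec.rng_seed, STREAM_COUNTS, subject, session)
    counts = rng.poisson(lam).astype(np.int64)
    return ConnectivityMatrix(
        counts=counts,
        seed_ids=np.arange(truth.mesh.n_vertices),
        target_ijk=target_space.target_ijk,
        grid_shape=target_space.grid_shape,
        per_seed_total=int(round(spec.depth)),
    )


def simulate_cohort(
    truth: LatentTruth,
    spec: CohortSpec,
    n_targets_per_tract: int = 120,
) -> tuple[dict[tuple[str, str], ConnectivityMatrix], TargetSpace]:
    """Connectivity matrices for every (subject, session) of the cohort."""
    target_space = make_target_space(truth, n_targets_per_tract, spec)
    matrices = {}
    for si, subj in enumerate(spec.subjects, start=1):
        for wi, ses in enumerate(spec.sessions, start=1):
            matrices[(subj, ses)] = simulate_connectivity(
                truth, n_targets_per_tract, spec, si, wi, target_space=target_space
            )
    return matrices, target_space


# --------------------------------------------------------------------------
# Term-map library
# --------------------------------------------------------------------------

def simulate_term_library(
    volume_grid: tuple[int, int, int],
    truth: LatentTruth,
    vertex_to_voxel_map: np.ndarray,
    n_noise_terms: int,
    rng_seed: int = 0,
    noise_sigma: float = 0.2,
    smooth_sigma: float = 0.0,
) -> TermMapLibrary:
    """A local stand-in for a meta-analytic term-map library.

    For each planted gradient g and decile d a "signal" term map is the
    (optionally Gaussian-smoothed) voxel indicator of that decile's
    vertices plus N(0, noise_sigma) noise — so with zero noise and no
    smoothing the planted term correlates perfectly with its decile
    mask.  ``n_noise_terms`` pure-noise maps and one anatomical map
    (the full seed-sheet footprint) complete the library, giving
    ``10 * m_true + n_noise_terms + 1`` terms.
    """
    v2v = np.asarray(vertex_to_voxel_map, dtype=np.int64)
    grid = tuple(int(s) for s in volume_grid)
    if np.any(v2v < 0) or np.any(v2v >= np.asarray(grid)):
        raise ValueError("volume grid too small to host all mapped vertices")
    rng = substream(rng_seed, STREAM_TERMS)
    terms: list[str] = []
    maps: dict[str, np.ndarray] = {}
    is_anatomical: dict[str, bool] = {}
    for gi in range(truth.m_true):
        masks = rank_deciles(truth.latent_fields[:, gi])
        for d, mask in enumerate(masks, start=1):
            name = f"signal_g{gi + 1}_d{d}"
            vol = np.zeros(grid)
            ijk = v2v[mask]
            vol[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = 1.0
            if smooth_sigma > 0:
                vol = ndimage.gaussian_filter(vol, smooth_sigma)
            if noise_sigma > 0:
                vol = vol + rng.normal(0.0, noise_sigma, size=grid)
            terms.append(name)
            maps[name] = vol
            is_anatomical[name] = False
    for t in range(1, n_noise_terms + 1):
        name = f"noise_{t:02d}"
        terms.append(name)
        maps[name] = rng.normal(0.0, 1.0, size=grid)
        is_anatomical[name] = False
    anat = np.zeros(grid)
    anat[v2v[:, 0], v2v[:, 1], v2v[:, 2]] = 1.0
    terms.append("temporal lobe")
    maps["temporal lobe"] = anat
    is_anatomical["temporal lobe"] = True
    return TermMapLibrary(terms=terms, maps=maps, is_anatomical=is_anatomical)
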