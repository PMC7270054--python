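"""Projection images and tract projections.

A connectopic map lives on the seed surface; to relate it to the white
matter carrying the underlying connections, the map is projected into
volume space.  For each subject a projection skeleton keeps, per seed
vertex, the target voxels visited by at least a fraction ``frac``
(default 1%) of that vertex's streamlines.  Each skeleton voxel is then
assigned the count-weighted average gradient value of the (up to) three
vertices whose streamlines hit it the most.  Restricting the resulting
projection image to named binary tract masks yields tract projections,
summarised per tract by the mean voxel value with a bootstrap CI.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import STREAM_BOOTSTRAP, substream
from .connectopic_mapping import ConnectopicMap
from .similarity_graph import ConnectivityMatrix

logger = logging.getLogger(__name__)

#: Canonical temporal-lobe tract labels.
TEMPORAL_TRACTS = ("ILF", "AF", "AR", "IFOF", "MdLF", "UF")


@dataclass
class ProjectionImage:
    """A gradient projected into the target voxel grid.

    ``values`` is a dense array of shape ``grid_shape`` holding gradient
    values in [1, 10] on populated voxels and NaN elsewhere.
    """

    values: np.ndarray
    mode_index: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        populated = self.values[np.isfinite(self.values)]
        if populated.size and (populated.min() < 1 - 1e-9 or populated.max() > 10 + 1e-9):
            raise ValueError("populated projection values must lie in [1, 10]")

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def populated(self) -> np.ndarray:
        """Boolean mask of voxels carrying a projected value."""
        return np.isfinite(self.values)

    @property
    def n_populated(self) -> int:
        return int(self.populated.sum())


@dataclass
class TractAtlas:
    """Named binary voxel masks on a common grid."""

    masks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError(f"tract masks disagree on grid shape: {shapes}")
        self.masks = {k: np.asarray(v).astype(bool) for k, v in self.masks.items()}

    @property
    def names(self) -> list[str]:
        return list(self.masks)

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return next(iter(self.masks.values())).shape


def projection_skeleton(cm: ConnectivityMatrix, frac: float = 0.01) -> np.ndarray:
    """Per-vertex binary sets of sufficiently visited target voxels.

    Voxel ``j`` survives for vertex ``i`` iff
    ``counts[i, j] >= frac * per_seed_total``.  Returns a boolean
    (n_seed, n_target) matrix.  Raising ``frac`` can only shrink the
    skeleton.
    """
    if not 0 < frac <= 1:
        raise ValueError(f"frac must be in (0, 1]; got {frac}")
    threshold = frac * cm.per_seed_total
    skel = cm.counts >= threshold
    empty = np.flatnonzero(~skel.any(axis=1))
    if empty.size:
        logger.warning(
            "projection_skeleton: %d vertices have no voxel above the "
            "%.3g%% threshold (e.g. vertex ids %s)",
            empty.size, 100 * frac, cm.seed_ids[empty[:5]].tolist(),
        )
    return skel


def make_projection_image(
    skeleton: np.ndarray,
    cm: ConnectivityMatrix,
    cmap: ConnectopicMap,
    mode: int,
) -> ProjectionImage:
    """Populate skeleton voxels with top-3 count-weighted gradient values.

    For each voxel in the union skeleton, the (up to) 3 vertices with
    the highest surviving counts to that voxel are selected — ties by
    ascending vertex index — and the voxel value is their gradient
    values averaged with the counts as weights.
    """
    skeleton = np.asarray(skeleton, dtype=bool)
    if skeleton.shape != cm.counts.shape:
        raise ValueError("skeleton and counts shapes differ")
    if cmap.n_vertices != cm.n_seed:
        raise ValueError("map vertex count does not match seed rows")
    g = cmap.mode(mode)
    surviving = np.where(skeleton, cm.counts, 0)
    vol = np.full(cm.grid_shape, np.nan)
    hit_cols = np.flatnonzero(skeleton.any(axis=0))
    for j in hit_cols:
        col = surviving[:, j]
        hitters = np.flatnonzero(col > 0)
        # top 3 by count, ties broken by ascending vertex index
        order = hitters[np.lexsort((hitters, -col[hitters]))][:3]
        w = col[order].astype(float)
        value = float(np.dot(w, g[order]) / w.sum())
        i0, i1, i2 = cm.target_ijk[j]
        vol[i0, i1, i2] = value
    return ProjectionImage(values=vol, mode_index=mode)


def tract_projection(
    img: ProjectionImage, atlas: TractAtlas
) -> dict[str, ProjectionImage]:
    """Restrict a projection image to each tract's binary mask."""
    if atlas.grid_shape != img.grid_shape:
        raise ValueError(
            f"atlas grid {atlas.grid_shape} does not match image grid {img.grid_shape}"
        )
    out: dict[str, ProjectionImage] = {}
    for name, mask in atlas.masks.items():
        vals = np.where(mask, img.values, np.nan)
        if not np.isfinite(vals).any():
            warnings.warn(
                f"tract_projection: tract {name!r} does not intersect the "
                "projection image; empty tract projection",
                RuntimeWarning,
                stacklevel=2,
            )
        out[name] = ProjectionImage(values=vals, mode_index=img.mode_index)
    return out


def tract_summary(
    tract_imgs: dict[str, dict[int, ProjectionImage]],
    modes: list[int],
    n_boot: int = 10_000,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Mean tract-projection value per (tract, mode) with bootstrap 95% CI.

    ``tract_imgs`` maps tract name → mode index → tract projection.
    The CI is the 2.5/97.5 percentile interval of the mean over voxels,
    from ``n_boot`` resamples; reproducible from ``rng_seed``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100 for a percentile CI")
    rng = substream(rng_seed, STREAM_BOOTSTRAP)
    rows = []
    for tract in tract_imgs:
        for mode in modes:
            img = tract_imgs[tract][mode]
            vals = img.values[img.populated]
            if vals.size == 0:
                raise ValueError(
                    f"tract {tract!r} has no populated voxels for mode {mode}"
                )
            idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
            boot_means = vals[idx].mean(axis=1)
            lo, hi = np.percentile(boot_means, [2.5, 97.5])
            rows.append(
                {
                    "tract": tract,
                    "mode": mode,
                    "mean": float(vals.mean()),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                    "n_voxels": int(vals.size),
                }
            )
    df = pd.DataFrame(rows)
    bad = df[(df["ci_low"] > df["mean"]) | (df["mean"] > df["ci_high"])]
    if len(bad):  # pragma: no cover - defensive
        raise AssertionError(f"bootstrap CI does not bracket the mean:\n{bad}")
    return df
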