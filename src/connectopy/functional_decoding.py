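"""Decile-based meta-analytic decoding of group gradients.

Each group connectopic map is split into ten equal-population decile
masks by rank.  Every decile mask is carried into volume space and
spatially correlated (Pearson) with each map of a term library — whole-
brain activation maps labelled with a cognitive term, as published by
large-scale fMRI meta-analysis services.  Per decile, the top three
positively correlated non-anatomical terms are retained, with synonym
groups (e.g. "object"/"objects") contributing at most one term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectopic_mapping import ConnectopicMap


@dataclass
class TermMapLibrary:
    """A library of term-labelled voxel maps on a shared grid.

    ``is_anatomical`` flags terms naming anatomy rather than function;
    these are never reported.  ``synonym_groups`` maps a term to its
    equivalence-class label; terms without an entry are their own class.
    """

    terms: list[str]
    maps: dict[str, np.ndarray]
    is_anatomical: dict[str, bool]
    synonym_groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [t for t in self.terms if t not in self.maps]
        if missing:
            raise ValueError(f"terms without maps: {missing[:5]}")
        shapes = {self.maps[t].shape for t in self.terms}
        if len(shapes) > 1:
            raise ValueError(f"term maps disagree on grid shape: {shapes}")
        unflagged = [t for t in self.terms if t not in self.is_anatomical]
        if unflagged:
            raise ValueError(f"terms without an anatomical flag: {unflagged[:5]}")

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.maps[self.terms[0]].shape

    def group_of(self, term: str) -> str:
        return self.synonym_groups.get(term, term)


@dataclass
class DecodingTable:
    """Decile × term spatial-correlation table with per-decile top terms.

    ``table`` holds Pearson r for retained terms (rows) × deciles 1–10
    (columns); non-positive correlations are absent (NaN).  ``top3``
    maps decile number to its ranked (term, r) list.
    """

    table: pd.DataFrame
    top3: dict[int, list[tuple[str, float]]]


# --------------------------------------------------------------------------
# Decile masks
# --------------------------------------------------------------------------

def rank_deciles(values: np.ndarray) -> list[np.ndarray]:
    """Split vertices into 10 contiguous rank bins of (near-)equal size.

    Vertices are ranked by ascending value (ties by ascending vertex
    index); with ``n = 10 q + r`` the lowest ``r`` bins receive one
    extra vertex.  The returned boolean masks partition all vertices;
    mask 0 is the lowest decile.
    """
    values = np.asarray(values, dtype=float).ravel()
    n = values.size
    if n < 10:
        raise ValueError(f"need at least 10 vertices for deciles; got {n}")
    if np.ptp(values) == 0:
        raise ValueError("cannot split a constant map into deciles")
    order = np.lexsort((np.arange(n), values))
    q, r = divmod(n, 10)
    sizes = [q + 1 if d < r else q for d in range(10)]
    masks = []
    start = 0
    for size in sizes:
        mask = np.zeros(n, dtype=bool)
        mask[order[start : start + size]] = True
        masks.append(mask)
        start += size
    return masks


def decile_partition(cmap: ConnectopicMap, mode: int) -> list[np.ndarray]:
    """Ten equal-population vertex masks of one gradient, lowest first."""
    return rank_deciles(cmap.mode(mode))


def mask_to_volume(
    mask: np.ndarray,
    vertex_to_voxel: np.ndarray,
    grid_shape: tuple[int, int, int],
) -> np.ndarray:
    """Binary voxel map marking voxels hit by at least one mask vertex."""
    mask = np.asarray(mask, dtype=bool).ravel()
    v2v = np.asarray(vertex_to_voxel, dtype=np.int64)
    if v2v.shape != (mask.size, 3):
        raise ValueError("vertex_to_voxel must map every mask vertex to an ijk triple")
    if np.any(v2v < 0) or np.any(v2v >= np.asarray(grid_shape)):
        raise ValueError("vertex mapped outside the volume grid")
    vol = np.zeros(grid_shape, dtype=bool)
    ijk = v2v[mask]
    vol[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = True
    return vol


# --------------------------------------------------------------------------
# Decoding
# --------------------------------------------------------------------------

def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    sx = np.sqrt(x @ x)
    sy = np.sqrt(y @ y)
    if sx == 0 or sy == 0:
        return np.nan
    return float((x @ y) / (sx * sy))


def _term_correlations(
    vol_mask: np.ndarray,
    lib: TermMapLibrary,
    analysis_mask: np.ndarray,
) -> dict[str, float]:
    """Pearson r of the binary decile map with every term map."""
    sel = np.asarray(analysis_mask, dtype=bool)
    if sel.shape != vol_mask.shape:
        raise ValueError("analysis mask grid does not match decile map grid")
    if not sel.any():
        raise ValueError("analysis mask is empty")
    x = np.asarray(vol_mask, dtype=float)[sel]
    out: dict[str, float] = {}
    for term in lib.terms:
        if lib.maps[term].shape != vol_mask.shape:
            raise ValueError(f"term {term!r} map grid does not match decile map")
        r = _pearson(x, lib.maps[term][sel].astype(float))
        if np.isnan(r):
            warnings.warn(
                f"decode: term {term!r} is constant over the analysis mask; skipped",
                RuntimeWarning,
                stacklevel=3,
            )
            continue
        out[term] = r
    return out


def decode_decile(
    vol_mask: np.ndarray,
    lib: TermMapLibrary,
    analysis_mask: np.ndarray | None = None,
) -> list[tuple[str, float]]:
    """Top-3 positively correlated, non-anatomical terms for one decile.

    Anatomical terms are dropped; within each synonym group only the
    maximally correlated member survives; only r > 0 is reported.
    Returned descending by r (ties by term name for determinism).
    """
    if analysis_mask is None:
        analysis_mask = np.ones_like(np.asarray(vol_mask, dtype=bool))
    corr = _term_correlations(np.asarray(vol_mask, dtype=bool), lib, analysis_mask)
    best: dict[str, tuple[str, float]] = {}
    for term, r in corr.items():
        if lib.is_anatomical[term] or r <= 0:
            continue
        grp = lib.group_of(term)
        if grp not in best or r > best[grp][1]:
            best[grp] = (term, r)
    ranked = sorted(best.values(), key=lambda tr: (-tr[1], tr[0]))
    return ranked[:3]


def decoding_table(
    group_map: ConnectopicMap,
    mode: int,
    lib: TermMapLibrary,
    vertex_to_voxel: np.ndarray,
    analysis_mask: np.ndarray | None = None,
) -> DecodingTable:
    """Assemble the decile × term correlation table for one gradient.

    Rows are the union of per-decile top-3 terms; each row shows that
    term's r at every decile where it is positive.
    """
    masks = decile_partition(group_map, mode)
    grid_shape = lib.grid_shape
    if analysis_mask is None:
        analysis_mask = np.ones(grid_shape, dtype=bool)
    vols = [mask_to_volume(m, vertex_to_voxel, grid_shape) for m in masks]
    top3: dict[int, list[tuple[str, float]]] = {}
    all_corr: dict[int, dict[str, float]] = {}
    for d, vol in enumerate(vols, start=1):
        all_corr[d] = _term_correlations(vol, lib, analysis_mask)
        top3[d] = decode_decile(vol, lib, analysis_mask)
    retained = sorted({term for ranked in top3.values() for term, _ in ranked})
    data = np.full((len(retained), 10), np.nan)
    for i, term in enumerate(retained):
        for d in range(1, 11):
            r = all_corr[d].get(term, np.nan)
            if np.isfinite(r) and r > 0:
                data[i, d - 1] = r
    table = pd.DataFrame(data, index=retained, columns=[f"decile_{d}" for d in range(1, 11)])
    return DecodingTable(table=table, top3=top3)
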