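"""File formats: MatrixMarket + JSON sidecar, GIFTI, NIfTI, TSV.

Connectivity matrices travel as MatrixMarket sparse integer files with
a JSON sidecar holding seed vertex ids, target voxel coordinates, the
grid shape and the per-vertex streamline total.  Surface data (meshes,
connectopic maps, latent fields) are GIFTI; volumes (projection images,
tract masks, term maps) are NIfTI; tables are TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import io as sio
from scipy import sparse

from .connectopic_mapping import ConnectopicMap
from .functional_decoding import TermMapLibrary
from .projection_tracts import ProjectionImage, TractAtlas
from .similarity_graph import ConnectivityMatrix
from .synthetic_cohort import SeedMesh

_AFFINE = np.eye(4)  # synthetic grids are index-space; 1 mm isotropic


# --------------------------------------------------------------------------
# Connectivity matrices: .mtx + .json sidecar
# --------------------------------------------------------------------------

def save_connectivity_matrix(cm: ConnectivityMatrix, prefix: str | Path) -> Path:
    """Write ``<prefix>.mtx`` and ``<prefix>.json``; returns the mtx path."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    mtx_path = prefix.with_suffix(".mtx")
    sio.mmwrite(str(mtx_path), sparse.coo_matrix(cm.counts), field="integer")
    sidecar = {
        "seed_ids": cm.seed_ids.tolist(),
        "target_ijk": cm.target_ijk.tolist(),
        "grid_shape": list(cm.grid_shape),
        "per_seed_total": cm.per_seed_total,
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar))
    return mtx_path


def load_connectivity_matrix(path: str | Path) -> ConnectivityMatrix:
    """Read a connectivity matrix from ``<prefix>.mtx`` (+ sidecar)."""
    path = Path(path)
    prefix = path.with_suffix("")
    counts = np.asarray(sio.mmread(str(prefix.with_suffix(".mtx"))).todense())
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return ConnectivityMatrix(
        counts=counts.astype(np.int64),
        seed_ids=np.asarray(meta["seed_ids"]),
        target_ijk=np.asarray(meta["target_ijk"]),
        grid_shape=tuple(meta["grid_shape"]),
        per_seed_total=meta["per_seed_total"],
    )


# --------------------------------------------------------------------------
# GIFTI surfaces and surface maps
# --------------------------------------------------------------------------

def save_mesh_gifti(mesh: SeedMesh, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.gifti.GiftiImage()
    img.add_gifti_data_array(
        nib.gifti.GiftiDataArray(
            mesh.vertex_coords.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
        )
    )
    img.add_gifti_data_array(
        nib.gifti.GiftiDataArray(
            mesh.triangles.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
        )
    )
    if mesh.sheet_shape is not None:
        img.meta["sheet_shape"] = json.dumps(list(mesh.sheet_shape))
    nib.save(img, path)
    return path


def load_mesh_gifti(path: str | Path) -> SeedMesh:
    img = nib.load(str(path))
    coords = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")[0].data
    tris = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")[0].data
    sheet = img.meta.get("sheet_shape")
    return SeedMesh(
        vertex_coords=np.asarray(coords, dtype=float),
        triangles=np.asarray(tris, dtype=np.int64),
        sheet_shape=tuple(json.loads(sheet)) if sheet else None,
    )


def save_map_gifti(cmap: ConnectopicMap, path: str | Path) -> Path:
    """One GIFTI functional file per map; one data array per mode."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.gifti.GiftiImage()
    for j in range(cmap.m):
        img.add_gifti_data_array(
            nib.gifti.GiftiDataArray(
                cmap.mode(j).astype(np.float32), intent="NIFTI_INTENT_NONE"
            )
        )
    img.meta["eigenvalues"] = json.dumps(cmap.eigenvalues.tolist())
    img.meta["subject_id"] = cmap.subject_id
    img.meta["session_id"] = cmap.session_id
    nib.save(img, path)
    return path


def load_map_gifti(path: str | Path) -> ConnectopicMap:
    img = nib.load(str(path))
    values = np.column_stack([d.data for d in img.darrays]).astype(float)
    # float32 storage: snap the per-mode extrema back to exactly [1, 10]
    values = np.clip(values, 1.0, 10.0)
    return ConnectopicMap(
        values=values,
        eigenvalues=np.asarray(json.loads(img.meta["eigenvalues"])),
        subject_id=img.meta.get("subject_id", ""),
        session_id=img.meta.get("session_id", ""),
    )


def save_fields_gifti(fields: np.ndarray, path: str | Path) -> Path:
    """Latent truth fields (columns) as a GIFTI functional file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.gifti.GiftiImage()
    for j in range(fields.shape[1]):
        img.add_gifti_data_array(
            nib.gifti.GiftiDataArray(
                fields[:, j].astype(np.float32), intent="NIFTI_INTENT_NONE"
            )
        )
    nib.save(img, path)
    return path


def load_fields_gifti(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.column_stack([d.data for d in img.darrays]).astype(float)


# --------------------------------------------------------------------------
# NIfTI volumes
# --------------------------------------------------------------------------

def save_volume(values: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float32), _AFFINE), path)
    return path


def load_volume(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def save_projection_image(img: ProjectionImage, path: str | Path) -> Path:
    return save_volume(img.values, path)


def load_projection_image(path: str | Path, mode_index: int) -> ProjectionImage:
    return ProjectionImage(values=load_volume(path), mode_index=mode_index)


def save_tract_atlas(atlas: TractAtlas, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, mask in atlas.masks.items():
        save_volume(mask.astype(np.float32), out_dir / f"{name}.nii")
    return out_dir


def load_tract_atlas(atlas_dir: str | Path) -> TractAtlas:
    atlas_dir = Path(atlas_dir)
    masks = {
        p.stem: load_volume(p) > 0.5
        for p in sorted(atlas_dir.glob("*.nii"))
    }
    if not masks:
        raise FileNotFoundError(f"no .nii tract masks found in {atlas_dir}")
    return TractAtlas(masks=masks)


# --------------------------------------------------------------------------
# Term-map library: NIfTI maps + terms.tsv
# --------------------------------------------------------------------------

def save_term_library(lib: TermMapLibrary, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    (out_dir / "maps").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, term in enumerate(lib.terms):
        fname = f"maps/term_{i:04d}.nii"
        save_volume(lib.maps[term], out_dir / fname)
        rows.append(
            {
                "term": term,
                "path": fname,
                "is_anatomical": int(lib.is_anatomical[term]),
                "synonym_group": lib.synonym_groups.get(term, ""),
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "terms.tsv", sep="\t", index=False)
    return out_dir


def load_term_library(lib_dir: str | Path) -> TermMapLibrary:
    lib_dir = Path(lib_dir)
    meta = pd.read_csv(lib_dir / "terms.tsv", sep="\t", keep_default_na=False)
    terms = meta["term"].tolist()
    maps = {row["term"]: load_volume(lib_dir / row["path"]) for _, row in meta.iterrows()}
    is_anat = {row["term"]: bool(int(row["is_anatomical"])) for _, row in meta.iterrows()}
    synonyms = {
        row["term"]: row["synonym_group"]
        for _, row in meta.iterrows()
        if str(row["synonym_group"]) not in ("", "nan")
    }
    return TermMapLibrary(
        terms=terms, maps=maps, is_anatomical=is_anat, synonym_groups=synonyms
    )


# --------------------------------------------------------------------------
# Cohort manifest
# --------------------------------------------------------------------------

def save_cohort_manifest(
    entries: list[dict], path: str | Path
) -> Path:
    """TSV with columns subject, session, path (one connectivity matrix each)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(entries, columns=["subject", "session", "path"]).to_csv(
        path, sep="\t", index=False
    )
    return path


def load_cohort_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"subject": str, "session": str})
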