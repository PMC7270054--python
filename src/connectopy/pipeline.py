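"""End-to-end orchestration: simulate → gradients → project → icc → decode.

A :class:`RunConfig` fixes every parameter of a run; ``run_pipeline``
executes the five stages in order, writes every intermediate artefact
under the output directory, and finishes with a JSON run manifest
(stage, inputs, outputs, checksums, wall time).  Identical config and
seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as cio
from .connectopic_mapping import (
    ALIGNMENT_THRESHOLD,
    FLIP_MIDPOINT,
    ConnectopicMap,
    align_map,
    common_dimension,
    estimate_intrinsic_dimension,
    fit_connectopic_map,
    group_average,
)
from .functional_decoding import decoding_table
from .projection_tracts import (
    make_projection_image,
    projection_skeleton,
    tract_projection,
    tract_summary,
)
from .reliability_icc import icc_table
from .synthetic_cohort import (
    CohortSpec,
    make_seed_mesh,
    make_target_space,
    plant_gradients,
    simulate_connectivity,
    simulate_term_library,
    vertex_to_voxel,
)

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """All knobs of a pipeline run, serialisable to/from YAML.

    Defaults follow the analysis conventions: 1% projection threshold,
    10,000 bootstrap resamples, flip threshold 0.75 about midpoint 5.5,
    Levina–Bickel neighbour range 8–20, raw count profiles.
    """

    out_dir: str = "connectopy_run"
    # cohort
    n_subjects: int = 6
    n_sessions: int = 2
    n_u: int = 20
    n_v: int = 20
    m_true: int = 2
    n_targets_per_tract: int = 120
    depth: float = 10_000.0
    sigma_subject: float = 0.03
    sigma_session: float = 0.008
    tau: float = 0.30
    perturbation_smoothness: float = 2.5
    # analysis
    m: str | int = "auto"
    k_min: int = 8
    k_max: int = 20
    frac: float = 0.01
    n_boot: int = 10_000
    profile_transform: str = "raw"
    alignment_threshold: float = ALIGNMENT_THRESHOLD
    flip_midpoint: float = FLIP_MIDPOINT
    # term library
    n_noise_terms: int = 20
    term_noise_sigma: float = 0.2
    # seeding
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.m != "auto":
            self.m = int(self.m)
            if self.m < 1:
                raise ValueError("m must be 'auto' or a positive integer")
        if not 0 < self.frac <= 1:
            raise ValueError("frac must lie in (0, 1]")
        if self.n_boot < 100:
            raise ValueError("n_boot must be at least 100")
        if self.alignment_threshold != ALIGNMENT_THRESHOLD:
            raise ValueError(
                "the alignment threshold is fixed at "
                f"{ALIGNMENT_THRESHOLD} by the mapping convention"
            )
        if self.flip_midpoint != FLIP_MIDPOINT:
            raise ValueError(
                f"the flip midpoint is fixed at {FLIP_MIDPOINT} "
                "by the [1, 10] normalisation"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            n_subjects=self.n_subjects,
            n_sessions=self.n_sessions,
            depth=self.depth,
            sigma_subject=self.sigma_subject,
            sigma_session=self.sigma_session,
            tau=self.tau,
            perturbation_smoothness=self.perturbation_smoothness,
            rng_seed=self.rng_seed,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    """Collects per-stage bookkeeping and writes the run manifest JSON."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.stages: list[dict] = []

    def record(self, name: str, inputs: list[Path], outputs: list[Path], dt: float) -> None:
        self.stages.append(
            {
                "stage": name,
                "inputs": [str(p) for p in inputs],
                "outputs": [str(p) for p in outputs],
                "checksums": {p.name: _sha256(p) for p in outputs},
                "wall_time_s": round(dt, 3),
                "status": "complete",
            }
        )

    def fail(self, name: str, error: str) -> None:
        self.stages.append({"stage": name, "status": "failed", "error": error})

    def write(self, path: Path) -> Path:
        doc = {
            "tool": "connectopy",
            "version": __version__,
            "config": self.config.to_dict(),
            "config_hash": self.config.config_hash,
            "stages": self.stages,
        }
        path.write_text(json.dumps(doc, indent=2, sort_keys=True))
        return path


def choose_reference(maps: dict[tuple[str, str], ConnectopicMap]) -> tuple[str, str]:
    """Deterministic medoid reference for sign alignment.

    The reference is the map with the largest total absolute Pearson
    correlation (summed over modes) to all other maps: a map whose
    eigenvectors came out atypically rough would correlate weakly with
    everyone and, through the flip-about-5.5 rule, scramble the signs
    of the whole cohort if it served as reference.  Ties break by key
    order, so the choice is reproducible.
    """
    keys = sorted(maps)
    if len(keys) == 1:
        return keys[0]
    vals = np.stack([maps[k].values for k in keys])          # (n_maps, n_vert, m)
    centred = vals - vals.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1)                  # (n_maps, m)
    score = np.zeros(len(keys))
    for j in range(vals.shape[2]):
        c = centred[:, :, j]
        corr = (c @ c.T) / np.outer(norms[:, j], norms[:, j])
        score += np.abs(corr).sum(axis=1) - 1.0              # exclude self
    return keys[int(np.argmax(score))]


def align_cohort(
    maps: dict[tuple[str, str], ConnectopicMap]
) -> tuple[dict[tuple[str, str], ConnectopicMap], tuple[str, str]]:
    """Align every map to the medoid reference map."""
    ref_key = choose_reference(maps)
    ref = maps[ref_key]
    aligned = {
        key: (m if key == ref_key else align_map(ref, m)) for key, m in maps.items()
    }
    return aligned, ref_key


def run_pipeline(config: RunConfig) -> dict:
    """Execute all five stages; returns the manifest document as a dict.

    Stage failure raises, naming the failing stage; stages completed
    so far (and the failure) are still recorded in the manifest file.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config)
    manifest_path = out / "run_manifest.json"
    state: dict = {}
    stages = [
        ("simulate", _stage_simulate),
        ("gradients", _stage_gradients),
        ("project", _stage_project),
        ("icc", _stage_icc),
        ("decode", _stage_decode),
    ]
    for name, fn in stages:
        t0 = time.perf_counter()
        try:
            inputs, outputs = fn(config, out, state)
        except Exception as exc:
            manifest.fail(name, repr(exc))
            manifest.write(manifest_path)
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest.record(name, inputs, outputs, time.perf_counter() - t0)
        logger.info("stage %s complete (%.2fs)", name, time.perf_counter() - t0)
    manifest.write(manifest_path)
    return json.loads(manifest_path.read_text())


# --------------------------------------------------------------------------
# Stages
# --------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, out: Path, state: dict):
    spec = config.cohort_spec()
    mesh = make_seed_mesh(config.n_u, config.n_v)
    truth = plant_gradients(mesh, config.m_true, config.rng_seed)
    target_space = make_target_space(truth, config.n_targets_per_tract, spec)
    outputs = [
        cio.save_mesh_gifti(mesh, out / "seed_mesh.surf.gii"),
        cio.save_fields_gifti(truth.latent_fields, out / "truth_fields.func.gii"),
    ]
    entries = []
    for si, subj in enumerate(spec.subjects, start=1):
        for wi, ses in enumerate(spec.sessions, start=1):
            cm = simulate_connectivity(
                truth, config.n_targets_per_tract, spec, si, wi, target_space
            )
            rel = f"matrices/{subj}_{ses}"
            outputs.append(cio.save_connectivity_matrix(cm, out / rel))
            entries.append({"subject": subj, "session": ses, "path": rel + ".mtx"})
            state[("cm", subj, ses)] = cm
    outputs.append(cio.save_cohort_manifest(entries, out / "cohort_manifest.tsv"))
    atlas = target_space.tract_atlas()
    cio.save_tract_atlas(atlas, out / "tract_atlas")
    outputs.append(out / "tract_atlas" / f"{atlas.names[0]}.nii")
    v2v = vertex_to_voxel(mesh)
    library = simulate_term_library(
        target_space.grid_shape,
        truth,
        v2v,
        config.n_noise_terms,
        rng_seed=config.rng_seed,
        noise_sigma=config.term_noise_sigma,
    )
    cio.save_term_library(library, out / "term_library")
    outputs.append(out / "term_library" / "terms.tsv")
    state.update(
        truth=truth, mesh=mesh, spec=spec, target_space=target_space,
        atlas=atlas, library=library, v2v=v2v,
    )
    return [], outputs


def _stage_gradients(config: RunConfig, out: Path, state: dict):
    import pandas as pd

    from .similarity_graph import similarity_matrix

    spec: CohortSpec = state["spec"]
    # dimensionality on each subject's first-session similarity matrix
    estimates = []
    for subj in spec.subjects:
        sim = similarity_matrix(state[("cm", subj, spec.sessions[0])])
        estimates.append(
            estimate_intrinsic_dimension(sim, k_min=config.k_min, k_max=config.k_max)
        )
    if config.m == "auto":
        m = common_dimension(estimates)
    else:
        m = int(config.m)
    outputs = []
    maps = {}
    dim_df = pd.DataFrame(
        {"subject": spec.subjects, "mle_dimension": estimates, "common_m": m}
    )
    dim_path = out / "dimensionality.tsv"
    dim_df.to_csv(dim_path, sep="\t", index=False)
    outputs.append(dim_path)
    for subj in spec.subjects:
        for ses in spec.sessions:
            cmap, _, _ = fit_connectopic_map(
                state[("cm", subj, ses)],
                m,
                subject_id=subj,
                session_id=ses,
                profile_transform=config.profile_transform,
            )
            maps[(subj, ses)] = cmap
    aligned, ref_key = align_cohort(maps)
    for (subj, ses), cmap in aligned.items():
        outputs.append(
            cio.save_map_gifti(cmap, out / "maps" / f"{subj}_{ses}.func.gii")
        )
    groups = {}
    for ses in spec.sessions:
        grp = group_average([aligned[(s, ses)] for s in spec.subjects])
        grp.session_id = ses
        groups[ses] = grp
        outputs.append(cio.save_map_gifti(grp, out / "maps" / f"group_{ses}.func.gii"))
    state.update(maps=aligned, groups=groups, common_m=m, ref_key=ref_key)
    return [out / "cohort_manifest.tsv"], outputs


def _stage_project(config: RunConfig, out: Path, state: dict):
    """Projection images and tract summaries for a representative subject."""
    spec: CohortSpec = state["spec"]
    subj, ses = state["ref_key"]
    cm = state[("cm", subj, ses)]
    cmap = state["maps"][(subj, ses)]
    skel = projection_skeleton(cm, frac=config.frac)
    atlas = state["atlas"]
    outputs = []
    tract_imgs: dict[str, dict[int, object]] = {name: {} for name in atlas.names}
    for mode in range(cmap.m):
        img = make_projection_image(skel, cm, cmap, mode)
        outputs.append(
            cio.save_projection_image(img, out / "projection" / f"{subj}_{ses}_g{mode + 1}.nii")
        )
        for name, timg in tract_projection(img, atlas).items():
            tract_imgs[name][mode] = timg
    summary = tract_summary(
        tract_imgs, modes=list(range(cmap.m)), n_boot=config.n_boot,
        rng_seed=config.rng_seed,
    )
    spath = out / "projection" / "tract_summary.tsv"
    summary.to_csv(spath, sep="\t", index=False)
    outputs.append(spath)
    state["tract_summary"] = summary
    return [out / "cohort_manifest.tsv"], outputs


def _stage_icc(config: RunConfig, out: Path, state: dict):
    table = icc_table(
        state["maps"],
        modes=list(range(state["common_m"])),
        n_boot=config.n_boot,
        rng_seed=config.rng_seed,
    )
    path = out / "icc_table.tsv"
    table.to_csv(path, sep="\t", index=False)
    state["icc_table"] = table
    return [], [path]


def _stage_decode(config: RunConfig, out: Path, state: dict):
    spec: CohortSpec = state["spec"]
    group = state["groups"][spec.sessions[0]]
    outputs = []
    tables = {}
    for mode in range(group.m):
        table = decoding_table(
            group, mode, state["library"], state["v2v"],
        )
        path = out / "decoding" / f"decoding_g{mode + 1}.tsv"
        path.parent.mkdir(parents=True, exist_ok=True)
        table.table.to_csv(path, sep="\t")
        outputs.append(path)
        tables[mode] = table
    state["decoding"] = tables
    return [], outputs
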