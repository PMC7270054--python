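# connectopy

Connectopic mapping of diffusion-tractography connectivity: overlapping
connectivity gradients from a seed-vertex × target-voxel streamline
visitation-count matrix, with white-matter tract projections,
test–retest reliability, and decile-based functional decoding.

## The problem

Probabilistic tractography summarises a cortical region's anatomical
connectivity as a matrix of streamline visitation counts from each seed
vertex to every voxel of the hemisphere. Rather than parcellating the
region into blocks of homogeneous connectivity, connectopic mapping
asks how connectivity *changes* across the region: it embeds the
vertices by the similarity of their connectivity profiles and reads the
low-order embedding coordinates as overlapping, smoothly varying
**modes of connectivity** (gradients g1, g2, …). The package implements
the full analysis:

1. **η² similarity** between count profiles:
   `η² = 1 − Σ[(aᵢ−mᵢ)² + (bᵢ−mᵢ)²] / Σ[(aᵢ−M̄)² + (bᵢ−M̄)²]`
   with `mᵢ = (aᵢ+bᵢ)/2` and `M̄ = mean(m)`;
2. a weighted k-nearest-neighbour graph at the **minimum k** giving a
   single connected component;
3. **Laplacian eigenmaps**: the generalised eigenproblem `L v = λ D v`
   (L = D − W), discarding the constant eigenvector and normalising
   each retained eigenvector to [1, 10];
4. model order by the **Levina–Bickel** maximum-likelihood intrinsic
   dimensionality (minimum common dimension across subjects);
5. alignment to a reference subject (flip about 5.5 when r < 0.75),
   group averaging, **ICC(2,1)** between-session and between-subject
   reliability with bootstrap CIs;
6. **projection images** (top-3 count-weighted gradient values in the
   1%-visitation skeleton), per-tract projections and summaries;
7. **decile decoding**: rank deciles of a group gradient, spatially
   correlated against a term-map library (top-3 positive,
   non-anatomical, synonym-collapsed terms per decile).

Real tractography inputs are expensive and external, so the package
ships a first-class **synthetic cohort generator** that plants known
gradients, tract-clustered targets, Poisson count noise and
subject/session variability — every stage of the pipeline is validated
against this planted ground truth (see `docs/methods.md`).

## Worked example

```python
import numpy as np
from scipy.stats import spearmanr
from connectopy import (
    CohortSpec, make_seed_mesh, plant_gradients, simulate_cohort,
    fit_connectopic_map, estimate_intrinsic_dimension, similarity_matrix,
)

mesh = make_seed_mesh(20, 20)                  # 400-vertex seed sheet
truth = plant_gradients(mesh, m_true=2, rng_seed=0)
spec = CohortSpec(n_subjects=3, n_sessions=1, sigma_subject=0.0,
                  sigma_session=0.0, rng_seed=1)
matrices, targets = simulate_cohort(truth, spec, n_targets_per_tract=120)

cm = matrices[("sub-001", "ses-1")]            # 400 × 720 counts
cmap, sim, graph = fit_connectopic_map(cm, m=2)
print("k_used:", graph.k_used)
print("eigenvalues:", np.round(cmap.eigenvalues, 5))
print("MLE dimensionality:", round(estimate_intrinsic_dimension(sim), 2))
rho = spearmanr(cmap.mode(0), truth.latent_fields[:, 0]).statistic
print("g1 vs planted field |rho|:", round(abs(rho), 3))
```

Output:

```
k_used: 4
eigenvalues: [0.00392 0.00929]
MLE dimensionality: 2.9
g1 vs planted field |rho|: 0.955
```

`k_used` is the smallest neighbour count that connects the similarity
graph; the two strictly increasing eigenvalues confirm a dominant and a
secondary mode; the dimensionality estimate sits near the two planted
gradients; and the first gradient closely reproduces the planted field's vertex
ordering.

The same pipeline runs end-to-end from the command line:

```bash
connectopy run --out run_dir --seed 1      # simulate → gradients → project → icc → decode
connectopy simulate --subjects 6 --sessions 2 --gradients 2 --seed 1 --out cohort/
connectopy gradients --cohort cohort/cohort_manifest.tsv --m auto --out maps/
```

Every run writes a JSON manifest with per-stage outputs, checksums and
wall times; identical config and seed reproduce byte-identical files.

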