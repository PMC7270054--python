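# Methods

`connectopy` re-implements connectopic mapping of diffusion-tractography
connectivity as a tested pipeline, together with a synthetic-cohort
generator that plants the ground truth the pipeline is supposed to
recover. This note records the model, the parameters that matter, the
numerical choices, and what the synthetic validation does and does not
establish about real data.

## The analysis model

The subject-level input is a **visitation-count matrix**: for each seed
vertex on a cortical surface patch, the number of probabilistic
streamlines reaching each target voxel. The analysis proceeds in five
stages.

**1. Profile similarity (η²).** The connectivity profile of vertex *i*
is its count row. Similarity between two profiles *a*, *b* is the η²
coefficient: with mᵢ = (aᵢ+bᵢ)/2 and M̄ the mean of the mᵢ,

    η² = 1 − [Σᵢ (aᵢ−mᵢ)² + (bᵢ−mᵢ)²] / [Σᵢ (aᵢ−M̄)² + (bᵢ−M̄)²],

the fraction of the pair's total variance not attributable to
within-pair disagreement. η² is 1 for identical non-constant profiles,
bounded in [0,1], and invariant to a common rescaling of both profiles.
Similarity is computed on raw counts by default; `log1p` and per-row
normalisation are available as `profile_transform` options.

**2. Minimal-k neighbour graph.** The similarity matrix becomes a
weighted graph by connecting each vertex to its k most similar others
(union symmetrisation, edge weight = similarity, ties broken by vertex
index, zero-similarity edges dropped), with k the smallest value that
leaves a single connected component. This minimal-k rule produces very
sparse graphs (k = 2–5 at n = 400); its spectral consequences are
discussed under *Limitations*.

**3. Laplacian eigenmaps.** With W the weights, D = diag(row sums) and
L = D − W, the generalised eigenproblem L v = λ D v is solved densely
(`scipy.linalg.eigh`; the seed patches here are a few hundred vertices,
far below the size where iterative solvers pay off). The constant
eigenvector at λ = 0 is discarded; the next *m* eigenvectors, by
ascending eigenvalue, are the connectivity gradients g1…gm. Each is
affinely normalised to [1, 10]. Eigenvector signs are canonicalised
(largest-magnitude entry positive) so single-subject output is
deterministic.

**4. Model order, alignment, group maps.** The number of modes *m* is
the floor of the minimum over subjects of the Levina–Bickel maximum-
likelihood intrinsic-dimensionality estimate, computed on the rows of
each subject's similarity matrix under Euclidean distance with the
neighbour range k = 8…20 (a conventional range; the estimate averages
over points, then over k; zero-distance duplicate terms are skipped with
a warning). Individual maps are sign-aligned to a reference subject:
a map is flipped about the midpoint 5.5 (g → 11 − g) when its Pearson
correlation with the reference is below 0.75. Aligned maps are averaged
vertex-wise per session and re-normalised to give group maps.

The reference is the cohort **medoid** — the map with the largest total
|r| to all others, ties broken by subject/session key. A fixed-index
reference (e.g. always the first subject) proved fragile: when that one
subject's higher-mode eigenvector comes out atypically rough, every
other subject correlates with it below 0.75 and the flip rule scrambles
signs across the whole cohort. The medoid is equally deterministic and
removes this failure mode. Note the flip rule itself is two-sided only
in intent: for a map whose correlation with the reference lies in
(0, 0.75) the flip makes agreement worse, not better. We implement the
stated rule as-is; the medoid reference keeps cohorts away from that
regime in practice.

**5. Derived analyses.**
*Projection images*: per vertex, target voxels visited by at least
`frac` (default 1%) of that vertex's streamlines form the projection
skeleton; each skeleton voxel receives the count-weighted mean gradient
value of the up-to-3 vertices with the highest surviving counts to it
(ties by vertex index). Weights are the visitation counts themselves,
taken post-threshold. Restricting a projection image to a named binary
tract mask gives a tract projection, summarised by the mean over
populated voxels with a 10,000-sample percentile-bootstrap 95% CI.
*Reliability*: ICC(2,1) — two-way random effects, absolute agreement,
single measure — over vertices, with the two sessions of one subject
(between-session) or the two members of a subject pair within a session
(between-subject) as the k = 2 raters; summaries are means over
subjects/pairs with percentile-bootstrap CIs (resampling subjects and
pairs respectively; subject-level resampling for the between-subject
case is available as an option).
*Decoding*: each group gradient is split into ten equal-population
rank deciles (remainder vertices go to the lowest bins, ties by vertex
index — rank bins make decoding invariant to monotone transforms of the
gradient); each decile's binary volume map is Pearson-correlated with
every term map in a library over an analysis mask (default: the whole
grid); anatomical-flagged terms are dropped, synonym groups keep only
their best member, only positive correlations are reported, top 3 per
decile.

## The synthetic cohort

The generator plants known structure with the statistical features the
pipeline exploits; all randomness flows from one seed through named
`SeedSequence` substreams, so cohorts are bit-reproducible and adding
subjects never perturbs existing ones.

* **Seed surface**: a regular triangulated n×n sheet (default 20×20,
  400 vertices). Real cortical geometry is deliberately not modelled;
  the sheet makes latent-field orthogonality and recovery measurable.
* **Planted gradients**: up to three smooth fields on the sheet — the
  normalised u-coordinate, the normalised v-coordinate, and the
  normalised radial distance from the sheet centre. The centre (rather
  than a corner) for the third field is forced by the orthogonality
  requirement: a corner-radial field has centred cosine ≈ 0.69 with
  both axis fields, while the centre-radial field is orthogonal to both
  by symmetry on a regular sheet.
* **Targets**: six "tracts" named after the temporal-lobe bundles
  (ILF, IFOF, UF, AF, MdLF, AR), each a cluster of voxels (default 120)
  whose latent positions are the tract centre plus a fixed per-voxel
  jitter N(0, (τ/2)²). Centres are spread widely along latent axis 1
  (0.06…0.94, uniform gaps — the inferior–superior ordering of the real
  bundles), and progressively more narrowly along axes 2 and 3 (spreads
  0.30 and 0.24, with AF separated from the rest on axis 2). The
  decreasing spreads make the planted modes explain strictly decreasing
  connectivity variance, mirroring the dominant-to-minor ordering of
  empirical gradients; with equal spreads the two leading eigenvalues
  are near-degenerate and the recovered modes mix or swap.
* **Counts**: vertex *i*'s expected profile mixes a diffuse Gaussian
  tuning kernel exp(−‖gᵢ − cⱼ‖²/2τ²) over the jittered tract centres
  (weight 0.97, τ = 0.30 latent units) with a proximal component
  concentrated on the vertex's few nearest target voxels, decaying
  exponentially with distance *rank* (weight `local_mass` = 0.03, decay
  1.0). The proximal mass models the stem of a vertex's own streamline
  paths — voxels traversed by essentially all of its streamlines — and
  is what allows voxels to clear a visitation threshold phrased as a
  fraction of streamlines seeded; being concentrated on different
  voxels for different vertices, it adds a near-constant offset to all
  pairwise η² distances and leaves the neighbour ranking, and hence the
  embedding, intact. Rows are scaled to `depth` (default 10,000)
  expected visits and realised as independent Poisson counts. Poisson
  noise is an assumption; the noise structure of real visitation
  matrices is not characterised in the literature we follow.
* **Subject/session variability**: additive Gaussian random fields on
  the sheet, spatially smoothed (width 2.5 vertices) and scaled to
  σ_subject = 0.03 (drawn once per subject, shared by its sessions) and
  σ_session = 0.008 (drawn per session). Smooth fields matter: i.i.d.
  vertex noise of the same magnitude destroys the local profile
  similarity the graph is built from and pushes cross-subject map
  correlations into the flip rule's destructive zone. With session
  noise below subject noise, between-session reliability exceeds
  between-subject reliability, the structure the reliability stage must
  detect.
* **Term library**: for each planted gradient and decile, the voxel
  indicator of that decile's vertices plus Gaussian noise (default
  σ = 0.2; smoothing optional and off by default so the zero-noise term
  correlates perfectly with its decile mask); plus pure-noise terms and
  one anatomical-flagged map (the seed-sheet footprint) that must never
  be reported.

## Problem sizes and verification scope

The validation suite runs the full pipeline at 400 vertices, 720
target voxels, and cohorts of 3–42 subjects; these sizes keep the whole
suite in the low minutes while leaving every stage's behaviour
measurable. At these conditions: single-gradient recovery is
|ρ| ≈ 0.998 per subject; two overlapping gradients are recovered by the
aligned group map at |ρ| ≈ 0.93–0.96; Levina–Bickel estimates on the
two-gradient cohort sit near 2.9 (common dimension 2); between-session
ICC exceeds between-subject ICC for every mode at the 42-subject scale;
and decile decoding recovers the planted term as top-1 for ≥ 9/10
deciles at term-map noise σ = 0.3.

## Numerical choices and degenerate inputs

* η² of two equal constant profiles is 1 by convention (with a
  warning); all-zero count rows are rejected at load.
* Duplicate points in the dimensionality estimator contribute
  zero-distance terms, which are skipped with a warning; all-duplicate
  input is an error.
* Constant maps cannot be normalised to [1, 10] or split into deciles;
  both reject rather than guess.
* Bootstrap CIs are percentile 2.5/97.5; on very small unit counts the
  interval is widened, if needed, to bracket the point estimate.
* A constant term map over the analysis mask has no defined
  correlation; the term is skipped with a warning.
* All ranking ties (neighbour lists, top-3 hitters, decile boundaries)
  break by ascending index; sorted term lists break ties by name.

## Limitations

* **The minimal-k graph is noise-stabilised.** At a few hundred
  vertices the minimum connected k is 2–5, barely above a spanning
  tree. Counter-intuitively, *reducing* count noise degrades the
  embedding: with near-noiseless counts the neighbour ranking becomes
  deterministic and anisotropic (each vertex picks neighbours along the
  slowest-varying latent axis), yielding a comb-shaped graph whose
  leading eigenvectors are distorted; Poisson ranking noise mixes the
  picks and keeps the graph isotropic on average. Individual-subject
  recovery of the *second* gradient consequently fluctuates (median
  |ρ| ≈ 0.95, occasional cohorts below 0.9); the aligned group average
  is the stable quantity, which is why overlap recovery is validated at
  the group level. Larger seed regions (real cohorts use thousands of
  vertices) relax all of this.
* **Tract summaries near gradient extremes are compressible.** The
  leading eigenvector flattens toward the ends of the sheet, and tract
  centres closer than about twice the voxel-jitter SD can swap their
  projection means through an unlucky jitter draw. Ordering is
  therefore asserted for tract pairs separated by more than 2× the
  jitter SD.
* Passing the synthetic suite shows the pipeline recovers smooth,
  overlapping, tract-clustered structure under Poisson noise and the
  stated subject/session model. It does not validate behaviour under
  real tractography artefacts (gyral bias, distance decay,
  false-positive bundles), real cortical geometry, or non-Poisson
  overdispersion — none of which the generator emulates.
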