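# Methods

This note documents the models, parameters, numerical choices and known
limitations of `evensurf`.

## Geometric substrate

All surfaces are closed genus-0 triangle meshes (`TriangleMesh`): per-vertex
mm coordinates plus ordered faces, validated for closedness (every edge in
exactly two faces), Euler characteristic 2, and absence of degenerate faces.
Degenerate faces are rejected at load rather than repaired.

**Icospheres.** `make_icosphere(n)` subdivides each icosahedron edge into
`n` equal segments and projects radially, giving `10n² + 2` vertices and
`20n²` faces. This is the "ico-n" resolution convention: ico32 has 10,242
vertices, ico64 has 40,962, ico256 has 655,362, ico512 has 2,621,442.

**Geodesics.** "Geodesic distance" throughout means the graph geodesic:
Dijkstra shortest paths along mesh edges weighted by Euclidean edge length.
Exact polyhedral geodesics (MMP, heat method) are out of scope; the graph
metric overestimates true geodesics by a direction-dependent lattice factor
(up to a few percent on these meshes), which is acceptable because every
comparison uses the same metric on both sides.

**Barycentric anchors.** Off-grid points are represented as (face, convex
weights) on a reference mesh. Location uses central (gnomonic) projection:
for face corner matrix `M = [A B C]`, solving `M u = p` gives the ray-face
intersection at weights `u / Σu`, valid iff `u ≥ 0`. Candidate faces come
from the nearest vertex's star (k-d tree lookup); ties on shared edges
resolve to the lowest face index; a full-mesh scan is the fallback for the
rare numerically marginal query. This is exact for star-shaped meshes,
which covers every mesh located against here (registration spheres).

## Synthetic cohorts

The generator emulates the one geometric property of real registration data
the method depends on: a smooth, population-shared pattern of local
expansion/shrinkage between the registration sphere and the anatomy (the
distortion that inflation introduces), with small per-subject variability.

- Registration sphere: icosphere of radius 100 mm (the FreeSurfer
  convention), shared by all subjects.
- Population log-distortion field `f`: i.i.d. standard normal per vertex,
  smoothed by `smooth_passes` rounds of vertex+neighbor averaging, then
  standardized to zero mean and unit s.d. Smoothing passes control the
  spatial scale of distortion; 4 passes (default) give a correlation length
  of a few mesh edges.
- Anatomy: `r(v) = 100 · exp(alpha · f(v))` along each vertex direction,
  plus i.i.d. normal jitter (`jitter` mm per coordinate) per subject.
  The exponential keeps radii positive and makes `alpha` a log-scale
  distortion amplitude; local area distortion is ≈ `exp(2·alpha·f)`.
- Defaults `alpha = 0.5`, `smooth_passes = 4`, `jitter = 0.2 mm` define the
  standard test conditions. At `alpha = 0.5` the realized surface is much
  larger and more strongly stretched than real cortex relative to its
  sphere (max/min area distortion far above the ≥2 regression floor), which
  makes it a deliberately hard case for uniform sampling.

What the generator does *not* emulate: gyral/sulcal folding geometry,
curvature-correlated distortion, topological noise, hemispheric asymmetry.
Passing tests therefore show that the optimizer equalizes sampling under
smooth radial distortion of realistic amplitude, not that it reproduces the
released template for real brains.

Synthetic responses mix a shared signal `S` with independent noise:
`X_p = sqrt(s)·S + sqrt(1−s)·N_p`, entries standard normal, so the expected
correlation between participants' patterns equals the signal fraction `s`.

## Sampling optimization

Loss: `L = Σ 1/(d_ij + ε)^p` over unordered pairs with `d_ij < d_thr`,
`p = 4`, `ε = 0.001` (the regularizer guards coincident points during
continuous moves; the headline loss can be recomputed with `ε = 0`).
Summing each unordered pair once halves the work of the symmetric
double-sum and leaves the argmin unchanged.

**Cutoff.** `d_thr` is about twice the mean inter-vertex distance of the
target resolution. On real-cortex geometry (100-mm sphere) this is
`256 mm / ico` — 8 mm at ico32, 4 mm at ico64 (`default_cutoff`). For
synthetic cohorts whose anatomical area differs greatly from the sphere's,
`calibrate_cutoff` measures the cohort directly: twice the mean anatomical
edge length of the icosahedral sampling at equal resolution. The
calibration matters: a cutoff well below twice the spacing lets the
optimizer reach configurations where *no* pair is within range, making the
loss identically zero and the placement indifferent to uniformity.

**Candidate set.** Candidates are the vertices of an icosphere ~8× the
template's linear resolution (~64× the count). Each candidate is located on
the subjects' registration spheres, carried to each anatomy barycentrically,
and candidate-mesh edges get anatomical lengths. By default edge lengths
are averaged across subjects before one cutoff-Dijkstra pass per candidate
(`mean-edge`); averaging per-subject Dijkstra distances (`mean-dijkstra`)
is available but costs one pass per subject. Distances are stored
cutoff-sparse and explicitly symmetrized (directional float drift in path
sums is removed by taking the element-wise maximum).

**Coarse stage.** Candidate loss values are maintained incrementally: a
relocation touches only candidates within `d_thr` of the old and new
locations (one sparse row each). Each vertex is removed, then placed on the
free candidate with minimal loss value — its own previous location counts
as free, so the total loss never increases; ties break to the lowest
candidate index. Sweeps visit all vertices in per-sweep random order and
stop early when no vertex moves; restart `r` uses seed `seed + r`, and the
restart with the smallest loss wins.

**Fine stage.** Each vertex gets a tangent-plane descent direction by
central differences (probe `1e-4` of the sphere radius) of its pairwise
loss, where distances to neighbors use the barycentric estimate
`d̂ = Σ w_ik w_jl d_kl` over the candidate distance matrix. Corner pairs
absent from the cutoff-sparse matrix are treated as lying exactly at the
cutoff (their contribution is ~0, keeping the estimate finite and
continuous at the boundary). The line search evaluates the null step plus
twelve geometric steps `2⁻²¹ … 2⁻¹⁰` (in units of the sphere radius by
default; mm optionally) and applies half the best displacement; the halving
guards the simultaneous update of all vertices. Rounds stop early when the
relative loss change drops below 1e-6 (default 10 rounds), and a round that
would raise the total loss is reverted, so the fine loss never exceeds the
coarse loss.

A behavioral note: because the interpolated distance field is piecewise
linear with cones at candidate vertices, a coarse-optimal vertex usually
sits in a V-shaped minimum of the estimated loss, and the fine stage then
(correctly) keeps the null step. Its gains are therefore small and
concentrated on vertices the discrete stage left off balance.

## Mesh construction

Initial faces are the convex-hull simplices of the template's sphere
locations. Diagonal flips then compare, for each pair of neighboring faces
forming quadrilateral ABCD, the current diagonal AC with the alternative BD
*measured on the cohort-average anatomy*; the shorter diagonal wins, ties
keep the current split. Since BD is generally not an edge of any subject
mesh, its anatomical length is the straight-line distance between the
anchored anatomical positions — cheap, and flips only compare lengths.
Flips are applied eagerly in ascending lexicographic edge order, guarded
against duplicate faces, non-manifold edges and interior-vertex valence
below 3; each flip strictly shortens one diagonal, so the total anatomical
edge length decreases monotonically and the passes terminate (revisited
configurations would stop the loop with a warning). Flips change
connectivity only, never vertex positions. Outward orientation uses the
centroid-ray test, which is exact for the star-shaped sphere meshes
produced here; positive signed volume certifies it.

## Evaluation

Three per-vertex density maps, all computed by locating the template's
sphere vertices on each subject's registration sphere and carrying them to
the subject anatomies:

- **Inter-vertex distance** (mm): mean straight-line distance to
  template-mesh neighbors, averaged over neighbors and subjects. Neighbors
  are within about one template edge, where the chord approximates the
  geodesic.
- **Vertex area** (mm²): one third of incident face areas on each subject
  anatomy, averaged over subjects.
- **Searchlight count**: vertices within a geodesic radius (default 20 mm)
  on the template graph weighted by mean anatomical edge lengths.

Dispersion uses the population variance (`ddof=0`, a flag switches to
sample variance), matching its descriptive use. `variance_reduction`
reports `100·(1 − new/old)`.

Runtime scaling of matrix operations is summarized by a least-squares line
in log-log space (`time ∝ size^p`); `doubling_factor` is `2^p`.

## MVPA benchmark

Between-participant time-point classification: the predicted pattern for
each time point is the training participants' mean; a left-out
participant's time point is correct iff its measured pattern correlates
highest with its own prediction among all T predictions (computed through
the T×T correlation Gram matrix; chance 1/T). RDMs use correlation distance
(1 − Pearson r) on time-point patterns, vectorized by the strict upper
triangle. RSA-ISC correlates each participant's RDM vector with the mean of
the others'; correlations are averaged through the Fisher z transform.
Reliability extrapolation: Cronbach's α with items as rows, the
Spearman–Brown prediction and its closed-form inverse, and `equivalent_n`,
which finds the fractional sample size at which a performance curve
reaches a target — cubic-spline interpolation for accuracy curves (the
spline family is a documented choice; the curves are smooth and monotone),
Spearman–Brown parameterization for ISC curves.

The PCA + nested-cross-validation preprocessing used for whole-cortex
classification of real data is exposed only as an optional preprocessing
hook and off by default: synthetic dimensionality is controlled, and the
step is orthogonal to template comparison. Hyperalignment is a pluggable
alignment interface with only the identity alignment shipped.

## Problem sizes and determinism

The standard benchmark conditions are: synthetic cohort of 10 subjects on
an ico-16 anatomy (2,562 vertices, `alpha = 0.5`), a 642-vertex template
(ico8) chosen from 40,962 candidates (ico64), 5 restarts × 20 sweeps of
coarse optimization and 5 fine rounds — sizes chosen so the full pipeline,
including the all-candidate cutoff-Dijkstra pass, runs in about a minute on
one CPU while keeping the candidate-to-vertex ratio (64×) and the
cutoff-to-spacing ratio (2×) of full-scale template construction. Under
these conditions the anatomy-based template reduces the variance of all
three density maps by well over 80% relative to sphere-based sampling;
at very small vertex counts (≲100) the vertex-area map is dominated by
triangulation-degree noise and the comparison is not meaningful.

Every stochastic component takes an explicit seed and is a pure function of
it (NumPy `default_rng`; cohort subjects use spawned seed sequences;
optimizer restart `r` uses `seed + r`). Relocation and flip orders are
deterministic given the seed, so runs reproduce bit-for-bit.

## Known limitations

- Graph geodesics, not exact polyhedral geodesics; the lattice anisotropy
  tilts fine-stage gradient directions by ~1° on icosphere candidate meshes.
- The synthetic anatomy is a radially distorted sphere; no folding, so
  conclusions about real-cortex magnitudes must come from real cohorts.
- Each hemisphere/mesh is optimized independently; no joint optimization.
- Hull-based triangulation assumes points in convex position on the
  registration sphere (true here by construction).
- The fine stage's step-size unit (sphere-radius fraction vs mm) is a
  convention choice exposed in configuration.
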