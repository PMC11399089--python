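# evensurf

Anatomy-based uniform sampling of cortical surface templates.

Surface-based neuroimaging analysis resamples every brain onto a shared
template mesh. Classic templates place their vertices as a geodesic
icosahedron on the *inflated spherical* surface, so after the sphere is
mapped back onto the folded cortex the sampling is far from uniform:
regions that expanded during inflation are sampled densely, regions that
shrank are sampled sparsely. Uneven sampling discards fine-grained pattern
information in undersampled cortex, reweights regions in multivariate
pattern analysis (MVPA), and inflates the cost of searchlight algorithms
wherever searchlights collect too many vertices.

`evensurf` builds templates the other way around: template vertices are
placed to be uniformly distributed on the cohort's *anatomical* surfaces.
It is aimed at researchers who build or evaluate surface template spaces,
and at anyone who wants a desk-scale, fully synthetic testbed for the
geometry and MVPA machinery involved.

## Method

Given a cohort of subjects with a spherical registration surface and an
anatomical surface in vertex-wise correspondence, template vertex locations
minimize the pairwise repulsion loss

```
L = Σ_{d_ij < d_thr}  1 / (d_ij + ε)^p        (unordered pairs i ≠ j)
```

where `d_ij` is the Dijkstra geodesic distance between vertices *i* and *j*
on the cohort-average anatomical edge metric, `p = 4`, `ε = 0.001`, and the
cutoff `d_thr` is about twice the mean inter-vertex distance (8 mm at the
ico32 resolution of real cortex; calibrated from the cohort in general).
Optimization has two stages:

1. **Coarse** — a greedy discrete search over the vertices of a
   high-resolution candidate icosphere (~64× as many candidates as template
   vertices). Every candidate carries a loss value equal to the increase in
   `L` its occupation would cause; each vertex in turn is removed and
   re-placed on the minimum-loss candidate, sweeping all vertices in random
   order until a local optimum, with random restarts.
2. **Fine** — vertices move freely on the registration sphere in small
   line-searched steps (2⁻²¹…2⁻¹⁰ of the sphere radius, best step halved
   because all vertices move simultaneously) along a numerically
   differentiated descent direction; distances between off-grid locations
   are estimated by barycentric interpolation of candidate-to-candidate
   distances, `d̂_ij = Σ_kl w_ik w_jl d_kl`.

The final mesh connectivity is the convex hull of the sphere locations,
improved by diagonal flips that re-split each quadrilateral of neighboring
faces along whichever diagonal is shorter on the anatomy, and ordered so
face normals point outward.

Template quality is quantified by the dispersion (variance/s.d.) of three
per-vertex density maps — inter-vertex distance, vertex area, and the
number of vertices in a 20-mm geodesic searchlight — and by MVPA benchmarks
on synthetic multi-participant responses: between-participant time-point
classification, representational-geometry inter-subject correlation
(RSA-ISC) with Fisher averaging, and reliability extrapolation over sample
size via Cronbach's α and the Spearman–Brown prediction
`r_n = n·r₁ / (1 + (n−1)·r₁)`.

Everything runs on synthetic cohorts (a distorted sphere standing in for a
hemisphere), and real FreeSurfer-binary / GIFTI surfaces are read and
written natively.

## Worked example

```python
from evensurf.synthetic import DistortionSpec, make_cohort
from evensurf.pipeline import build_template
from evensurf.uniformity import evaluate_template, dispersion, variance_reduction
from evensurf.mesh import make_icosphere

spec = DistortionSpec(ico_order=8, alpha=0.5, seed=0)   # 642-vertex anatomy
cohort = make_cohort(spec, 5)
result = build_template(cohort, template_ico=4, candidate_ico=16,
                        restarts=5, max_sweeps=20, fine_rounds=5, seed=0)
maps = evaluate_template(result.template.sphere, cohort, radius=40.0)
baseline = evaluate_template(make_icosphere(4, radius=cohort.sphere_radius),
                             cohort, radius=40.0)
for name in maps:
    old, new = dispersion(baseline[name]), dispersion(maps[name])
    print(name, f"{old.variance:.2f} -> {new.variance:.2f}",
          f"({variance_reduction(old, new):.1f}% reduction)")
```

prints

```
 inter_vertex_distance: variance     943.94 ->     38.00 (96.0% reduction)
           vertex_area: variance 9260958.57 -> 699553.68 (92.4% reduction)
     searchlight_count: variance       4.80 ->      0.36 (92.5% reduction)
```

i.e. on this synthetic cohort, a 162-vertex anatomy-optimized template cuts
the variance of all three density maps by >90% relative to sphere-based
icosahedral sampling at equal vertex count: sampling density became nearly
uniform on the folded surface.

The same pipeline is available from the shell:

```sh
evensurf synth --ico 16 --subjects 10 --alpha 0.5 --seed 0 --out cohort/
evensurf build --cohort cohort/ --template-ico 8 --candidate-ico 64 \
               --restarts 5 --sweeps 20 --seed 0 --out template/
evensurf eval  --template template/ --cohort cohort/ --compare-ico 8 --out stats/
evensurf mvpa  --participants 12 --signal-fraction 0.5 --out mvpa/
```

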