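# curvomesh

Robust estimation of membrane curvature on triangle meshes extracted from
binary voxel segmentations, using tensor voting over geodesic neighborhoods.

Surfaces segmented from 3D images — cryo-electron tomograms above all, but
also light-microscopy or MRI segmentations — are binary voxel masks. The
triangle meshes extracted from them carry *quantization noise* (step-like
artifacts of the voxel grid) and, because of missing-wedge artifacts and
segmentation holes, *open borders*. Classical discrete curvature operators
(1-ring cotangent formulas, osculating-circle fits) measure mostly the steps
between neighboring triangles on such data. `curvomesh` instead estimates
normals, principal directions and principal curvatures per *triangle center*
by accumulating weighted votes from a geodesic neighborhood of the surface,
which averages the quantization noise away while preserving features larger
than the chosen neighborhood scale.

## Method

A segmentation (membrane mask + filled compartment lumen) is turned into an
oriented, single-layer mesh (Gaussian smoothing with σ = 1 voxel, Marching
Cubes at half maximum, masking back to the membrane). The mesh is mapped to a
**surface graph**: one vertex per triangle at its centroid, *strong* edges
between triangles sharing an edge, *weak* edges between triangles sharing one
vertex. Dijkstra shortest paths on this graph approximate geodesic distances;
triangles with fewer than three strong edges are surface borders and can be
filtered out to a chosen geodesic depth.

The neighborhood scale is set by a single parameter `radius_hit` (rh), the
radius of the smallest feature to resolve: g_max = π·rh/2 (a quarter circle
of radius rh), with exponential vote decay σ = g_max/3.

**Normals (VV).** Each neighbor at cᵢ with unit normal n̂_cᵢ casts the vote

    n̂ᵢ = n̂_cᵢ + 2 cos θᵢ · (cᵢ−v)/‖cᵢ−v‖ ,   cos θᵢ = −n̂_cᵢ·(cᵢ−v)/‖cᵢ−v‖,

the normal transported along the circular arc from cᵢ to v. Votes accumulate
into V_v = Σ wᵢ n̂ᵢn̂ᵢᵀ with wᵢ = (aᵢ/a_max)·exp(−gᵢ/σ) (area aᵢ, geodesic
distance gᵢ); the dominant eigenvector of V_v, signed by the original
orientation, is the estimated normal n̂_v.

**Curvatures.** Each neighbor vᵢ contributes a tangent tᵢ (projection of
vᵢ−v onto the tangent plane) and the signed curvature of the arc through v
and vᵢ, κᵢ = ±2 sin(φᵢ/2)/‖vᵢ−v‖, positive where the patch bends toward the
(inward) normal. Votes form the tensor

    B_v = (1/2π) Σ wᵢ κᵢ tᵢtᵢᵀ ,   Σ wᵢ = 2π.

Discarding the eigenvalue whose eigenvector is most parallel to n̂_v (it is
≈ 0; a built-in diagnostic), the remaining eigenpairs b₁ ≥ b₂ give the
principal directions and κ₁ = 3b₁ − b₂, κ₂ = 3b₂ − b₁, from which mean and
Gaussian curvature, curvedness and shape index follow. Variants:

| variant | vote weights | notes |
|---|---|---|
| RVV | exp(−gᵢ/σ) | regular vector voting |
| AVV | (aᵢ/a_max)·exp(−gᵢ/σ) | area-weighted; **default**, robust to irregular tessellation |
| NVV | exp(−gᵢ/σ), κᵢ = φᵢ/gᵢ unsigned | kept to document its curvature-sign failure |
| SSVV | equal, 8 surface samples at distance rh | osculating-circle sampling; exact on spheres, needs rh ≈ feature radius |

## Worked example

```
$ curvomesh demo --outdir demo_out
demo vesicle r=8: 2312 triangles, median kappa_1 = 0.1296 voxel^-1 (true 1/r = 0.1250)
```

The demo voxelizes a spherical vesicle of radius 8 (membrane shell + lumen,
written as MRC), extracts the oriented surface, and estimates curvature with
AVV at rh = 8: the median maximum principal curvature 0.1296 voxel⁻¹ recovers
the vesicle curvature 1/r = 0.125 to within ~4% despite voxelization. The
same pipeline from Python, on the quantization-noise benchmark sphere
(radius 10 voxels in a 25³ volume):

```python
import curvomesh as cm
bench = cm.make_voxel_sphere(r=10, box=25)
table = cm.run_benchmark_table(bench, ["AVV"], [8, 10])
print(table)
```

```
algorithm  rh   auc_k1   auc_k2  auc_both  n_triangles  n_failed  failed
      AVV   8 0.910568 0.839117  0.874842         3804         0   False
      AVV  10 0.947792 0.929180  0.938486         3804         0   False
```

`auc_both` is the normalized area under the cumulative histogram of the
relative errors of both principal curvatures against the true 1/r = 0.1
(1.0 = every triangle exact): at the optimal rh = 10 ≈ feature radius, AVV
reaches ~94% despite the fully step-like input surface.

Shell workflow for real data:

```
curvomesh surface --membrane mem.mrc --lumen lum.mrc -o surf.vtp
curvomesh curvature -i surf.vtp -o curv.vtp --algorithm AVV --radius-hit 10 --exclude-borders 5
```

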