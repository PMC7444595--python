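# Methods

## Problem setting

Binary segmentations of membranes (from cryo-electron tomography, light
microscopy, MRI, ...) define surfaces only up to the voxel grid: the mesh
extracted from a {0,1} mask is step-like (quantization noise), and holes or
missing-wedge artifacts leave open borders. Curvature is a second-order
differential property, so naive discrete estimators amplify this noise.
`curvomesh` estimates normals, principal directions and principal curvatures
at triangle centers by tensor voting over geodesic neighborhoods, trading
spatial resolution (features smaller than the neighborhood are averaged out)
for robustness.

## Surface model and conventions

* Meshes are oriented triangle meshes; estimation quantities live on
  triangle centroids, not mesh vertices, so every vote is cast by a whole
  triangle and can be weighted by its area.
* Normals point **inward** on a convex closed surface (into the enclosed
  compartment). With this convention both principal curvatures are positive
  on convex regions; a saddle has κ₁ > 0 > κ₂.
* Degenerate triangles (area < 10⁻¹² input units²) keep their graph vertex
  but cast no votes.
* Coordinates are voxel-centered and 0-based; physical units enter only as
  a scale factor (curvatures in voxel⁻¹ times 1/voxel-size give nm⁻¹).

## Surface generation from segmentations

The compartment path joins the membrane mask with the filled lumen, smooths
the binary volume with a Gaussian kernel (σ = 1 voxel by default — enough to
remove Marching-Cubes spikes while exploiting sub-voxel precision), extracts
the isosurface at 0.5 (half maximum of a binary mask), orients it by the
smoothed-field gradient (inward = toward the filled volume), and keeps only
triangles within 3 voxels (Euclidean, via distance transform) of the
membrane mask — the threshold bridges small segmentation holes. The ~3-voxel
collar this leaves at open ends is removed later by graph-based border
filtering, not during masking. A membrane-only mask is handled by
morphological hole-filling followed by the same path; masks that do not
enclose a volume are rejected rather than guessed at.

## Surface graph and geodesics

One graph vertex per triangle at its centroid; triangle pairs sharing a mesh
edge (two vertices) get *strong* edges, pairs sharing one vertex *weak*
edges, each weighted by the Euclidean centroid distance (the natural choice;
nothing in the construction pins down another metric). Geodesic distances
are Dijkstra shortest paths over both edge classes — weak edges only enlarge
the path set, so they can only shorten path estimates. Exact polyhedral
geodesics are deliberately out of scope; the graph approximation
overestimates true geodesics slightly but consistently.

Borders are exactly the vertices with fewer than three strong edges.
`filter_borders` removes all triangles within a chosen geodesic distance of
any border (5 voxels reproduces the benchmark protocol; estimates closer to
a border lack neighborhood support and degrade measurably — the cylinder
benchmark quantifies this).

## Neighborhood scale

One parameter, `radius_hit` (rh, in input length units), approximates the
radius of the smallest feature whose curvature (rh⁻¹) is still estimated
reliably. The geodesic reach is g_max = π·rh/2 (a quarter circle of radius
rh) and the weight decay is σ = g_max/3, so votes at the neighborhood edge
carry weight e⁻³ ≈ 5%. rh should be chosen ≈ the radius of the features of
interest; larger rh averages them away, smaller rh measures voxel steps.

## Normal voting (VV)

Votes are Householder reflections of the neighbor normal across the plane
perpendicular to the connecting chord — equivalently, parallel transport
along the shortest circular arc — and are unit vectors by construction.
The vote covariance V_v = Σ wᵢ n̂ᵢn̂ᵢᵀ with wᵢ = (aᵢ/a_max)e^{−gᵢ/σ} is
positive semi-definite with trace Σ wᵢ; its dominant eigenvector is the
normal estimate, signed to agree with the original surface orientation
(the covariance loses the sign). The center triangle casts no vote for
itself; its original normal enters only through the sign rule. On a
noiseless plane the estimate is an exact fixed point; on a 10%-noise plane
the maximum orientation error drops from ~21% (raw normals) to below 1%
at rh = 4.

## Curvature voting and tensor decomposition

For each neighbor: tangent tᵢ = normalized tangent-plane projection of
vᵢ−v (votes with projection norm < 10⁻¹² are skipped); turning angle φᵢ
between n̂_v and the projection of the neighbor's estimated normal onto the
arc plane, computed atan2-style for stability; curvature magnitude
|κᵢ| = 2 sin(φᵢ/2)/‖vᵢ−v‖ — exactly 1/r for any two points on a sphere of
radius r — and sign −sign(tᵢᵀn̂_vip), positive toward the normal. Weights
(RVV: distance decay; AVV: additionally area-normalized) are rescaled to
Σwᵢ = 2π before forming B_v = (1/2π)Σ wᵢκᵢ tᵢtᵢᵀ. The rescaling is applied
to AVV as well as RVV: it is what makes the linear eigenvalue map below
exact under isotropic vote coverage.

Averaging Euler's relation κ(ψ) = κ₁cos²ψ + κ₂sin²ψ over uniformly
distributed tangent directions gives in-plane tensor eigenvalues
(3κ₁+κ₂)/8 and (κ₁+3κ₂)/8 and a null eigenvalue along the normal; hence
κ₁ = 3b₁ − b₂ and κ₂ = 3b₂ − b₁ recover the principal curvatures, and on a
sphere κ = 2b₁ exactly. **Eigenvalue selection:** the near-zero "normal"
eigenvalue is identified as the one whose eigenvector is most parallel to
n̂_v, not by magnitude ordering — on saddles (torus inner rim: in-plane
eigenvalues 0.0292 and −0.0125 for κ₁ = 0.1, κ₂ = −1/15) the normal
eigenvalue lies *between* the in-plane ones and value-sorting would corrupt
both curvatures. |b₃| and the angle between its eigenvector and n̂_v are
reported per triangle as estimation diagnostics.

NVV replaces the arc curvature by the turning angle per geodesic length,
κᵢ = φᵢ/gᵢ, *unsigned* as in the original vertex-based formulation. This is
retained only as a documented negative result: without the arc sign the
tensor cannot produce negative κ₂, and the torus test shows NVV calling the
inner rim positive while RVV/AVV/SSVV recover the sign everywhere. (With
the arc sign attached, the turning-angle variant recovers signs too — the
failure is the unsigned vote, not the eigen-analysis.)

SSVV samples the surface instead of collecting neighbors: eight tangent
directions (π/4 apart; the first is the deterministic tangent-plane
projection of the global x-axis, y-axis fallback, so runs need no seed) of
length rh define points v_t; the line through v_t parallel to n̂_v is
intersected with the mesh (vectorized Möller–Trumbore over line parameters,
nearest hit with |offset| ≤ 2rh, own triangle excluded), and each hit
contributes the curvature of the osculating circle through v tangent to tᵢ:
κᵢ = 2h/(rh² + h²) with h the signed offset along the normal. On a sphere
h = r − √(r²−rh²) gives κᵢ = 1/r exactly, which justifies the construction.
B_v = (1/8)Σκᵢtᵢtᵢᵀ over found hits; triangles with fewer than three hits
are flagged (rank-deficient tensor) — the mechanism behind SSVV's collapse
once rh reaches the feature radius, when the sample lines graze the surface.

Flagged triangles (empty neighborhood, failed sampling) carry NaN
attributes; evaluation charges them the maximum error so that algorithm
failures lower accuracy scores instead of disappearing.

## Benchmark surfaces

All benchmarks carry analytic per-triangle ground truth (κ₁ ≥ κ₂, inward
normals), are deterministic given parameters (and a seed where noise is
involved), and are validated against an independent finite-difference
shape-operator oracle in the tests.

* **Noisy plane** — regular grid triangulation (default 73×73 vertices at
  unit spacing, > 10⁴ triangles), each vertex displaced along the plane
  normal by N(0, (f·ē)²) with f the noise fraction and ē the mean edge
  length. The stated noise scale is interpreted as a standard deviation
  (the common reading of a percentage noise level); truth κ = 0.
* **Quantization-noise sphere** — ball of radius 10 voxelized in 25³
  (voxel centers with distance ≤ r) and converted to its *exact voxel-
  boundary surface*: the axis-aligned faces between foreground and
  background voxels, two triangles each. Binary labels carry no sub-voxel
  information, so this staircase is the surface a binary mask actually
  defines; interpolating Marching Cubes at 0.5 through a {0,1} volume
  instead manufactures half-voxel precision and roughly quarters the
  quantization noise, which would misrepresent the regime this benchmark
  exists to probe. Known consequence: all staircase triangles have equal
  area, so area weighting is a no-op here and AVV coincides with RVV on
  this one benchmark.
* **Smooth sphere** — ball mask smoothed with a 3D Gaussian (σ = 3.3
  voxels), then isosurfaced. Diffusion shifts the half-maximum level
  surface inward by ≈ σ²/r, which would corrupt the 1/r truth; the
  isosurface level is therefore chosen as the spherically averaged field
  value at distance r from the center (computed on golden-spiral
  directions), placing the surface at radius r by construction (measured
  mean vertex radius 10.01 for r = 10). The non-uniform Marching-Cubes
  tessellation is the point of this benchmark — it is what separates AVV
  from RVV.
* **Torus** (ring radius 25, tube radius 10) and **open cylinder**
  (r = 10, h = 25), regular parametric triangulations with ~1-voxel edges
  by default (tests use 2-voxel edges for speed; the qualitative results
  are resolution-stable). Torus truth: κ₁ = 1/csr, κ₂ = cos ψ/(rr+csr·cos ψ).
  Cylinder truth: κ₁ = 1/r, κ₂ = 0, axis-aligned t₂; its two end rings are
  the border-filtering test bed.

## Evaluation protocol

Vector error 1 − |v̂_t·v̂_e| (orientation-invariant, 1 = perpendicular);
scalar relative error |κ_t−κ_e|/|κ_t|, replaced by the absolute error |κ_e|
exactly where the truth is zero (plane, cylinder κ₂). Accuracy over a
surface is the normalized area under the cumulative relative-frequency
histogram of the errors — 20 equal-width bins on [0, 1] with clipping; the
exact bin convention shifts absolute AUC values by a few points, which is
why cross-implementation comparisons of these scores carry percentage-point
slack. `run_benchmark_table` estimates on the full surface and excludes
border-near triangles (geodesic distance ≤ the exclusion depth) from the
statistics only; a run whose every retained triangle is flagged is reported
as 0 with a `failed` flag.

## Problem sizes and runtime choices

Benchmark meshes are a few thousand triangles (quantization sphere 3 804,
smooth sphere ~3 750, cylinder 3 150, plane ~10⁴) — the scale at which every
(algorithm, rh) run completes in seconds on one CPU. Geodesic neighborhoods
are computed by chunked multi-source Dijkstra and shared between the normal
and curvature passes and across rh values (a neighborhood at smaller rh is a
filtered copy of the largest one). Per-center vote collection is fully
vectorized; SSVV line casting is batched across all centers.

## Known limitations

* Graph geodesics overestimate true surface geodesics by the mesh detour
  factor; all weights inherit this bias consistently, so it largely cancels
  between numerator and normalization.
* Accuracy scores on quantization-noise surfaces depend visibly on the
  surface-extraction dialect (staircase vs. interpolated isosurface vs.
  point-cloud reconstruction); the staircase used here brackets the noisiest
  end. Equal triangle areas on the staircase make AVV ≡ RVV there.
* RVV's equal-weight votes leave a κ₁/κ₂ eigenvalue split of several
  percent under anisotropic tessellation even on analytic spheres; AVV
  suppresses this by an order of magnitude (the reason it is the default).
* SSVV assumes the surface is closed enough for its sample lines to hit it;
  on complex or strongly curved-beyond-rh surfaces it underestimates
  curvature or fails (flagged triangles).
* Border filtering needs a connected graph neighborhood; curvature values
  within ~rh of an unfiltered border should not be trusted.
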