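# Methods

This note documents the models, numerical choices and limitations behind
`laminaflat`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## Coordinate conventions

All voxel grids are indexed `[i, j, k]`; the world coordinate of a voxel
center is `origin + (index + 0.5) * voxel_size` (μm), and every field —
depth, orientation, flat coordinates — is a sample at voxel centers. This
single convention is used by the segment search, the ray marcher, the level
set, the streamline integrator and the mesh, which removes the usual class
of half-voxel inconsistencies. Flat space uses half-open `[0, 1)` binning;
the value 1.0 is clamped into the last bin. Invalid values are NaN.

A consequence worth spelling out: relative depth is 0/1 at the top/bottom
shell voxel *centers*, not at the outer faces. On a slab of `nz` planes the
depth of plane `k` is `k/(nz-1)`; on a spherical shell with nominal voxel
radii `a < b` the matching closed-form harmonic depth has its Dirichlet
spheres at the center radii `a + 1/2` and `b - 1/2`. The synthetic fixtures
encode their analytic ground truth in this convention.

## Principal-axis fields

**Segment route.** Top→nearest-bottom and bottom→nearest-top voxel-center
segments are found with a k-d tree; ties are broken by lowest linear voxel
index for determinism. Per voxel, the `n_segments` nearest segments (true
point-to-segment distance, computed exactly on a midpoint-tree candidate
set; point-to-midpoint is available as a cheaper documented option) are
averaged: orientation is the normalized mean direction signed toward the
bottom shell, thickness the mean length. Depth is the distance from the
voxel center to the top shell along −O̅, obtained by ray marching with step
0.25·voxel and refining the mask-exit point by bisection, minus half a
voxel (exit face → shell-center plane), divided by the local thickness and
clamped to [0, 1]. Rays that exit through a side are flagged and filled
from the nearest resolved voxel. `n_segments` has no universal default — it
sets the spatial smoothing scale and must be chosen for the voxel
resolution and geometry, so the API requires it explicitly.

**Laplace route.** The 6-neighbor graph Laplacian over the source volume
with d = 0 on the top shell, d = 1 on the bottom shell and natural (zero
normal flux) boundaries elsewhere is solved directly (sparse LU) up to
60k unknowns and by Jacobi-preconditioned conjugate gradients (relative
tolerance 1e-8) beyond. Components touching neither shell make the problem
ill-posed and raise an error listing them. Orientation is the normalized
central-difference gradient of the solution after continuing it one voxel
outward by nearest-neighbor values, which suppresses one-sided-difference
artifacts at the boundary; voxels whose 26-neighborhood is not fully
covered by the continued field are marked invalid.

On the octant-shell fixture (20 voxels across the shell) the solved depth
matches the closed form `(1/a − 1/r)/(1/a − 1/b)` (center radii) within
0.02 on interior voxels, and the gradient orientation is within 1° of
radial on interior voxels at least two voxels from the boundary; directly
at the jagged Dirichlet staircase both quantities are dominated by the
half-voxel geometry of the shells themselves, which is why summaries are
taken over interior voxels — the same reason smoothness statistics
(Laplacian of d, divergence of O̅) exclude boundary voxels.

## Flatmapping

**Level set and mesh.** Voxels below `d*` that 6-touch a deeper in-volume
voxel form the level-set cloud; all but its largest 26-connected component
are dropped (count reported). Reconstruction projects the cloud on its two
leading principal axes, Delaunay-triangulates there, and removes triangles
whose *projected* edge exceeds 2.6× the median projected nearest-neighbor
spacing (removing hull slivers without destroying steep regions). This
reconstructor meets the pipeline's contract — the mesh contains the input
points, has one component and one boundary loop — and is deliberately a
pluggable step: any reconstructor with the same contract can replace it.
It assumes the surface is injective under the PCA projection, i.e. caps up
to a hemisphere; strongly folded cortices would need a different
reconstructor. Refinement is plain 1→4 midpoint subdivision (parent
vertices keep their indices), iterated until the vertex count reaches the
source-volume voxel count or a pass limit.

**Authalic flattening.** The boundary loop is pinned to a user-chosen
convex border polygon: corners map to anchor vertices and intermediate
vertices are placed by cumulative 3D arc length. Anchors come from an
explicit list, from the first-vertex-shift rule (the default), or from
`anchors="auto"`, which picks the sharpest boundary turning angles — on
box-like geometries the shift rule wraps geometric corners onto border-edge
midpoints and costs ~20% area distortion that has nothing to do with the
solver, so the tests use auto anchors there. The interior solves the
discrete authalic system (weights `(cot γ + cot δ)/‖x_i − x_j‖²` with the
angles adjacent to the edge at its far vertex); the weights reproduce
planar meshes to machine precision, which the suite checks. The iterative
mode then minimizes Σ_t (a_t − Â_t)²/Â_t over interior vertices (Â_t the
rescaled 3D triangle areas) with L-BFGS and analytic gradients; on the
octant cap it reduces mean relative area-fraction distortion from ~8% to
~0.3%. Inverted (negative-area) triangles are counted and warned about
above 0.1%; they are not an error because boundary-dominated meshes can
carry a few benign folds near the border.

**Streamlines and eligibility.** Depth and orientation are trilinearly
interpolated (orientation renormalized; zero blends fall back to the
nearest voxel); outside the valid region both fields are continued by
nearest neighbor so boundary blends are not dragged toward fill values.
Integration is fixed-step RK2 with step 0.25·voxel; forward is the
direction of O̅ (increasing depth). A voxel is eligible when the forward
pass reaches depth 1 − ε₁ and the backward pass reaches ε₀ inside the
volume. The default ε₀ = ε₁ = 0.01 suits slab-like fields; on the shell
fixture the depth gradient at the inner shell is ~0.05 per voxel, so the
half-voxel staircase makes 0.05 the resolution-appropriate tolerance — with
it the shell coverage is 1.000 and the projected points still sit within
0.01 voxel of the closed-form level radius. Projection roots of
d(S(t)) = d* are bracketed during integration and refined by bisection
(40 iterations); if a noisy field produces several sign changes, the root
nearest the seed in arc length is taken to preserve locality.

**Composition and discretization.** Nearest-vertex lookup uses a k-d tree
with a lowest-index tie rule, checked exactly against brute force. The
median nearest-vertex distance is reported and a warning is raised at half
a voxel or more — note that a perfectly regular slab already sits at this
threshold, because the level-set plane is the voxel plane *below* d\*.
Pixelization is `floor(coord · N)` with 1.0 clamped; preimage tables are
grouped once (sort + offsets) so lookups are O(answer). Mirroring uses
x ↦ 2 − x so the two hemisphere maps share the x = 1 edge continuously.
Flat views aggregate preimage values by mode (ties → smallest label), mean
or max.

## Metrics

Uniformity normalizes preimage size by `eligible / nonempty-pixel count`,
i.e. by the *used* flat area; with unused border pixels excluded the mean
over nonempty pixels is exactly 100%, so the informative quantity is the
spread. Conicity fits a least-squares slope to the 10-bin depth histogram
of a preimage (bins the local column spans), reported both raw (voxels per
unit depth) and normalized by the mean bin count. Connectedness uses
26-connectivity on the preimage's bounding box; continuity is the worst
combined-preimage connectedness over the four 4-neighbor pixel pairs.

The preimage radius fits the radial-distance histogram (√n bins, density
normalized) around the first principal component with the truncated-square-
pyramid radial density: for half-width a the circle-in-square arc length is
2πr for r ≤ a and r(2π − 8 arccos(a/r)) for a < r ≤ a√2, integrated over a
linear half-width profile a(z) from r0 to r1 and normalized. The density
only depends on the *distribution* of half-widths, so (r0, r1) and
(r1, r0) are exchangeable — harmless, since the radius is (r0 + r1)/2. The
formula is validated against Monte-Carlo samples before use (max deviation
< 5% of the density peak), and the fit recovers prism half-widths to ~0.1%
and truncated-pyramid (2 and 4 voxels) mean radius to ~0.3% on dense
samples; preimages under 4 voxels or collinear fall back to half a voxel,
flagged. Distance calibration is the ordinary least-squares slope of mean
fitted radius (μm) against pixel size (flat units), requiring at least
three resolutions; on a 1000 μm cube it yields ~514 μm per flat unit
against the geometric 500 (the residual reflects pixel/voxel lattice
mismatch at coarse resolutions). Area calibration multiplies flat area
fractions by the projection-mesh area.

## Applications

Decomposition assigns eligible voxels to square or hexagonal tiling cells
(cells validated pairwise interior-disjoint; shared edges resolve to the
first cell). Barrel refinement reassigns each labeled voxel to the label of
its nearest flat-space neighbor *at strictly positive distance*, iterated
to a fixed point — voxels of one column share identical flat coordinates
and carry no lateral information, so zero-distance neighbors are excluded.
Columns are preimages of the convex hulls of each barrel's flat positions;
flat points claimed by several hulls are resolved to the nearest barrel
cloud *before* preimaging, making columns disjoint by construction. Barrel
metrics: volumes from voxel counts, surface area from hull flat area ×
mesh area, ellipticity as the covariance-ellipse axis ratio (level-
invariant), conicity as above, curvature as the displacement between the
centroid-seeded central streamline and its least-squares line at the
column ends, and layer-border depths as mean absolute depth (d·D̄) of
voxels of each layer 6-adjacent to the next.

Curvature deliberately measures displacement from a *fitted* line, so a
bend spread over much of the column is partly absorbed by the fit
(leverage); the bent-column fixture therefore localizes its known offset
in a plateau-plus-ramp profile near the top, where the recovered value is
within a voxel of the constructed offset.

## Synthetic fixtures: what they do and do not show

The fixtures (slab, cube, layered slab, octant spherical shell, bent
column) have closed-form depth, thickness and orientation, so every stage
can be checked against exact geometry; the shell is an octant so the level
surface has a single boundary loop, and the slab's default `nz` makes
depth dyadic so second differences vanish exactly in floating point. Label
jitter (seeded) flips shell labels for robustness tests. What they lack:
anisotropic voxel sizes in anger, annotation noise at real-atlas scale,
regions where top and bottom shell areas differ several-fold (the
"hotspot" regime), and non-injective, strongly folded surfaces. Passing
tests therefore demonstrate correctness of the machinery and its
convergence on smooth geometry, not robustness to every artifact of a real
atlas; on real data the metric suite is the instrument for judging a
specific flatmap.

## Problem sizes

The suite and the acceptance script use a 16×16×17 slab, a 40³ cube, an
octant shell of outer radius 40 voxels (~29k source voxels, 20 voxels
across the shell) and a 121-plane bent column — sizes chosen so each
scenario still resolves the quantity it checks (e.g. ≥20 voxels across the
shell for the harmonic comparison, 4 calibration resolutions dividing the
cube lattice) while the whole run stays in the tens of seconds on one CPU.
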