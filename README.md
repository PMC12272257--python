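# laminaflat

Laminar coordinate systems and area-preserving flatmaps for voxelized brain
atlases.

Layered brain regions such as the neocortex are poorly served by the
Cartesian axes of a digital atlas: the direction in which layers succeed one
another (the *principal axis*) curves through space. `laminaflat` enhances a
region-annotated voxel atlas with a laminar coordinate system — per-voxel
relative depth *d* ∈ [0, 1], local thickness *D̄* (μm) and a unit
orientation vector *O̅* along the principal axis — and derives a *flatmap*:
a mapping ℳ from voxel centers to 2D coordinates in the unit square whose
two axes are locally orthogonal to the principal axis. The set of voxels
mapping to a flat point or pixel is its *preimage* ℳ⁻¹; because each voxel
has a single flat location, preimages of disjoint flat shapes are disjoint,
which enables clean volume decomposition into cortical-column-like
subvolumes and, as a concrete application, nonoverlapping barrel-column
annotations in barrel cortex. The intended users are neuroanatomists and
data-driven modelers working with atlas-registered volumetric data.

## Method

Given painted *top* and *bottom* shells (one-voxel-thick boundary layers,
e.g. pia and white-matter boundary):

1. **Principal axis.** Either join every top-shell voxel to its nearest
   bottom-shell voxel (and vice versa) and average the *N* nearest segments
   per voxel — *O̅* is the mean direction (signed toward the bottom), *D̄*
   the mean length, and *d = y/D̄* with *y* the ray-marched distance to the
   top shell along −*O̅* — or solve the Laplace equation (hot top, cold
   bottom, adiabatic sides) and take the solution as *d* and its normalized
   gradient as *O̅*.
2. **Projection mesh (stage I).** Extract the level set of *d* at a chosen
   depth *d\**, triangulate the voxel-center cloud into an open surface
   mesh, refine by midpoint subdivision, and flatten it onto a convex
   border with an authalic (area-preserving) parameterization ℱ — a direct
   discrete-authalic solve, optionally polished by an iterative
   area-equalizing optimization.
3. **Voxel projection (stage II).** Integrate a streamline through the
   trilinearly interpolated orientation field from every voxel center
   (fixed-step RK2), forward to relative depth 1 and backward to 0 within
   tolerances; voxels whose streamline leaves the volume early are not
   *eligible*. Root-find d(S(t)) = *d\** to project each center onto the
   level surface (operator S).
4. **Flatmap (stage III).** Snap each projection to the nearest mesh vertex
   (operator N) and compose ℳ = ℱ∘N∘S. Discretize flat space into N×N
   pixels, build preimage tables, optionally mirror to two hemispheres
   (x ↦ 2 − x).

A metric suite quantifies quality: coverage (fraction of eligible voxels),
usage fraction (nonempty pixels), orthogonality (cosine between
∇x_flat × ∇y_flat and *O̅*), smoothness (Laplacian of *d*, divergence of
*O̅*), and per-pixel preimage size, uniformity, connectedness, continuity,
conicity and radius (fitted with the truncated-square-pyramid radial
density). A linear fit of mean preimage radius against pixel size converts
flat distances to μm; the projection-mesh area converts flat areas to mm².

## Worked example

Flatten one octant of a spherical shell (inner radius 20, outer radius 40
voxels at 25 μm — a curved "cortex" with exactly known geometry):

```python
import numpy as np
import laminaflat as lf
from laminaflat.meshing import BorderSpec

fx = lf.make_fixture(lf.FixtureSpec(kind="spherical_shell",
                                    inner_radius=20, outer_radius=40,
                                    voxel_size=25.0))
res = lf.make_flatmap(fx.depth, fx.orientation, mask=fx.mask, d_star=0.5,
                      border=BorderSpec(polygon=np.array([[0, 0], [1, 0],
                                                          [0.5, 3**0.5 / 2]]),
                                        anchors="auto"),
                      eps0=0.05, eps1=0.05)
fm = res.flatmap
print(f"source volume: {fx.mask.sum()} voxels")
print(f"projection mesh: {len(res.mesh.vertices)} vertices, "
      f"area {fm.mesh_area:.4f} mm^2")
print(f"coverage: {lf.coverage(fm, fx.mask):.4f}")
ortho = lf.orthogonality(fm, fx.orientation)
print(f"orthogonality median: {np.nanmedian(ortho):.4f}")
grid = lf.discretize(fm, 16)
print(f"usage fraction at 16x16: {lf.usage_fraction(grid):.3f}")
ppm = lf.per_pixel_metrics(grid, fx.depth)
ok = np.isfinite(ppm.connectedness)
print(f"median preimage connectedness: {np.median(ppm.connectedness[ok]):.3f}")
```

prints

```
source volume: 29318 voxels
projection mesh: 56413 vertices, area 0.7218 mm^2
coverage: 0.9999
orthogonality median: 0.9961
usage fraction at 16x16: 0.516
median preimage connectedness: 1.000
```

Coverage ≈ 1 means essentially every voxel's streamline spans the full
depth range; orthogonality ≈ 1 means the flat axes are locally orthogonal
to the principal axis; connectedness 1 means each pixel's preimage is one
solid radial chunk. The mesh area (0.722 mm²) is the flat-space area
calibration factor: a region covering a fraction *f* of flat space occupies
*f* × 0.722 mm² of the projection surface.

The same stages are exposed on the command line (`laminaflat fixture`,
`fields`, `laplace`, `flatmap`, `metrics`, `flatview`, `decompose`,
`barrels`); real atlases are read from NRRD or NIfTI with their voxel size
in μm.

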