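"""Synthetic atlases with analytically known laminar structure.

Every fixture returns a label volume, shell labels and closed-form depth /
orientation / thickness fields on the same grid, so the whole pipeline can be
exercised and checked against exact geometry without any external data.

Fixture kinds
-------------
slab
    An axis-aligned box; top shell at k=0, bottom at k=nz-1, lateral boundary
    voxels are sides. Depth is linear in k, orientation is +z, thickness is
    constant. The default nz is chosen so nz-1 is a power of two: depth values
    are then dyadic rationals and second differences of the analytic depth
    vanish exactly in floating point.
cube
    A slab with equal sides.
layered_slab
    A slab whose labels are stacked layer bands with prescribed relative
    thicknesses (L1..Ln from the top).
spherical_shell
    One octant of a spherical shell with inner radius a and outer radius b
    (in voxels). The planar faces are sides, so the level-set surface has a
    single boundary loop as the flattener requires. The analytic depth is the
    harmonic (Laplace) solution d(r) = (1/a - 1/r)/(1/a - 1/b) when the top
    shell is the inner surface, and its complement when the top is the outer
    surface; orientation is radial, signed toward the bottom shell.
bent_column
    A slab in which every z-layer is shifted laterally by a profile that is
    zero over most of the depth and ramps sharply to a known offset ``delta``
    at the top — a column whose central streamline deviates from a straight
    line by delta at its top end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import BOTTOM, EXTERIOR, INTERIOR, SIDE, TOP, Volume


@dataclass
class FixtureSpec:
    kind: str = "slab"
    shape: tuple[int, int, int] = (16, 16, 17)
    voxel_size: float = 50.0                 # μm
    layer_fractions: tuple = (0.1, 0.2, 0.2, 0.2, 0.2, 0.1)
    inner_radius: int = 20                   # voxels, spherical_shell
    outer_radius: int = 40                   # voxels, spherical_shell
    top_surface: str = "inner"               # spherical_shell: {"inner","outer"}
    bend_offset: float = 0.0                 # μm, bent_column
    bend_fraction: float = 0.02              # fraction of depth over which it bends
    column_halfwidth: int = 4                # voxels, bent_column
    noise: float = 0.0                       # probability of shell-label jitter
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("slab", "cube", "layered_slab", "spherical_shell",
                             "bent_column"):
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.kind != "spherical_shell" and min(self.shape) < 4:
            raise ValueError("fixture dimensions must be >= 4 voxels per axis")
        if abs(sum(self.layer_fractions) - 1.0) > 1e-9:
            raise ValueError("layer fractions must sum to 1")
        if self.kind == "spherical_shell" and not (
                0 < self.inner_radius < self.outer_radius):
            raise ValueError("need 0 < inner_radius < outer_radius")
        if self.top_surface not in ("inner", "outer"):
            raise ValueError("top_surface must be 'inner' or 'outer'")


@dataclass
class Fixture:
    spec: FixtureSpec
    annotation: Volume       # integer labels, 0 = outside
    shells: Volume           # EXTERIOR/INTERIOR/TOP/BOTTOM/SIDE
    depth: Volume            # analytic relative depth, NaN outside
    orientation: Volume      # analytic unit vectors (nx,ny,nz,3), NaN outside
    thickness: Volume        # analytic local thickness μm, NaN outside
    meta: dict = field(default_factory=dict)

    @property
    def mask(self) -> np.ndarray:
        return self.annotation.data > 0


def _classify_box_shells(mask: np.ndarray, top_k: int, bottom_k: int) -> np.ndarray:
    """Shell labels for a box-like mask: top/bottom by k-plane, remaining
    boundary voxels are sides."""
    from .fields import extract_boundary_candidates

    boundary = extract_boundary_candidates(mask)
    shells = np.where(mask, INTERIOR, EXTERIOR).astype(np.uint8)
    shells[boundary] = SIDE
    top = np.zeros_like(mask)
    top[:, :, top_k] = True
    bot = np.zeros_like(mask)
    bot[:, :, bottom_k] = True
    shells[boundary & top] = TOP
    shells[boundary & bot] = BOTTOM
    return shells


def _apply_jitter(shells: np.ndarray, noise: float, rng: np.random.Generator):
    """Flip boundary voxel labels among {top, bottom, side} with prob. noise."""
    if noise <= 0:
        return shells
    boundary = np.isin(shells, (TOP, BOTTOM, SIDE))
    idx = np.argwhere(boundary)
    flip = rng.random(len(idx)) < noise
    for i, j, k in idx[flip]:
        choices = [c for c in (TOP, BOTTOM, SIDE) if c != shells[i, j, k]]
        shells[i, j, k] = rng.choice(choices)
    return shells


def _make_slab(spec: FixtureSpec, labels: np.ndarray | None = None) -> Fixture:
    nx, ny, nz = spec.shape
    h = float(spec.voxel_size)
    mask = np.ones(spec.shape, dtype=bool)
    ann = labels if labels is not None else np.ones(spec.shape, dtype=np.int32)
    shells = _classify_box_shells(mask, 0, nz - 1)
    rng = np.random.default_rng(spec.seed)
    shells = _apply_jitter(shells, spec.noise, rng)

    k = np.arange(nz, dtype=float)
    depth = np.broadcast_to(k / (nz - 1), spec.shape).copy()
    orient = np.zeros(spec.shape + (3,))
    orient[..., 2] = 1.0
    thick = np.full(spec.shape, (nz - 1) * h)

    vol = Volume(ann, h)
    return Fixture(
        spec=spec,
        annotation=vol,
        shells=vol.like(shells),
        depth=vol.like(depth),
        orientation=vol.like(orient),
        thickness=vol.like(thick),
        meta={"height_um": (nz - 1) * h, "side_um": nx * h},
    )


def _make_layered_slab(spec: FixtureSpec) -> Fixture:
    nx, ny, nz = spec.shape
    k = np.arange(nz, dtype=float)
    d = k / (nz - 1)
    edges = np.cumsum((0.0,) + tuple(spec.layer_fractions))
    # label 1..n from the top; depth exactly at an edge goes to the deeper layer
    layer_of_k = np.searchsorted(edges[1:-1], d, side="right") + 1
    labels = np.broadcast_to(
        layer_of_k.astype(np.int32), spec.shape
    ).copy()
    fx = _make_slab(spec, labels=labels)
    fx.meta["layer_edges"] = edges
    return fx


def _make_spherical_shell(spec: FixtureSpec) -> Fixture:
    a, b = float(spec.inner_radius), float(spec.outer_radius)
    h = float(spec.voxel_size)
    n = int(np.ceil(b)) + 1
    shape = (n, n, n)
    idx = np.indices(shape, dtype=float)
    centers = (idx + 0.5)  # in voxel units; sphere centered at grid origin
    r = np.sqrt(np.sum(centers**2, axis=0))
    mask = (r >= a) & (r <= b)
    ann = np.where(mask, 1, 0).astype(np.int32)

    shells = np.where(mask, INTERIOR, EXTERIOR).astype(np.uint8)
    # classify boundary voxels by which kind of exterior their 6-neighbors touch
    inner_ext = np.zeros(shape, dtype=bool)
    outer_ext = np.zeros(shape, dtype=bool)
    plane_ext = np.zeros(shape, dtype=bool)
    ext = ~mask
    for axis in range(3):
        for shift in (-1, 1):
            sl = [slice(None)] * 3
            sl[axis] = slice(0, 1) if shift == 1 else slice(n - 1, n)
            nb_ext = np.roll(ext, shift, axis=axis)
            nb_ext[tuple(sl)] = True
            nb_r = np.roll(r, shift, axis=axis)
            nb_r[tuple(sl)] = np.nan  # off grid: planar face (or beyond outer)
            off_grid = np.zeros(shape, dtype=bool)
            off_grid[tuple(sl)] = True
            is_ext_nb = nb_ext & mask
            inner_ext |= is_ext_nb & ~off_grid & (nb_r < a)
            outer_ext |= is_ext_nb & ~off_grid & (nb_r > b)
            # off-grid low side = planar symmetry face; high side = outer space
            if shift == 1:  # neighbor at index-1 missing -> low face
                plane_ext |= mask & off_grid
            else:
                outer_ext |= mask & off_grid
    if spec.top_surface == "inner":
        shells[mask & inner_ext] = TOP
        shells[mask & outer_ext] = BOTTOM
    else:
        shells[mask & outer_ext] = TOP
        shells[mask & inner_ext] = BOTTOM
    shells[mask & plane_ext & ~(inner_ext | outer_ext)] = SIDE

    # 26-connected boundary voxels not caught by the 6-neighbor scan are sides
    from .fields import extract_boundary_candidates

    boundary = extract_boundary_candidates(mask)
    leftover = boundary & (shells == INTERIOR)
    shells[leftover] = SIDE

    # Dirichlet conditions act at shell voxel CENTERS (cf. the slab, whose
    # depth is 0/1 at the top/bottom center planes): the matching closed-form
    # harmonic solution has its boundary spheres at the center radii.
    a_c, b_c = a + 0.5, b - 0.5
    harmonic = shell_harmonic_depth(np.clip(r, a_c, b_c), a_c, b_c)
    if spec.top_surface == "inner":
        depth = harmonic
        sign = 1.0
    else:
        depth = 1.0 - harmonic
        sign = -1.0
    depth = np.where(mask, np.clip(depth, 0.0, 1.0), np.nan)

    orient = np.where(
        mask[..., None], sign * np.moveaxis(centers, 0, -1) / r[..., None], np.nan
    )
    thick = np.where(mask, (b_c - a_c) * h, np.nan)

    vol = Volume(ann, h)
    return Fixture(
        spec=spec,
        annotation=vol,
        shells=vol.like(shells),
        depth=vol.like(depth),
        orientation=vol.like(orient),
        thickness=vol.like(thick),
        meta={"a_um": a * h, "b_um": b * h, "a_vox": a, "b_vox": b,
              "a_center_vox": a_c, "b_center_vox": b_c},
    )


def _make_bent_column(spec: FixtureSpec) -> Fixture:
    nx, ny, nz = spec.shape
    h = float(spec.voxel_size)
    w = spec.column_halfwidth
    cx, cy = nx / 2.0, ny / 2.0
    k = np.arange(nz, dtype=float)
    d = k / (nz - 1)
    # lateral shift (in voxels): full bend_offset on a plateau near the top
    # (so the offset survives the streamline's depth-tolerance cutoff), a
    # localized linear ramp below it, zero over most of the depth — the
    # offset is then read off directly as endpoint displacement from a
    # straight line fitted to the centerline
    p = spec.bend_fraction               # plateau end (relative depth)
    ramp_w = 1.5 * spec.bend_fraction    # ramp width
    ramp = np.clip(1.0 - (d - p) / ramp_w, 0.0, 1.0)
    shift = (spec.bend_offset / h) * ramp

    mask = np.zeros(spec.shape, dtype=bool)
    ii = np.arange(nx)[:, None] + 0.5
    jj = np.arange(ny)[None, :] + 0.5
    for kk in range(nz):
        mask[:, :, kk] = (np.abs(ii - cx - shift[kk]) <= w) & (np.abs(jj - cy) <= w)
    ann = np.where(mask, 1, 0).astype(np.int32)

    from .fields import extract_boundary_candidates

    boundary = extract_boundary_candidates(mask)
    shells = np.where(mask, INTERIOR, EXTERIOR).astype(np.uint8)
    shells[boundary] = SIDE
    top = np.zeros_like(mask)
    top[:, :, 0] = True
    bot = np.zeros_like(mask)
    bot[:, :, nz - 1] = True
    shells[boundary & top & mask] = TOP
    shells[boundary & bot & mask] = BOTTOM

    depth = np.where(mask, np.broadcast_to(d, spec.shape), np.nan)
    # orientation follows the column axis: dz = 1, dx = d(shift)/dk
    # toward the bottom (increasing k) the column center moves by dshift per k
    dshift = np.gradient(shift)
    orient = np.full(spec.shape + (3,), np.nan)
    vec = np.stack([dshift, np.zeros(nz), np.ones(nz)], axis=-1)
    vec /= np.linalg.norm(vec, axis=1, keepdims=True)
    orient[mask] = np.broadcast_to(vec, spec.shape + (3,))[mask]
    thick = np.where(mask, (nz - 1) * h, np.nan)

    vol = Volume(ann, h)
    return Fixture(
        spec=spec,
        annotation=vol,
        shells=vol.like(shells),
        depth=vol.like(depth),
        orientation=vol.like(orient),
        thickness=vol.like(thick),
        meta={"shift_voxels": shift, "delta_um": spec.bend_offset},
    )


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Build the fixture described by ``spec`` (deterministic given its seed)."""
    if spec.kind == "slab":
        return _make_slab(spec)
    if spec.kind == "cube":
        s = max(spec.shape)
        cubic = FixtureSpec(**{**spec.__dict__, "kind": "slab",
                               "shape": (s, s, s)})
        fx = _make_slab(cubic)
        fx.spec = spec
        return fx
    if spec.kind == "layered_slab":
        return _make_layered_slab(spec)
    if spec.kind == "spherical_shell":
        return _make_spherical_shell(spec)
    if spec.kind == "bent_column":
        return _make_bent_column(spec)
    raise ValueError(spec.kind)


def shell_harmonic_depth(r, a, b):
    """Closed-form harmonic depth between spheres: 0 at r=a, 1 at r=b."""
    return (1.0 / a - 1.0 / r) / (1.0 / a - 1.0 / b)
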