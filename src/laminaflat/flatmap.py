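"""Stage III: composition of the flatmap operator ℳ = ℱ∘N∘S, flat-space
discretization, preimages, hemisphere mirroring, flat views and flat point
projection."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .io import Flatmap, Volume
from .meshing import FlatMesh, SurfaceMesh
from .streamlines import ProjectionResult


def nearest_vertex(points: np.ndarray, mesh: SurfaceMesh,
                   tie_k: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Exact nearest mesh vertex per query point (operator N).

    Returns (vertex indices, distances); the distance is the local
    mesh-approximation error. Ties are broken by lowest vertex index (the
    tree result is cross-checked against the ``tie_k`` nearest candidates).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(mesh.vertices) == 0:
        raise ValueError("mesh has no vertices")
    tree = cKDTree(mesh.vertices)
    k = min(tie_k, len(mesh.vertices))
    dist, idx = tree.query(points, k=k)
    if k == 1:
        return np.atleast_1d(idx), np.atleast_1d(dist)
    dist = np.atleast_2d(dist)
    idx = np.atleast_2d(idx)
    best = dist[:, :1]
    tied = dist <= best + 1e-9 * np.maximum(best, 1.0)
    pick = np.where(tied, idx, np.iinfo(np.int64).max).min(axis=1)
    return pick, best[:, 0]


def build_flatmap(projections: ProjectionResult, mesh: SurfaceMesh,
                  flat: FlatMesh, d_star: float,
                  voxel_size, origin) -> Flatmap:
    """Map every eligible voxel to the flat image of the mesh vertex nearest
    to its surface projection; ineligible voxels get invalid coordinates."""
    if len(flat.vertices2d) != len(mesh.vertices):
        raise ValueError("mesh and flat mesh vertex counts differ "
                         f"({len(mesh.vertices)} vs {len(flat.vertices2d)})")
    elig = projections.eligible
    pts = projections.points[elig]
    coords = np.full(elig.shape + (2,), np.nan)
    if len(pts):
        vidx, dist = nearest_vertex(pts, mesh)
        coords[elig] = flat.vertices2d[vidx]
        half_voxel = 0.5 * float(np.min(np.broadcast_to(voxel_size, (3,))))
        med = float(np.median(dist))
        if med >= half_voxel:
            warnings.warn(
                f"median nearest-vertex distance {med:.1f} μm is at least "
                f"half the voxel size; the projection mesh under-resolves "
                f"the surface (check d*, reconstruction, refinement)")
    fm = Flatmap(
        coords=np.clip(coords, 0.0, 1.0),
        voxel_size=voxel_size,
        origin=origin,
        d_star=d_star,
        mesh_area=mesh.area_mm2,
    )
    return fm


@dataclass
class PixelGrid:
    """Regular N×N discretization of flat space with the preimage table ℳ⁻¹.

    ``assignment`` holds per-voxel linear pixel ids (-1 where not eligible);
    preimages are grouped once into (order, starts) so ``preimage`` lookups
    are O(size of answer).
    """

    resolution: int
    shape: tuple[int, int, int]
    assignment: np.ndarray        # (nx, ny, nz) int64 pixel id, -1 invalid
    x_range: tuple[float, float] = (0.0, 1.0)
    y_range: tuple[float, float] = (0.0, 1.0)
    _order: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    _starts: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))

    @property
    def n_pixels_x(self) -> int:
        span = self.x_range[1] - self.x_range[0]
        return int(round(self.resolution * span))

    @property
    def n_pixels(self) -> int:
        return self.n_pixels_x * self.resolution

    def pixel_id(self, ij: np.ndarray) -> np.ndarray:
        ij = np.atleast_2d(ij)
        return ij[:, 0] * self.resolution + ij[:, 1]

    def preimage_by_id(self, pid: int) -> np.ndarray:
        """Linear voxel indices mapping to one pixel id."""
        return self._order[self._starts[pid]:self._starts[pid + 1]]

    def preimage(self, i: int, j: int) -> np.ndarray:
        return self.preimage_by_id(i * self.resolution + j)

    @property
    def sizes(self) -> np.ndarray:
        """Preimage voxel counts, shape (n_pixels_x, resolution)."""
        return np.diff(self._starts).reshape(self.n_pixels_x, self.resolution)

    @property
    def n_nonempty(self) -> int:
        return int((np.diff(self._starts) > 0).sum())

    @property
    def n_eligible(self) -> int:
        return len(self._order)


def discretize(fm: Flatmap, resolution: int) -> PixelGrid:
    """Bin flat coordinates into integer pixel indices: floor(coord · N),
    with the value at the top of the range clamped into the last bin."""
    if resolution < 1:
        raise ValueError("resolution must be >= 1")
    coords = fm.coords
    valid = fm.valid_mask
    xy = coords[valid]
    if xy.size and (
            xy[:, 0].min() < fm.x_range[0] - 1e-9
            or xy[:, 0].max() > fm.x_range[1] + 1e-9
            or xy[:, 1].min() < fm.y_range[0] - 1e-9
            or xy[:, 1].max() > fm.y_range[1] + 1e-9):
        raise ValueError("flat coordinates outside the declared flat range")
    N = resolution
    span_x = fm.x_range[1] - fm.x_range[0]
    nx_pix = int(round(N * span_x))
    ii = np.floor((xy[:, 0] - fm.x_range[0]) * N).astype(np.int64)
    jj = np.floor((xy[:, 1] - fm.y_range[0]) * N).astype(np.int64)
    ii = np.clip(ii, 0, nx_pix - 1)
    jj = np.clip(jj, 0, N - 1)
    pid = ii * N + jj

    assignment = np.full(fm.shape, -1, dtype=np.int64)
    assignment[valid] = pid
    lin = np.ravel_multi_index(np.argwhere(valid).T, fm.shape)
    order = lin[np.argsort(pid, kind="stable")]
    counts = np.bincount(pid, minlength=nx_pix * N)
    starts = np.concatenate([[0], np.cumsum(counts)])
    return PixelGrid(
        resolution=N, shape=fm.shape, assignment=assignment,
        x_range=fm.x_range, y_range=fm.y_range,
        _order=order, _starts=starts,
    )


def preimage(fm: Flatmap, region) -> np.ndarray:
    """Linear voxel indices whose flat coordinates fall in ``region``.

    ``region`` is either a set/list of (i, j) pixel pairs together with a
    PixelGrid, passed as ``(grid, pixels)``, or a 2D polygon (k, 2) tested at
    native resolution with the even-odd rule (matplotlib Path).
    """
    if isinstance(region, tuple) and isinstance(region[0], PixelGrid):
        grid, pixels = region
        ids = [grid.pixel_id(np.array([p]))[0] for p in pixels]
        if ids:
            return np.unique(np.concatenate(
                [grid.preimage_by_id(int(i)) for i in ids]))
        return np.empty(0, dtype=np.int64)
    poly = np.asarray(region, dtype=float)
    from matplotlib.path import Path

    valid = fm.valid_mask
    xy = fm.coords[valid]
    inside = Path(poly).contains_points(xy)
    lin = np.ravel_multi_index(np.argwhere(valid).T, fm.shape)
    return lin[inside]


def mirror_two_hemispheres(fm: Flatmap, axis: int = 0) -> Flatmap:
    """Extend a single-hemisphere flatmap to both hemispheres of a volume
    symmetric about the mid-plane of ``axis``.

    The hemisphere carrying valid coordinates keeps x in [0, 1]; each voxel
    of the other hemisphere takes the coordinates of its mirror voxel with
    x ↦ 2 − x (so the two maps share the x = 1 edge continuously); y is
    unchanged. Mirroring twice restores the original coordinates.
    """
    coords = fm.coords
    n = coords.shape[axis]
    mirrored = np.flip(coords, axis=axis)
    valid = fm.valid_mask
    out = coords.copy()
    fill = ~valid & np.flip(valid, axis=axis)
    out[fill] = mirrored[fill]
    out[fill, 0] = 2.0 - mirrored[fill][:, 0]
    return Flatmap(
        coords=out,
        voxel_size=fm.voxel_size,
        origin=fm.origin,
        d_star=fm.d_star,
        mesh_area=fm.mesh_area,
        distance_factor=fm.distance_factor,
        x_range=(0.0, 2.0),
        y_range=fm.y_range,
    )


_AGGREGATORS = ("mode", "mean", "max")


def flat_view(grid: PixelGrid, volume: Volume | np.ndarray,
              aggregator: str = "mode") -> np.ma.MaskedArray:
    """2D image: per pixel, the aggregate of the voxel values in its
    preimage; pixels with empty preimages are masked (no data).

    ``mode`` ties resolve to the smallest value (deterministic).
    """
    values = volume.data if isinstance(volume, Volume) else np.asarray(volume)
    if values.shape[:3] != grid.shape:
        raise ValueError("volume grid does not match the flatmap grid")
    if aggregator not in _AGGREGATORS:
        raise ValueError(f"unknown aggregator {aggregator!r}; "
                         f"use one of {_AGGREGATORS}")
    flat_vals = values.reshape(-1)
    nxp = grid.n_pixels_x
    N = grid.resolution
    img = np.ma.masked_all((nxp, N), dtype=float)
    starts = grid._starts
    order = grid._order
    sizes = np.diff(starts)
    if aggregator == "mean":
        sums = np.add.reduceat(
            flat_vals[order].astype(float), starts[:-1][sizes > 0])
        out = np.full(nxp * N, np.nan)
        out[sizes > 0] = sums / sizes[sizes > 0]
        img = np.ma.masked_invalid(out.reshape(nxp, N))
    elif aggregator == "max":
        maxs = np.maximum.reduceat(
            flat_vals[order].astype(float), starts[:-1][sizes > 0])
        out = np.full(nxp * N, np.nan)
        out[sizes > 0] = maxs
        img = np.ma.masked_invalid(out.reshape(nxp, N))
    else:  # mode
        out = np.full(nxp * N, np.nan)
        for pid in np.where(sizes > 0)[0]:
            vals = flat_vals[order[starts[pid]:starts[pid + 1]]]
            uniq, cnt = np.unique(vals, return_counts=True)
            out[pid] = uniq[np.argmax(cnt)]  # first max = smallest value
        img = np.ma.masked_invalid(out.reshape(nxp, N))
    return img


def flat_points(fm: Flatmap, points: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, int]:
    """Flat coordinates of 3D world points (e.g. soma/neurite positions).

    Each point takes the flat coordinates of its containing voxel; points in
    ineligible or outside voxels are dropped. Returns (flat xy of the kept
    points, boolean keep mask, number dropped).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    vol = fm.as_volume()
    idx = vol.index_of(pts)
    ok = vol.contains_index(idx)
    keep = ok.copy()
    xy = np.full((len(pts), 2), np.nan)
    sub = idx[ok]
    cc = fm.coords[sub[:, 0], sub[:, 1], sub[:, 2]]
    xy[ok] = cc
    keep[ok] &= ~np.isnan(cc).any(axis=1)
    return xy[keep], keep, int((~keep).sum())
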