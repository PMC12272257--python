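"""Quality metrics for depth/orientation fields and flatmaps, plus the
distance and area calibration of flat space.

Global: coverage, usage fraction. Per voxel: orthogonality of the flatmap
axes to the principal axis, Laplacian of depth and divergence of orientation
(smoothness). Per pixel: preimage size, size uniformity, connectedness,
continuity, conicity and radius. Calibration: μm-per-flat-unit from the
linear fit of mean preimage radius against pixel size, and mm² per unit flat
area from the projection-mesh area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, stats

from .io import BOTTOM, EXTERIOR, SIDE, TOP, Flatmap, Volume
from .flatmap import PixelGrid

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


# ---------------------------------------------------------------------------
# global metrics


def coverage(fm: Flatmap, mask: np.ndarray) -> float:
    """Fraction of source-volume voxels that are eligible (have a flat
    projection)."""
    total = int(np.asarray(mask, dtype=bool).sum())
    if total == 0:
        raise ValueError("empty source volume")
    return float((fm.valid_mask & mask).sum() / total)


def usage_fraction(grid: PixelGrid) -> float:
    """Fraction of pixels with a nonempty preimage."""
    return grid.n_nonempty / grid.n_pixels


def native_usage_fraction(vertex_ids: np.ndarray, n_vertices: int) -> float:
    """At native resolution: vertices with nonempty preimages / all vertices."""
    return len(np.unique(vertex_ids)) / n_vertices


# ---------------------------------------------------------------------------
# per-voxel metrics


def _masked_gradient(f: np.ndarray, mask: np.ndarray, spacing) -> np.ndarray:
    """Central differences with one-sided fallback where a neighbor is
    invalid; NaN where fewer than one valid neighbor exists on an axis."""
    out = np.full(f.shape + (3,), np.nan)
    spacing = np.broadcast_to(spacing, (3,))
    fv = np.where(mask, f, np.nan)
    for axis in range(3):
        plus = np.roll(fv, -1, axis=axis)
        minus = np.roll(fv, 1, axis=axis)
        sl = [slice(None)] * 3
        sl[axis] = slice(-1, None)
        plus[tuple(sl)] = np.nan
        sl[axis] = slice(0, 1)
        minus[tuple(sl)] = np.nan
        h = spacing[axis]
        central = (plus - minus) / (2 * h)
        fwd = (plus - fv) / h
        bwd = (fv - minus) / h
        g = np.where(np.isnan(central), np.where(np.isnan(fwd), bwd, fwd),
                     central)
        out[..., axis] = g
    return out


def orthogonality(fm: Flatmap, orientation: Volume) -> np.ndarray:
    """Cosine between (∇x_flat × ∇y_flat), sign chosen toward the bottom
    shell, and the orientation vector; NaN where gradients are undefined.

    The cross-product sense is fixed globally (majority vote over voxels); a
    per-voxel negative value then flags locally reversed flat axes.
    """
    valid = fm.valid_mask
    gx = _masked_gradient(fm.coords[..., 0], valid, fm.voxel_size)
    gy = _masked_gradient(fm.coords[..., 1], valid, fm.voxel_size)
    cr = np.cross(gx, gy)
    nrm = np.linalg.norm(cr, axis=-1)
    o = orientation.data
    o_ok = ~np.isnan(o).any(axis=-1)
    ok = valid & o_ok & (nrm > 1e-30) & ~np.isnan(nrm)
    cosv = np.full(fm.shape, np.nan)
    dots = np.einsum("...d,...d->...", cr, o)
    cosv[ok] = dots[ok] / nrm[ok]
    # global sense toward the bottom shell = sense agreeing with orientation
    if np.isfinite(cosv).any() and np.nanmedian(cosv) < 0:
        cosv = -cosv
    return cosv


@dataclass
class SmoothnessReport:
    laplacian: np.ndarray      # per-voxel Δd (μm⁻²·... in depth units per μm²)
    divergence: np.ndarray     # per-voxel ∇·O (per μm)
    stats: dict = field(default_factory=dict)


def field_smoothness(depth: Volume, orientation: Volume,
                     shells: Volume | None = None) -> SmoothnessReport:
    """Laplacian of depth and divergence of orientation (central
    differences); medians and IQRs over interior voxels only, to avoid
    boundary-difference artifacts.

    When no shell volume is given, "interior" means voxels whose full
    26-neighborhood is valid.
    """
    d = depth.data
    mask = ~np.isnan(d)
    h = np.broadcast_to(depth.voxel_size, (3,))
    lap = np.full(d.shape, np.nan)
    dv = np.where(mask, d, np.nan)
    acc = np.zeros(d.shape)
    ok = np.ones(d.shape, dtype=bool)
    for axis in range(3):
        plus = np.roll(dv, -1, axis=axis)
        minus = np.roll(dv, 1, axis=axis)
        sl = [slice(None)] * 3
        sl[axis] = slice(-1, None)
        plus[tuple(sl)] = np.nan
        sl[axis] = slice(0, 1)
        minus[tuple(sl)] = np.nan
        term = (plus - 2 * dv + minus) / h[axis] ** 2
        ok &= ~np.isnan(term)
        acc = acc + np.where(np.isnan(term), 0.0, term)
    lap[ok & mask] = acc[ok & mask]

    o = orientation.data
    div = np.full(d.shape, np.nan)
    acc = np.zeros(d.shape)
    okd = np.ones(d.shape, dtype=bool)
    o_ok = ~np.isnan(o).any(axis=-1)
    for axis in range(3):
        comp = np.where(o_ok, o[..., axis], np.nan)
        plus = np.roll(comp, -1, axis=axis)
        minus = np.roll(comp, 1, axis=axis)
        sl = [slice(None)] * 3
        sl[axis] = slice(-1, None)
        plus[tuple(sl)] = np.nan
        sl[axis] = slice(0, 1)
        minus[tuple(sl)] = np.nan
        term = (plus - minus) / (2 * h[axis])
        okd &= ~np.isnan(term)
        acc = acc + np.where(np.isnan(term), 0.0, term)
    div[okd & o_ok] = acc[okd & o_ok]

    if shells is not None:
        interior = shells.data != EXTERIOR
        for code in (TOP, BOTTOM, SIDE):
            interior &= shells.data != code
    else:
        interior = ndimage.binary_erosion(mask, structure=_STRUCT26,
                                          border_value=0)
    out_stats = {}
    for name, arr in (("laplacian", lap), ("divergence", div)):
        vals = arr[interior & ~np.isnan(arr)]
        if len(vals):
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            out_stats[name] = {"median": float(med), "iqr": float(q3 - q1),
                               "n": int(len(vals))}
        else:
            out_stats[name] = {"median": np.nan, "iqr": np.nan, "n": 0}
    return SmoothnessReport(lap, div, out_stats)


# ---------------------------------------------------------------------------
# per-pixel metrics


def _largest_component_fraction(lin_idx: np.ndarray, shape) -> float:
    """Fraction of voxels in the largest 26-connected component."""
    if len(lin_idx) == 0:
        return np.nan
    if len(lin_idx) == 1:
        return 1.0
    ijk = np.array(np.unravel_index(lin_idx, shape)).T
    lo = ijk.min(axis=0)
    sub = ijk - lo + 1
    box = np.zeros(tuple(sub.max(axis=0) + 2), dtype=bool)
    box[tuple(sub.T)] = True
    lab, n = ndimage.label(box, structure=_STRUCT26)
    if n <= 1:
        return 1.0
    counts = np.bincount(lab[box])
    return float(counts.max() / len(lin_idx))


@dataclass
class PerPixelMetrics:
    size: np.ndarray          # (nx_pix, N) int
    uniformity: np.ndarray    # percent of the uniform expectation
    connectedness: np.ndarray
    continuity: np.ndarray
    conicity: np.ndarray      # voxels per unit relative depth
    conicity_norm: np.ndarray  # slope / mean bin count

    def summary(self) -> dict:
        out = {}
        for name in ("size", "uniformity", "connectedness", "continuity",
                     "conicity", "conicity_norm"):
            arr = getattr(self, name)
            vals = arr[np.isfinite(arr)]
            out[name] = {
                "mean": float(vals.mean()) if len(vals) else np.nan,
                "median": float(np.median(vals)) if len(vals) else np.nan,
            }
        return out


def per_pixel_metrics(grid: PixelGrid, depth: Volume,
                      n_depth_bins: int = 10) -> PerPixelMetrics:
    """All five per-pixel preimage metrics at the grid's resolution.

    Uniformity is measured against the count expected from pixel area within
    the *used* flat area (the mean over nonempty pixels is then exactly
    100%). Continuity takes the worst combined-preimage connectedness over
    the four 4-neighbor pixel pairs. Conicity is the least-squares slope of
    the depth histogram of the preimage (counts per unit relative depth).
    """
    nxp, N = grid.n_pixels_x, grid.resolution
    size = grid.sizes
    nonempty = size > 0
    n_elig = grid.n_eligible
    expected = n_elig / max(nonempty.sum(), 1)
    uniformity = np.where(nonempty, 100.0 * size / expected, np.nan)

    d_flat = depth.data.reshape(-1)
    shape = grid.shape
    connectedness = np.full((nxp, N), np.nan)
    conicity = np.full((nxp, N), np.nan)
    conicity_norm = np.full((nxp, N), np.nan)
    edges = np.linspace(0.0, 1.0, n_depth_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    for i in range(nxp):
        for j in range(N):
            if not nonempty[i, j]:
                continue
            pix = grid.preimage(i, j)
            connectedness[i, j] = _largest_component_fraction(pix, shape)
            dd = d_flat[pix]
            dd = dd[np.isfinite(dd)]
            if len(dd):
                hist, _ = np.histogram(np.clip(dd, 0, 1), bins=edges)
                present = hist > 0
                # fit over depth bins the local column actually spans
                if present.sum() >= 2:
                    slope = np.polyfit(centers[present], hist[present], 1)[0]
                else:
                    slope = 0.0
                conicity[i, j] = slope
                m = hist[present].mean() if present.any() else np.nan
                conicity_norm[i, j] = slope / m if m else np.nan

    continuity = np.full((nxp, N), np.nan)
    for i in range(nxp):
        for j in range(N):
            if not nonempty[i, j]:
                continue
            worst = 1.0
            own = grid.preimage(i, j)
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                a, b = i + di, j + dj
                if not (0 <= a < nxp and 0 <= b < N):
                    continue
                combined = np.concatenate([own, grid.preimage(a, b)])
                worst = min(worst,
                            _largest_component_fraction(combined, shape))
            continuity[i, j] = worst

    return PerPixelMetrics(size, uniformity, connectedness, continuity,
                           conicity, conicity_norm)


# ---------------------------------------------------------------------------
# preimage radius (truncated-square-pyramid fit)


def square_radial_arc(r: np.ndarray, a: float) -> np.ndarray:
    """Arc length of the circle of radius r inside a square of half-width a
    (the unnormalized radial density of a uniform square cross-section)."""
    r = np.asarray(r, dtype=float)
    out = np.zeros_like(r)
    inside = r <= a
    out[inside] = 2 * np.pi * r[inside]
    corner = (r > a) & (r <= a * np.sqrt(2))
    rc = r[corner]
    out[corner] = rc * (2 * np.pi - 8 * np.arccos(a / rc))
    return out


def pyramid_radial_density(r: np.ndarray, r0: float, r1: float,
                           n_z: int = 64) -> np.ndarray:
    """Radial-distance density of a uniform truncated square pyramid whose
    square cross-section half-width varies linearly from r0 to r1 with
    height; normalized so ∫p dr = 1."""
    r = np.asarray(r, dtype=float)
    z = (np.arange(n_z) + 0.5) / n_z
    a_z = r0 + (r1 - r0) * z
    dens = np.zeros_like(r)
    for a in a_z:
        dens += square_radial_arc(r, a)
    # normalization: ∫ arc(r, a) dr = area = 4a² per slice
    dens /= np.sum(4.0 * a_z**2)
    return dens


def preimage_radius(points: np.ndarray, voxel_size: float,
                    ) -> tuple[float, float, float, bool]:
    """Radius of a preimage from the truncated-square-pyramid fit.

    The preimage axis is the first principal component through the centroid;
    the histogram of radial distances r(v) is fitted (least squares, density
    normalized, √n bins) with the pyramid radial density; the radius is
    (r0 + r1)/2. Degenerate preimages (< 4 voxels, or collinear) fall back
    to half a voxel, flagged. Returns (radius, r0, r1, flagged).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    h = float(voxel_size)
    if len(pts) < 4:
        return 0.5 * h, 0.5 * h, 0.5 * h, True
    centered = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):  # collinear
        return 0.5 * h, 0.5 * h, 0.5 * h, True
    axis = vt[0]
    radial = centered - np.outer(centered @ axis, axis)
    r = np.linalg.norm(radial, axis=1)
    rmax = r.max()
    if rmax < 1e-12:
        return 0.5 * h, 0.5 * h, 0.5 * h, True
    nbins = max(4, int(np.sqrt(len(r))))
    hist, edges = np.histogram(r, bins=nbins, range=(0.0, rmax * 1.001),
                               density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def resid(params):
        r0, r1 = params
        return pyramid_radial_density(centers, r0, r1) - hist

    x0 = rmax / np.sqrt(2.0)
    fit = optimize.least_squares(resid, x0=[x0, x0],
                                 bounds=([1e-6 * h, 1e-6 * h],
                                         [4 * rmax, 4 * rmax]))
    r0, r1 = float(fit.x[0]), float(fit.x[1])
    return 0.5 * (r0 + r1), r0, r1, False


def mean_preimage_radius(grid: PixelGrid, vol: Volume,
                         min_voxels: int = 4) -> float:
    """Mean fitted preimage radius over nonempty pixels (μm); pixels smaller
    than ``min_voxels`` use the half-voxel fallback and are skipped from the
    mean when any fitted pixel exists."""
    h = float(np.min(vol.voxel_size))
    radii = []
    fitted = []
    sizes = grid.sizes
    for i in range(grid.n_pixels_x):
        for j in range(grid.resolution):
            if sizes[i, j] == 0:
                continue
            lin = grid.preimage(i, j)
            ijk = np.array(np.unravel_index(lin, grid.shape)).T
            pts = vol.world(ijk)
            rad, _, _, flagged = preimage_radius(pts, h)
            radii.append(rad)
            fitted.append(not flagged)
    radii = np.array(radii)
    fitted = np.array(fitted)
    if fitted.any():
        return float(radii[fitted].mean())
    return float(radii.mean())


# ---------------------------------------------------------------------------
# calibration


def calibrate_distance(mean_radii: np.ndarray, pixel_sizes: np.ndarray
                       ) -> tuple[float, float]:
    """Slope (± standard error) of mean preimage radius (μm) against pixel
    size (flat units): μm per flat coordinate unit."""
    mean_radii = np.asarray(mean_radii, dtype=float)
    pixel_sizes = np.asarray(pixel_sizes, dtype=float)
    if len(mean_radii) < 3 or len(pixel_sizes) != len(mean_radii):
        raise ValueError("need mean radii at >= 3 resolutions")
    fit = stats.linregress(pixel_sizes, mean_radii)
    return float(fit.slope), float(fit.stderr)


def calibrate_distance_from_grids(grids: list[PixelGrid], vol: Volume
                                  ) -> tuple[float, float]:
    radii = [mean_preimage_radius(g, vol) for g in grids]
    sizes = [1.0 / g.resolution for g in grids]
    return calibrate_distance(np.array(radii), np.array(sizes))


def calibrate_area(fm: Flatmap):
    """mm² per unit of flat area fraction: f ↦ f · mesh_area."""
    if not np.isfinite(fm.mesh_area):
        raise ValueError("flatmap records no projection-mesh area")
    area = fm.mesh_area

    def factor(flat_area_fraction: float) -> float:
        return flat_area_fraction * area

    return factor
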