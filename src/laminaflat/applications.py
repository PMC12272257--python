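"""Applications of flatmaps: volume decomposition into columns, barrel /
barrel-column annotation, and per-barrel anatomical metrics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.strtree import STRtree

from .io import Flatmap, Volume
from .streamlines import ContinuousFields, trace_streamline


# ---------------------------------------------------------------------------
# tilings


@dataclass
class Tiling:
    """Convex cells covering (part of) flat space, pairwise interior-disjoint."""

    cells: list  # list of shapely Polygons

    def __post_init__(self):
        for c in self.cells:
            if not c.is_valid or c.area <= 0:
                raise ValueError("tiling cells must be valid nonempty polygons")

    def validate_disjoint(self, tol: float = 1e-12) -> None:
        tree = STRtree(self.cells)
        for i, cell in enumerate(self.cells):
            for j in tree.query(cell):
                if j <= i:
                    continue
                inter = cell.intersection(self.cells[j]).area
                if inter > tol * min(cell.area, self.cells[j].area):
                    raise ValueError(
                        f"tiling cells {i} and {j} overlap (area {inter:g})")


def square_tiling(n: int, x_range=(0.0, 1.0), y_range=(0.0, 1.0)) -> Tiling:
    """n × n square grid over the flat range."""
    xs = np.linspace(*x_range, n + 1)
    ys = np.linspace(*y_range, n + 1)
    cells = [
        Polygon([(xs[i], ys[j]), (xs[i + 1], ys[j]),
                 (xs[i + 1], ys[j + 1]), (xs[i], ys[j + 1])])
        for i in range(n) for j in range(n)
    ]
    return Tiling(cells)


def hex_tiling(circumradius: float, x_range=(0.0, 1.0),
               y_range=(0.0, 1.0)) -> Tiling:
    """Flat-side-up hexagonal grid covering the flat range; border cells are
    kept (clipped to the range)."""
    R = float(circumradius)
    w = np.sqrt(3) * R          # flat-to-flat width
    dy = 1.5 * R
    cells = []
    domain = Polygon([(x_range[0], y_range[0]), (x_range[1], y_range[0]),
                      (x_range[1], y_range[1]), (x_range[0], y_range[1])])
    ny = int(np.ceil((y_range[1] - y_range[0]) / dy)) + 2
    nx = int(np.ceil((x_range[1] - x_range[0]) / w)) + 2
    ang = np.pi / 6 + np.arange(6) * np.pi / 3  # flat side up
    for row in range(-1, ny):
        cy = y_range[0] + row * dy
        off = 0.5 * w if row % 2 else 0.0
        for col in range(-1, nx):
            cx = x_range[0] + col * w + off
            hexagon = Polygon(
                [(cx + R * np.cos(a), cy + R * np.sin(a)) for a in ang])
            clipped = hexagon.intersection(domain)
            if clipped.area > 1e-12:
                cells.append(clipped)
    return Tiling(cells)


def decompose(fm: Flatmap, tiling: Tiling) -> Volume:
    """Label every eligible voxel by the tiling cell containing its flat
    coordinates (1-based cell ids; 0 = unassigned/ineligible).

    The resulting subvolumes are pairwise disjoint and cover the eligible
    set wherever the tiling covers flat space.
    """
    tiling.validate_disjoint()
    valid = fm.valid_mask
    xy = fm.coords[valid]
    labels = np.zeros(len(xy), dtype=np.int64)
    tree = STRtree([Point(p) for p in xy])
    for ci, cell in enumerate(tiling.cells):
        hits = tree.query(cell, predicate="intersects")
        for h in hits:
            if labels[h] == 0:  # first containing cell wins on shared edges
                labels[h] = ci + 1
    out = np.zeros(fm.shape, dtype=np.int64)
    out[valid] = labels
    return Volume(out, fm.voxel_size, fm.origin)


# ---------------------------------------------------------------------------
# barrels


@dataclass
class BarrelAnnotation:
    """Integer barrel labels (0 = none) and, once built, the corresponding
    full-depth column labels and the layer-4 mask used to clip barrels."""

    barrel_labels: Volume
    column_labels: Volume | None = None
    layer4_mask: np.ndarray | None = None
    report: dict = field(default_factory=dict)

    @property
    def labels(self) -> np.ndarray:
        return np.unique(
            self.barrel_labels.data[self.barrel_labels.data > 0])


def refine_barrel_labels(fm: Flatmap, barrels: BarrelAnnotation,
                         max_iter: int = 50) -> BarrelAnnotation:
    """Reassign mislabeled barrel voxels to the label of their nearest
    labeled neighbor in flat space, iterated to a fixed point."""
    lab = barrels.barrel_labels.data.copy()
    valid = fm.valid_mask
    sel = (lab > 0) & valid
    if not sel.any():
        raise ValueError("no labeled barrel voxels with flat coordinates")
    idx = np.argwhere(sel)
    xy = fm.coords[sel]
    cur = lab[sel].astype(np.int64)
    n_changed_total = 0
    # voxels of one column share identical flat coordinates, so the nearest
    # neighbor is taken at strictly positive flat distance (coincident voxels
    # carry no lateral information about the barrel outline)
    tree = cKDTree(xy)
    kq = min(len(xy), 32)
    dist, nn = tree.query(xy, k=kq)
    pos = dist > 1e-12
    first = np.argmax(pos, axis=1)
    has = pos.any(axis=1)
    neighbor = nn[np.arange(len(xy)), first]
    for _ in range(max_iter):
        new = np.where(has, cur[neighbor], cur)
        changed = new != cur
        if not changed.any():
            break
        cur = new
        n_changed_total += int(changed.sum())
    out = lab.copy()
    out[tuple(idx.T)] = cur
    flagged = [int(b) for b in np.unique(cur)
               if (cur == b).sum() < 3]
    return BarrelAnnotation(
        barrel_labels=barrels.barrel_labels.like(out),
        layer4_mask=barrels.layer4_mask,
        report={"n_reassigned": n_changed_total,
                "small_barrels_flagged": flagged},
    )


def build_barrel_columns(fm: Flatmap, barrels: BarrelAnnotation,
                         layer4_mask: np.ndarray | None = None
                         ) -> BarrelAnnotation:
    """Columns as preimages of the convex hulls of each barrel's flat
    positions; barrels clipped to the layer-4 mask.

    Flat positions claimed by several hulls (touching barrels) are resolved
    before taking preimages, by nearest-cluster assignment (smallest distance
    to the claiming barrels' flat point sets), so columns are disjoint by
    construction.
    """
    if layer4_mask is None:
        layer4_mask = barrels.layer4_mask
    lab = barrels.barrel_labels.data
    valid = fm.valid_mask
    ids = [int(b) for b in np.unique(lab[lab > 0])]
    if not ids:
        raise ValueError("no barrel labels")
    hulls = {}
    clouds = {}
    for b in ids:
        sel = (lab == b) & valid
        pts = fm.coords[sel]
        if len(pts) < 3:
            continue
        hulls[b] = MultiPoint([tuple(p) for p in pts]).convex_hull
        clouds[b] = pts
    elig_idx = np.argwhere(valid)
    exy = fm.coords[valid]
    epts = [Point(p) for p in exy]
    tree = STRtree(epts)
    claims: dict[int, list[int]] = {}
    for b, hull in hulls.items():
        for h in tree.query(hull, predicate="covers"):
            claims.setdefault(int(h), []).append(b)
    col = np.zeros(fm.shape, dtype=np.int64)
    trees = {b: cKDTree(c) for b, c in clouds.items()}
    n_contested = 0
    for h, bs in claims.items():
        if len(bs) == 1:
            winner = bs[0]
        else:
            n_contested += 1
            dists = [(trees[b].query(exy[h])[0], b) for b in bs]
            winner = min(dists)[1]
        col[tuple(elig_idx[h])] = winner
    barrel_clipped = lab.copy()
    barrel_clipped[col == 0] = 0
    new_barrel = np.where(col > 0, col, 0)
    if layer4_mask is not None:
        new_barrel = np.where(layer4_mask, new_barrel, 0)
    return BarrelAnnotation(
        barrel_labels=barrels.barrel_labels.like(new_barrel),
        column_labels=barrels.barrel_labels.like(col),
        layer4_mask=layer4_mask,
        report={"n_contested": n_contested,
                "n_columns": len(hulls)},
    )


# ---------------------------------------------------------------------------
# barrel metrics


def fit_ellipse_axes(xy: np.ndarray) -> tuple[float, float]:
    """Major/minor half-axes of the 2-sigma covariance ellipse of 2D points
    (the axis ratio is invariant to the confidence level)."""
    cov = np.cov(np.asarray(xy).T)
    ev = np.linalg.eigvalsh(cov)
    ev = np.clip(ev, 0.0, None)
    return 2.0 * float(np.sqrt(ev[1])), 2.0 * float(np.sqrt(ev[0]))


def column_curvature(streamline_points: np.ndarray) -> float:
    """Maximal displacement between a column's central streamline and its
    least-squares straight line, evaluated at the column top and bottom."""
    pts = np.asarray(streamline_points, dtype=float)
    c = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - c, full_matrices=False)
    axis = vt[0]
    proj = (pts - c) @ axis
    resid = pts - c - np.outer(proj, axis)
    disp = np.linalg.norm(resid, axis=1)
    return float(max(disp[0], disp[-1]))


def barrel_metrics(annotation: BarrelAnnotation, fm: Flatmap,
                   fields: ContinuousFields | None,
                   depth: Volume, thickness: Volume | None = None,
                   layer_labels: Volume | None = None,
                   n_depth_bins: int = 10) -> pd.DataFrame:
    """Per-barrel anatomical metrics.

    volume (mm³) from voxel counts; surface area (mm²) from the flat convex
    hull area scaled by the projection-mesh area; ellipticity from the
    covariance ellipse of the flat positions; curvature from the central
    streamline (seeded at the barrel centroid); conicity as the slope of the
    depth-wise volume histogram of the column; mean absolute layer-border
    depths (μm, needs thickness) when a layer-label volume is given.
    """
    if not np.isfinite(fm.mesh_area):
        raise ValueError("flatmap records no mesh area; area calibration "
                         "is required for barrel surface areas")
    col = annotation.column_labels
    bar = annotation.barrel_labels
    if col is None:
        raise ValueError("annotation has no columns; run build_barrel_columns")
    vol = bar.voxel_volume_mm3
    valid = fm.valid_mask
    rows = []
    edges = np.linspace(0.0, 1.0, n_depth_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    for b in [int(x) for x in np.unique(col.data[col.data > 0])]:
        bsel = bar.data == b
        csel = col.data == b
        flat_xy = fm.coords[bsel & valid]
        row = {
            "barrel": b,
            "barrel_volume_mm3": float(bsel.sum() * vol),
            "column_volume_mm3": float(csel.sum() * vol),
        }
        if len(flat_xy) >= 3:
            hull = MultiPoint([tuple(p) for p in flat_xy]).convex_hull
            row["surface_area_mm2"] = float(hull.area * fm.mesh_area)
            major, minor = fit_ellipse_axes(flat_xy)
            row["ellipticity"] = major / minor if minor > 0 else np.inf
        else:
            row["surface_area_mm2"] = np.nan
            row["ellipticity"] = np.nan
        dd = depth.data[csel]
        dd = dd[np.isfinite(dd)]
        if len(dd) >= 2:
            hist, _ = np.histogram(np.clip(dd, 0, 1), bins=edges)
            present = hist > 0
            row["conicity"] = (
                float(np.polyfit(centers[present], hist[present], 1)[0])
                if present.sum() >= 2 else 0.0)
        else:
            row["conicity"] = np.nan
        if fields is not None and bsel.any():
            centroid = Volume(
                np.zeros(fm.shape, np.uint8), fm.voxel_size, fm.origin
            ).world(np.argwhere(bsel)).mean(axis=0)
            if fields.inside(centroid.reshape(1, 3))[0]:
                s = trace_streamline(centroid, fields)
                row["curvature_um"] = column_curvature(s.points)
            else:
                row["curvature_um"] = np.nan
        else:
            row["curvature_um"] = np.nan
        if layer_labels is not None and thickness is not None:
            abs_depth = depth.data * thickness.data
            for la, lb in _adjacent_layer_pairs(layer_labels.data, csel):
                border = _border_voxels(layer_labels.data, csel, la, lb)
                if border.any():
                    row[f"border_L{la}_L{lb}_um"] = float(
                        np.nanmean(abs_depth[border]))
        rows.append(row)
    return pd.DataFrame(rows).set_index("barrel")


def _adjacent_layer_pairs(layers: np.ndarray, sel: np.ndarray):
    present = sorted(int(x) for x in np.unique(layers[sel]) if x > 0)
    return list(zip(present[:-1], present[1:]))


def _border_voxels(layers: np.ndarray, sel: np.ndarray, la: int, lb: int
                   ) -> np.ndarray:
    """Voxels of layer `la` inside `sel` 6-adjacent to layer `lb`."""
    a = sel & (layers == la)
    b = layers == lb
    nb = np.zeros_like(a)
    for axis in range(3):
        for shift in (-1, 1):
            nb |= np.roll(b, shift, axis=axis)
    return a & nb
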