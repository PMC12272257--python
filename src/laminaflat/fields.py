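"""Principal-axis atlases: relative depth, thickness and orientation fields.

Two routes are provided:

* the segment route: pair every top-shell voxel with its nearest bottom-shell
  voxel (and vice versa), then define per-voxel orientation / thickness /
  depth from the N nearest such segments;
* the Laplace route: solve the steady-state heat equation with hot top shell,
  cold bottom shell and adiabatic sides, and take the (normalized) solution
  as depth and its gradient as orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import cg, spsolve
from scipy.spatial import cKDTree

from .io import BOTTOM, EXTERIOR, INTERIOR, SHELL_NAMES, SIDE, TOP, Volume

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


# ---------------------------------------------------------------------------
# shells


def extract_boundary_candidates(mask: np.ndarray) -> np.ndarray:
    """Boolean grid of mask voxels with at least one exterior voxel in their
    26-neighborhood (voxels on the array edge count as touching exterior)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask: no source volume voxels")
    interior = ndimage.binary_erosion(mask, structure=_STRUCT26, border_value=0)
    return mask & ~interior


@dataclass
class ShellReport:
    counts: dict
    violations: list
    fatal: bool

    def __str__(self):
        lines = [f"{name}: {n}" for name, n in self.counts.items()]
        lines += [f"VIOLATION: {v}" for v in self.violations]
        lines.append("fatal" if self.fatal else "ok")
        return "\n".join(lines)


def validate_shells(shells: Volume | np.ndarray,
                    mask: np.ndarray | None = None) -> ShellReport:
    """Check shell-label invariants; report-only, never raises.

    Checks: top/bottom/side voxels belong to the source volume and touch the
    exterior (26-neighborhood); top and bottom shells are nonempty.
    """
    labels = shells.data if isinstance(shells, Volume) else np.asarray(shells)
    if mask is None:
        mask = labels != EXTERIOR
    counts = {name: int((labels == code).sum())
              for code, name in SHELL_NAMES.items()}
    violations = []
    fatal = False
    try:
        boundary = extract_boundary_candidates(mask)
    except ValueError:
        return ShellReport(counts, ["empty source volume"], True)
    for code in (TOP, BOTTOM, SIDE):
        where = labels == code
        n_outside = int((where & ~mask).sum())
        if n_outside:
            violations.append(
                f"{n_outside} {SHELL_NAMES[code]} voxel(s) outside source volume")
        n_buried = int((where & mask & ~boundary).sum())
        if n_buried:
            violations.append(
                f"{n_buried} {SHELL_NAMES[code]} voxel(s) not touching exterior")
    for code in (TOP, BOTTOM):
        if counts[SHELL_NAMES[code]] == 0:
            violations.append(f"empty {SHELL_NAMES[code]} shell")
            fatal = True
    return ShellReport(counts, violations, fatal)


# ---------------------------------------------------------------------------
# shortest segments


@dataclass
class SegmentSet:
    """Line segments joining top-shell and bottom-shell voxel centers (μm).

    ``provenance`` is 0 for segments found by pairing a top voxel with its
    nearest bottom voxel and 1 for the reverse pairing. Duplicates (pairs
    found in both directions) are kept.
    """

    p_top: np.ndarray     # (n, 3)
    p_bottom: np.ndarray  # (n, 3)
    provenance: np.ndarray  # (n,) uint8

    def __len__(self):
        return len(self.p_top)

    @property
    def directions(self) -> np.ndarray:
        """Unit vectors from top to bottom (toward the bottom shell)."""
        d = self.p_bottom - self.p_top
        return d / np.linalg.norm(d, axis=1, keepdims=True)

    @property
    def lengths(self) -> np.ndarray:
        return np.linalg.norm(self.p_bottom - self.p_top, axis=1)

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.p_top + self.p_bottom)


def _nearest_lowest_index(sources: np.ndarray, targets: np.ndarray,
                          target_order: np.ndarray) -> np.ndarray:
    """Index (into targets) of the Euclidean-nearest target per source; ties
    broken by lowest ``target_order`` value (linear voxel index)."""
    tree = cKDTree(targets)
    dist, idx = tree.query(sources, k=1)
    # resolve ties deterministically: any target within rtol of the min
    eps = 1e-9 * np.maximum(dist, 1.0)
    for s, (d, _) in enumerate(zip(dist, idx)):
        cand = tree.query_ball_point(sources[s], d + eps[s])
        if len(cand) > 1:
            cand = np.asarray(cand)
            dd = np.linalg.norm(targets[cand] - sources[s], axis=1)
            close = cand[dd <= d + eps[s]]
            idx[s] = close[np.argmin(target_order[close])]
    return idx


def shortest_segments(shells: Volume) -> SegmentSet:
    """All segments joining each top voxel with its nearest bottom voxel and
    vice versa (both directions kept, duplicates allowed)."""
    labels = shells.data
    top_idx = np.argwhere(labels == TOP)
    bot_idx = np.argwhere(labels == BOTTOM)
    if len(top_idx) == 0 or len(bot_idx) == 0:
        raise ValueError("top and bottom shells must both be nonempty")
    top_pts = shells.world(top_idx)
    bot_pts = shells.world(bot_idx)
    shape = labels.shape
    top_lin = np.ravel_multi_index(top_idx.T, shape)
    bot_lin = np.ravel_multi_index(bot_idx.T, shape)

    j = _nearest_lowest_index(top_pts, bot_pts, bot_lin)
    i = _nearest_lowest_index(bot_pts, top_pts, top_lin)
    p_top = np.vstack([top_pts, top_pts[i]])
    p_bottom = np.vstack([bot_pts[j], bot_pts])
    provenance = np.concatenate(
        [np.zeros(len(top_pts), dtype=np.uint8),
         np.ones(len(bot_pts), dtype=np.uint8)]
    )
    return SegmentSet(p_top, p_bottom, provenance)


def point_segment_distance(points: np.ndarray, p0: np.ndarray,
                           p1: np.ndarray) -> np.ndarray:
    """Distances from points (n,3) to finite segments (m,3)-(m,3) -> (n,m)."""
    seg = p1 - p0                                   # (m,3)
    seglen2 = np.einsum("md,md->m", seg, seg)
    diff = points[:, None, :] - p0[None, :, :]      # (n,m,3)
    t = np.einsum("nmd,md->nm", diff, seg) / seglen2
    t = np.clip(t, 0.0, 1.0)
    closest = p0[None, :, :] + t[..., None] * seg[None, :, :]
    return np.linalg.norm(points[:, None, :] - closest, axis=2)


# ---------------------------------------------------------------------------
# fields from segments


@dataclass
class FieldSet:
    orientation: Volume
    thickness: Volume
    depth: Volume
    flags: Volume = None          # uint8: 1 = side exit, 2 = no direction
    report: dict = field(default_factory=dict)


def _ray_exit_distance(start: np.ndarray, direction: np.ndarray,
                       mask: np.ndarray, vol: Volume, step: float,
                       max_dist: float) -> tuple[np.ndarray, np.ndarray]:
    """March each start point along its direction until leaving ``mask``;
    return (distance to the refined exit point, linear index of the last
    inside voxel). Vectorized over points."""
    n = len(start)
    shape = np.array(mask.shape)

    def inside(pts):
        idx = np.floor((pts - vol.origin) / vol.voxel_size).astype(np.int64)
        ok = np.all((idx >= 0) & (idx < shape), axis=1)
        lin = np.zeros(len(pts), dtype=np.int64)
        lin[ok] = np.ravel_multi_index(idx[ok].T, mask.shape)
        ok[ok] &= mask.ravel()[lin[ok]]
        return ok, lin

    t_lo = np.zeros(n)
    t_hi = np.full(n, np.nan)
    last_lin = np.zeros(n, dtype=np.int64)
    ok0, lin0 = inside(start)
    last_lin[:] = lin0
    active = ok0.copy()
    t = np.zeros(n)
    nsteps = int(np.ceil(max_dist / step)) + 2
    for _ in range(nsteps):
        if not active.any():
            break
        t_next = t[active] + step
        pts = start[active] + t_next[:, None] * direction[active]
        ok, lin = inside(pts)
        sub = np.where(active)[0]
        out = sub[~ok]
        t_hi[out] = t[out] + step
        t_lo[out] = t[out]
        stay = sub[ok]
        last_lin[stay] = lin[ok]
        t[stay] += step
        active[out] = False
    # unresolved rays (still inside after max_dist) get NaN distance
    t_hi[active] = np.nan

    # bisection refine the crossing between t_lo and t_hi
    resolved = ~np.isnan(t_hi)
    lo = t_lo[resolved]
    hi = t_hi[resolved]
    pts0 = start[resolved]
    dirs = direction[resolved]
    for _ in range(25):
        mid = 0.5 * (lo + hi)
        ok, lin = inside(pts0 + mid[:, None] * dirs)
        lo = np.where(ok, mid, lo)
        hi = np.where(ok, hi, mid)
        rr = np.where(resolved)[0]
        upd = rr[ok]
        last_lin[upd] = lin[ok]
    out_t = np.full(n, np.nan)
    out_t[resolved] = 0.5 * (lo + hi)
    return out_t, last_lin


def fields_from_segments(shells: Volume, segs: SegmentSet, n_segments: int,
                         distance_mode: str = "segment",
                         ray_step_factor: float = 0.25) -> FieldSet:
    """Per-voxel orientation / thickness / depth from the N nearest segments.

    Orientation is the normalized mean of the segment directions (signed
    toward the bottom shell); thickness the mean segment length; depth the
    ray-marched distance to the top shell along -orientation divided by
    thickness, clamped to [0, 1]. Voxels whose ray exits through a side are
    filled from their nearest resolved neighbor and flagged.
    """
    if not 1 <= n_segments <= len(segs):
        raise ValueError(f"n_segments must be in [1, {len(segs)}]")
    labels = shells.data
    mask = labels != EXTERIOR
    vox_idx = np.argwhere(mask)
    centers = shells.world(vox_idx)
    nvox = len(centers)

    mids = segs.midpoints
    dirs = segs.directions
    lens = segs.lengths
    tree = cKDTree(mids)

    if distance_mode == "midpoint":
        _, knn = tree.query(centers, k=n_segments)
        knn = np.atleast_2d(knn.T).T if n_segments == 1 else knn
        if knn.ndim == 1:
            knn = knn[:, None]
        sel = knn
    elif distance_mode == "segment":
        # midpoint prefilter, exact point-to-segment distance on candidates
        k_cand = min(len(segs), max(4 * n_segments, n_segments + 32))
        _, cand = tree.query(centers, k=k_cand)
        if cand.ndim == 1:
            cand = cand[:, None]
        sel = np.empty((nvox, n_segments), dtype=np.int64)
        chunk = max(1, int(2e7 // max(k_cand, 1)))
        for s in range(0, nvox, chunk):
            e = min(nvox, s + chunk)
            c = cand[s:e]
            d = _point_to_candidate_segments(centers[s:e], c, segs)
            part = np.argpartition(d, n_segments - 1, axis=1)[:, :n_segments]
            sel[s:e] = np.take_along_axis(c, part, axis=1)
    else:
        raise ValueError(f"unknown distance_mode {distance_mode!r}")

    mean_dir = dirs[sel].mean(axis=1)
    norms = np.linalg.norm(mean_dir, axis=1)
    no_dir = norms < 1e-12
    mean_dir[~no_dir] /= norms[~no_dir, None]
    thickness_v = lens[sel].mean(axis=1)

    # ray-march toward the top shell (against the orientation)
    h = float(np.min(shells.voxel_size))
    step = ray_step_factor * h
    max_dist = float(np.linalg.norm(np.array(mask.shape) * shells.voxel_size)) * 1.5
    t_exit, last_lin = _ray_exit_distance(
        centers[~no_dir], -mean_dir[~no_dir], mask, shells, step, max_dist)
    exit_label = labels.ravel()[last_lin]
    y = t_exit - 0.5 * h  # exit surface -> center of the last (shell) voxel
    d_v = np.full(nvox, np.nan)
    ok = np.where(~no_dir)[0]
    d_v[ok] = np.clip(y / thickness_v[ok], 0.0, 1.0)
    side_exit = np.zeros(nvox, dtype=bool)
    side_exit[ok] = (exit_label != TOP) | np.isnan(t_exit)

    # assemble grids
    shape = labels.shape
    orient = np.full(shape + (3,), np.nan)
    thick = np.full(shape, np.nan)
    depth = np.full(shape, np.nan)
    flags = np.zeros(shape, dtype=np.uint8)
    sel_ok = ~no_dir
    orient[tuple(vox_idx[sel_ok].T)] = mean_dir[sel_ok]
    thick[tuple(vox_idx.T)] = thickness_v
    depth[tuple(vox_idx.T)] = d_v
    flags[tuple(vox_idx[side_exit].T)] |= 1
    flags[tuple(vox_idx[no_dir].T)] |= 2

    # side-exit voxels take depth from their nearest resolved neighbor
    bad = np.zeros(shape, dtype=bool)
    bad[tuple(vox_idx[side_exit].T)] = True
    good = mask & ~bad & ~np.isnan(depth)
    if bad.any() and good.any():
        _, (ix, iy, iz) = ndimage.distance_transform_edt(
            ~good, return_indices=True, sampling=shells.voxel_size)
        depth[bad] = depth[ix[bad], iy[bad], iz[bad]]

    vol = Volume(labels, shells.voxel_size, shells.origin)
    return FieldSet(
        orientation=vol.like(orient),
        thickness=vol.like(thick),
        depth=vol.like(depth),
        flags=vol.like(flags),
        report={
            "n_side_exit": int(side_exit.sum()),
            "n_no_direction": int(no_dir.sum()),
            "n_voxels": nvox,
        },
    )


def _point_to_candidate_segments(points: np.ndarray, cand: np.ndarray,
                                 segs: SegmentSet) -> np.ndarray:
    """Exact point-to-segment distances for per-point candidate lists.

    points: (n,3); cand: (n,k) indices into segs -> (n,k) distances."""
    p0 = segs.p_top[cand]          # (n,k,3)
    p1 = segs.p_bottom[cand]
    seg = p1 - p0
    seglen2 = np.einsum("nkd,nkd->nk", seg, seg)
    diff = points[:, None, :] - p0
    t = np.einsum("nkd,nkd->nk", diff, seg) / seglen2
    t = np.clip(t, 0.0, 1.0)
    closest = p0 + t[..., None] * seg
    return np.linalg.norm(points[:, None, :] - closest, axis=2)


# ---------------------------------------------------------------------------
# Laplace route


def laplace_depth(shells: Volume, rtol: float = 1e-8,
                  direct_max_unknowns: int = 60_000) -> Volume:
    """Discrete harmonic relative depth: 0 on the top shell, 1 on the bottom
    shell, zero normal flux through the sides.

    Solved with a 6-neighbor graph Laplacian over the source volume; a direct
    sparse factorization for small systems, conjugate gradients (Jacobi
    preconditioned) otherwise.
    """
    labels = shells.data
    mask = labels != EXTERIOR
    top = labels == TOP
    bottom = labels == BOTTOM
    if not top.any() or not bottom.any():
        raise ValueError("top and bottom shells must both be nonempty")

    comp, ncomp = ndimage.label(mask, structure=_STRUCT26)
    bad_components = []
    for c in range(1, ncomp + 1):
        sel = comp == c
        if not (top[sel].any() or bottom[sel].any()):
            bad_components.append((c, int(sel.sum())))
    if bad_components:
        raise ValueError(
            "source volume has component(s) touching neither shell: "
            + ", ".join(f"component {c} ({n} voxels)" for c, n in bad_components))

    unknown = mask & ~top & ~bottom
    n_unknown = int(unknown.sum())
    d = np.full(labels.shape, np.nan)
    d[top] = 0.0
    d[bottom] = 1.0
    if n_unknown == 0:
        return Volume(d, shells.voxel_size, shells.origin)

    num = -np.ones(labels.shape, dtype=np.int64)
    num[unknown] = np.arange(n_unknown)
    rows, cols, vals = [], [], []
    diag = np.zeros(n_unknown)
    b = np.zeros(n_unknown)
    uidx = np.argwhere(unknown)
    for axis in range(3):
        for shift in (-1, 1):
            nb = uidx.copy()
            nb[:, axis] += shift
            ok = (nb[:, axis] >= 0) & (nb[:, axis] < labels.shape[axis])
            src = np.where(ok)[0]
            nb = nb[ok]
            in_mask = mask[tuple(nb.T)]
            src = src[in_mask]
            nb = nb[in_mask]
            diag_add = np.ones(len(src))
            np.add.at(diag, src, diag_add)
            nb_unknown = unknown[tuple(nb.T)]
            rows.append(src[nb_unknown])
            cols.append(num[tuple(nb[nb_unknown].T)])
            vals.append(-np.ones(nb_unknown.sum()))
            fixed = ~nb_unknown
            np.add.at(b, src[fixed], d[tuple(nb[fixed].T)])
    A = sparse.coo_matrix(
        (np.concatenate(vals + [diag]),
         (np.concatenate(rows + [np.arange(n_unknown)]),
          np.concatenate(cols + [np.arange(n_unknown)]))),
        shape=(n_unknown, n_unknown),
    ).tocsr()
    if n_unknown <= direct_max_unknowns:
        x = spsolve(A, b)
    else:
        M = sparse.diags(1.0 / A.diagonal())
        x, info = cg(A, b, rtol=rtol, maxiter=20_000, M=M)
        if info != 0:
            raise RuntimeError(f"Laplace CG failed to converge (info={info})")
    d[unknown] = x
    return Volume(d, shells.voxel_size, shells.origin)


def extend_field_outward(data: np.ndarray, mask: np.ndarray,
                         voxel_size) -> np.ndarray:
    """Continue a field one voxel beyond the mask by nearest-neighbor values
    (reduces one-sided-difference artifacts at the boundary)."""
    _, (ix, iy, iz) = ndimage.distance_transform_edt(
        ~mask, return_indices=True, sampling=np.broadcast_to(voxel_size, (3,)))
    ring = ndimage.binary_dilation(mask, structure=_STRUCT26) & ~mask
    out = np.where(mask, data, np.nan)
    out[ring] = data[ix[ring], iy[ring], iz[ring]]
    return out


def orientation_from_gradient(depth: Volume,
                              mask: np.ndarray | None = None) -> Volume:
    """Orientation as the normalized central-difference gradient of depth,
    computed after one-voxel outward extension of the depth field."""
    d = depth.data
    if mask is None:
        mask = ~np.isnan(d)
    if not mask.any():
        raise ValueError("depth field has no valid voxels")
    ext = extend_field_outward(np.where(mask, d, 0.0), mask, depth.voxel_size)
    ext_f = np.where(np.isnan(ext), 0.0, ext)
    gx, gy, gz = np.gradient(ext_f, *depth.voxel_size)
    g = np.stack([gx, gy, gz], axis=-1)
    # gradients touching never-filled voxels are unreliable -> invalid
    filled = ~np.isnan(ext)
    ok_nb = ndimage.binary_erosion(filled, structure=_STRUCT26, border_value=0)
    norms = np.linalg.norm(g, axis=-1)
    valid = mask & ok_nb & (norms > 1e-12)
    orient = np.full(d.shape + (3,), np.nan)
    orient[valid] = g[valid] / norms[valid, None]
    out = Volume(orient, depth.voxel_size, depth.origin)
    out.n_invalid = int((mask & ~valid).sum())  # lightweight report
    return out
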