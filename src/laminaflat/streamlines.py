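"""Streamline integration through the orientation field and projection of
voxel centers onto the projection surface (the level set of depth at d*).

Depth and orientation are made continuous by trilinear interpolation of the
voxel-center samples (orientation renormalized after blending). Streamlines
are integrated with fixed-step RK2 (midpoint), forward (toward the bottom,
increasing depth) until relative depth reaches 1 - eps1, then backward until
depth reaches eps0; a voxel whose integration leaves the source volume before
hitting its target depth is not eligible for flattening.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .io import Volume


class ContinuousFields:
    """Trilinear interpolants of the depth and orientation volumes.

    Sampling is exact at voxel centers; beyond the outermost centers values
    are continued by nearest neighbor (``mode='nearest'``), and the inside
    test uses the containing voxel of the source-volume mask.
    """

    def __init__(self, depth: Volume, orientation: Volume,
                 mask: np.ndarray | None = None):
        if depth.data.shape != orientation.data.shape[:3]:
            raise ValueError("depth and orientation grids differ")
        self.depth = depth
        self.orientation = orientation
        if mask is None:
            mask = ~np.isnan(depth.data)
        self.mask = mask
        # continue both fields beyond the valid region by nearest neighbor so
        # trilinear blends near the boundary are not dragged toward fill values
        from scipy.ndimage import distance_transform_edt

        d_ok = ~np.isnan(depth.data) & mask
        _, nn = distance_transform_edt(~d_ok, return_indices=True)
        self._d = depth.data[nn[0], nn[1], nn[2]]
        o = orientation.data
        o_ok = ~np.isnan(o).any(axis=-1) & mask
        if not np.array_equal(o_ok, d_ok):
            _, nn = distance_transform_edt(~o_ok, return_indices=True)
        self._o = [o[..., c][nn[0], nn[1], nn[2]] for c in range(3)]
        self.voxel_size = depth.voxel_size
        self.origin = depth.origin
        self.shape = np.array(depth.data.shape)

    def _frac_index(self, pts: np.ndarray) -> np.ndarray:
        # voxel centers sit at fractional index (i) for world origin+(i+0.5)h
        return ((pts - self.origin) / self.voxel_size - 0.5).T

    def d(self, pts: np.ndarray) -> np.ndarray:
        """Interpolated relative depth at world points (n, 3)."""
        ci = self._frac_index(np.atleast_2d(pts))
        return map_coordinates(self._d, ci, order=1, mode="nearest")

    def O(self, pts: np.ndarray) -> np.ndarray:  # noqa: E743
        """Interpolated unit orientation at world points (n, 3).

        The trilinear blend is renormalized; a zero-norm blend falls back to
        the nearest-voxel orientation.
        """
        pts = np.atleast_2d(pts)
        ci = self._frac_index(pts)
        vec = np.stack(
            [map_coordinates(c, ci, order=1, mode="nearest") for c in self._o],
            axis=1)
        norm = np.linalg.norm(vec, axis=1)
        bad = norm < 1e-9
        if bad.any():
            nearest = np.stack(
                [map_coordinates(c, ci[:, bad], order=0, mode="nearest")
                 for c in self._o], axis=1)
            vec[bad] = nearest
            norm = np.linalg.norm(vec, axis=1)
            norm[norm < 1e-30] = 1.0
        return vec / norm[:, None]

    def inside(self, pts: np.ndarray) -> np.ndarray:
        """True where the containing voxel belongs to the source volume."""
        pts = np.atleast_2d(pts)
        idx = np.floor((pts - self.origin) / self.voxel_size).astype(np.int64)
        ok = np.all((idx >= 0) & (idx < self.shape), axis=1)
        out = np.zeros(len(pts), dtype=bool)
        if ok.any():
            sub = idx[ok]
            out[ok] = self.mask[sub[:, 0], sub[:, 1], sub[:, 2]]
        return out


@dataclass
class Streamline:
    """Polyline S_v(t), t in [0, 1] linear in cumulative arc length, running
    from the top shell (t=0) to the bottom shell (t=1) through the seed."""

    points: np.ndarray           # (n, 3) μm, ordered top -> bottom
    eligible: bool
    seed_index: int              # index of the seeding point in `points`
    report: dict = field(default_factory=dict)

    @property
    def t(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        return cum / max(cum[-1], 1e-30)

    def at(self, t: float | np.ndarray) -> np.ndarray:
        """Point(s) on the linear spline at parameter t."""
        tq = np.atleast_1d(np.asarray(t, dtype=float))
        tt = self.t
        out = np.empty((len(tq), 3))
        for c in range(3):
            out[:, c] = np.interp(tq, tt, self.points[:, c])
        return out if np.ndim(t) else out[0]


def _march(fields: ContinuousFields, x0: np.ndarray, sign: float,
           stop_depth_ok, step: float, max_steps: int):
    """Vectorized RK2 march of many seeds; returns (list of per-seed point
    lists, reached flag). ``stop_depth_ok(d)`` is the termination predicate."""
    n = len(x0)
    pts = [[p.copy()] for p in x0]
    pos = x0.copy()
    active = fields.inside(pos)
    reached = stop_depth_ok(fields.d(pos)) & active
    active &= ~reached
    for _ in range(max_steps):
        if not active.any():
            break
        sub = np.where(active)[0]
        p = pos[sub]
        k1 = sign * fields.O(p)
        k2 = sign * fields.O(p + 0.5 * step * k1)
        p_new = p + step * k2
        ok = fields.inside(p_new)
        d_new = fields.d(p_new)
        done = stop_depth_ok(d_new) & ok
        for s, pn, o in zip(sub, p_new, ok):
            if o:
                pts[s].append(pn.copy())
        pos[sub[ok]] = p_new[ok]
        reached[sub[done]] = True
        active[sub[~ok]] = False
        active[sub[done]] = False
    return pts, reached


def trace_streamline(x0, fields: ContinuousFields, step: float | None = None,
                     eps0: float = 0.01, eps1: float = 0.01,
                     max_steps: int = 10_000) -> Streamline:
    """Integrate the streamline through a single point (see module docstring).

    Forward (toward depth 1 - eps1) and backward (toward depth eps0) passes
    are joined into one top->bottom polyline through ``x0``.
    """
    x0 = np.asarray(x0, dtype=float).reshape(1, 3)
    if not fields.inside(x0)[0]:
        raise ValueError(f"seed point {x0[0]} is outside the source volume")
    if step is None:
        step = 0.25 * float(np.min(fields.voxel_size))
    fwd_pts, fwd_ok = _march(fields, x0, +1.0,
                             lambda d: d >= 1.0 - eps1, step, max_steps)
    bwd_pts, bwd_ok = _march(fields, x0, -1.0,
                             lambda d: d <= eps0, step, max_steps)
    back = bwd_pts[0][::-1]
    forward = fwd_pts[0]
    points = np.array(back + forward[1:])
    eligible = bool(fwd_ok[0] and bwd_ok[0])
    endpoints_d = fields.d(points[[0, -1]])
    return Streamline(
        points=points,
        eligible=eligible,
        seed_index=len(back) - 1,
        report={"reached_top": bool(bwd_ok[0]), "reached_bottom": bool(fwd_ok[0]),
                "endpoint_depths": endpoints_d, "step": step},
    )


def project_streamline(s: Streamline, fields: ContinuousFields,
                       d_star: float, tol: float = 1e-6) -> np.ndarray | None:
    """Point S_v(t*) where F(t) = d(S_v(t)) - d* crosses zero.

    Uses bracketed bisection on the spline parameter; with several sign
    changes (noisy fields) the root closest in arc length to the seed is
    taken, preserving locality of the projection. Returns None when F never
    changes sign.
    """
    if not s.eligible:
        raise ValueError("cannot project an ineligible streamline")
    tt = s.t
    F = fields.d(s.points) - d_star
    sign_change = np.where(F[:-1] * F[1:] <= 0)[0]
    exact = np.where(F == 0)[0]
    if len(sign_change) == 0 and len(exact) == 0:
        return None
    t_seed = tt[s.seed_index]
    candidates = []
    for i in sign_change:
        lo, hi = tt[i], tt[i + 1]
        flo = F[i]
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            fm = float(fields.d(s.at(mid).reshape(1, 3))[0]) - d_star
            if abs(fm) < tol:
                lo = hi = mid
                break
            if flo * fm <= 0:
                hi = mid
            else:
                lo, flo = mid, fm
        candidates.append(0.5 * (lo + hi))
    for i in exact:
        candidates.append(tt[i])
    t_star = min(candidates, key=lambda t: abs(t - t_seed))
    return s.at(t_star)


@dataclass
class ProjectionResult:
    points: np.ndarray     # (nx, ny, nz, 3) projected voxel centers, NaN if not
    eligible: np.ndarray   # (nx, ny, nz) bool
    report: dict = field(default_factory=dict)


def project_voxels(fields: ContinuousFields, d_star: float = 0.5,
                   step: float | None = None, eps0: float = 0.01,
                   eps1: float = 0.01, max_steps: int = 10_000,
                   mask: np.ndarray | None = None) -> ProjectionResult:
    """Project every source-volume voxel center onto the projection surface
    along its streamline (batch form of trace + project).

    Integrates all seeds simultaneously; each seed records the bracketing
    step where its depth crosses d*, refined by bisection along the last RK2
    chord. Eligibility additionally requires the forward pass to reach depth
    1 - eps1 and the backward pass to reach eps0 inside the source volume.
    """
    if mask is None:
        mask = fields.mask
    if step is None:
        step = 0.25 * float(np.min(fields.voxel_size))
    vol = Volume(np.zeros(tuple(fields.shape), dtype=np.uint8),
                 fields.voxel_size, fields.origin)
    seeds = vol.voxel_centers(mask)
    n = len(seeds)

    reached = {}
    crossing = {"lo": np.full((n, 3), np.nan), "hi": np.full((n, 3), np.nan),
                "found": np.zeros(n, dtype=bool)}

    d_seed = fields.d(seeds)

    for sign, name, stop in ((+1.0, "fwd", lambda d: d >= 1.0 - eps1),
                             (-1.0, "bwd", lambda d: d <= eps0)):
        pos = seeds.copy()
        d_cur = d_seed.copy()
        active = fields.inside(pos)
        done = stop(d_cur) & active
        active &= ~done
        ok_flag = done.copy()
        for _ in range(max_steps):
            if not active.any():
                break
            sub = np.where(active)[0]
            p = pos[sub]
            k1 = sign * fields.O(p)
            k2 = sign * fields.O(p + 0.5 * step * k1)
            p_new = p + step * k2
            ok = fields.inside(p_new)
            d_new = fields.d(p_new)
            # record the d* bracket the first time it is crossed
            if sign > 0:
                cross = ((d_cur[sub] - d_star) * (d_new - d_star) <= 0) & ok
            else:
                cross = ((d_cur[sub] - d_star) * (d_new - d_star) <= 0) & ok
            new_cross = sub[cross & ~crossing["found"][sub]]
            if len(new_cross):
                sel = np.isin(sub, new_cross)
                crossing["lo"][new_cross] = p[sel]
                crossing["hi"][new_cross] = p_new[sel]
                crossing["found"][new_cross] = True
            fin = stop(d_new) & ok
            pos[sub[ok]] = p_new[ok]
            d_cur[sub[ok]] = d_new[ok]
            ok_flag[sub[fin]] = True
            active[sub[~ok]] = False
            active[sub[fin]] = False
        reached[name] = ok_flag

    eligible_flat = reached["fwd"] & reached["bwd"]
    # seeds sitting exactly on the surface
    on_surface = np.abs(d_seed - d_star) < 1e-12
    crossing["lo"][on_surface] = seeds[on_surface]
    crossing["hi"][on_surface] = seeds[on_surface]
    crossing["found"][on_surface] = True

    # bisection along the bracketing chord
    refine = crossing["found"] & eligible_flat
    lo = crossing["lo"][refine]
    hi = crossing["hi"][refine]
    if len(lo):
        flo = fields.d(lo) - d_star
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            fm = fields.d(mid) - d_star
            take_lo = flo * fm <= 0
            hi = np.where(take_lo[:, None], mid, hi)
            same = ~take_lo
            lo = np.where(same[:, None], mid, lo)
            flo = np.where(same, fm, flo)
        proj_pts = 0.5 * (lo + hi)
    else:
        proj_pts = lo

    points = np.full(tuple(fields.shape) + (3,), np.nan)
    elig = np.zeros(tuple(fields.shape), dtype=bool)
    vox_idx = np.argwhere(mask)
    ok_all = refine
    elig[tuple(vox_idx[ok_all].T)] = True
    points[tuple(vox_idx[ok_all].T)] = proj_pts
    return ProjectionResult(
        points=points,
        eligible=elig,
        report={
            "n_seeds": n,
            "n_eligible": int(ok_all.sum()),
            "n_no_crossing": int((eligible_flat & ~crossing["found"]).sum()),
            "coverage": float(ok_all.sum() / max(n, 1)),
            "step": step,
            "eps0": eps0, "eps1": eps1,
        },
    )
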