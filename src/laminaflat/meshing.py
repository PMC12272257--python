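"""Projection mesh extraction, refinement and area-preserving flattening.

The projection surface is the level set of the relative depth field at d*.
Its voxel-center point cloud is triangulated into an open surface mesh,
optionally refined by midpoint subdivision, and flattened onto a convex
border (unit square by default) with an authalic parameterization:

* ``discrete`` mode solves the linear system of the discrete authalic
  (area-preserving) weights;
* ``iterative`` mode additionally minimizes the squared deviation of flat
  triangle areas from their (rescaled) 3D areas with L-BFGS over the
  interior vertices, boundary held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage, sparse
from scipy.spatial import Delaunay

from .io import Volume

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)

UNIT_SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


# ---------------------------------------------------------------------------
# level set


def levelset_points(depth: Volume, d_star: float,
                    mask: np.ndarray | None = None) -> tuple[np.ndarray, dict]:
    """Voxel centers on the boundary between the masks d < d* and d >= d*.

    Isolated voxels and minor 26-connected components are dropped so a single
    component remains; returns (points (n,3) μm, info dict).
    """
    if not 0.0 < d_star < 1.0:
        raise ValueError("d_star must be strictly inside (0, 1)")
    d = depth.data
    if mask is None:
        mask = ~np.isnan(d)
    lower = mask & (d < d_star)
    upper = mask & ~lower
    # lower-mask voxels with a 6-neighbor in the upper (deeper) mask
    nb_upper = np.zeros_like(lower)
    for axis in range(3):
        for shift in (-1, 1):
            rolled = np.roll(upper, shift, axis=axis)
            sl = [slice(None)] * 3
            sl[axis] = slice(0, 1) if shift == 1 else slice(-1, None)
            rolled[tuple(sl)] = False
            nb_upper |= rolled
    level = lower & nb_upper
    if not level.any():
        raise ValueError(f"level set at d*={d_star} is empty")
    comp, ncomp = ndimage.label(level, structure=_STRUCT26)
    sizes = np.bincount(comp.ravel())[1:]
    keep = int(np.argmax(sizes)) + 1
    removed = int(level.sum() - sizes[keep - 1])
    level &= comp == keep
    pts = depth.world(np.argwhere(level))
    info = {"n_points": len(pts), "n_removed": removed,
            "n_components_before": int(ncomp)}
    return pts, info


# ---------------------------------------------------------------------------
# mesh types


@dataclass
class SurfaceMesh:
    vertices: np.ndarray   # (n, 3) μm
    faces: np.ndarray      # (m, 3) int

    @property
    def area_um2(self) -> float:
        return float(self.trimesh.area)

    @property
    def area_mm2(self) -> float:
        return self.area_um2 * 1e-6

    @property
    def trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    def boundary_loops(self) -> list[np.ndarray]:
        """Ordered vertex-index loops of boundary edges."""
        edges = np.sort(
            np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                            self.faces[:, [2, 0]]]), axis=1)
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        bedges = uniq[counts == 1]
        if len(bedges) == 0:
            return []
        adj: dict[int, list[int]] = {}
        for a, b in bedges:
            adj.setdefault(int(a), []).append(int(b))
            adj.setdefault(int(b), []).append(int(a))
        loops = []
        unvisited = {tuple(e) for e in bedges}
        while unvisited:
            a, b = next(iter(unvisited))
            loop = [a, b]
            unvisited.discard((a, b))
            while True:
                nxt = [v for v in adj[loop[-1]] if v != loop[-2]]
                nxt = [v for v in nxt
                       if tuple(sorted((loop[-1], v))) in unvisited]
                if not nxt:
                    break
                v = nxt[0]
                unvisited.discard(tuple(sorted((loop[-1], v))))
                if v == loop[0]:
                    break
                loop.append(v)
            loops.append(np.array(loop))
        return loops

    def validate(self) -> dict:
        tm = self.trimesh
        n_components = len(
            trimesh.graph.connected_components(tm.face_adjacency,
                                               nodes=np.arange(len(self.faces))))
        loops = self.boundary_loops()
        areas = tm.area_faces
        return {
            "n_components": int(n_components),
            "n_boundary_loops": len(loops),
            "n_degenerate": int((areas <= 0).sum()),
        }


@dataclass
class FlatMesh:
    vertices2d: np.ndarray  # (n, 2), within the convex border
    faces: np.ndarray
    report: dict = field(default_factory=dict)


@dataclass
class BorderSpec:
    """Convex border of flat space.

    ``polygon``: (k, 2) counterclockwise convex vertices (unit square by
    default); a convex parametric curve can be supplied pre-sampled as a
    polygon. Anchor correspondence: either ``anchors`` (boundary-vertex index
    of the surface mesh for each polygon corner, in loop order) or ``shift``
    (arc-length fraction by which the first boundary vertex is moved along
    the border before corners are assigned at equal arc-length fractions).
    """

    polygon: np.ndarray = field(default_factory=lambda: UNIT_SQUARE.copy())
    anchors: np.ndarray | str | None = None  # explicit ids, "auto", or shift rule
    shift: float = 0.0

    def __post_init__(self):
        self.polygon = np.asarray(self.polygon, dtype=float)
        if len(self.polygon) < 3:
            raise ValueError("border polygon needs at least 3 vertices")
        if not _is_convex_ccw(self.polygon):
            raise ValueError("border polygon must be convex (CCW)")


def _is_convex_ccw(poly: np.ndarray) -> bool:
    n = len(poly)
    cross = []
    for i in range(n):
        a, b, c = poly[i], poly[(i + 1) % n], poly[(i + 2) % n]
        u, v = b - a, c - b
        cross.append(u[0] * v[1] - u[1] * v[0])
    cross = np.array(cross)
    return bool(np.all(cross > -1e-12) and cross.sum() > 0)


# ---------------------------------------------------------------------------
# reconstruction


def reconstruct_mesh(points: np.ndarray,
                     max_edge_factor: float = 2.6) -> SurfaceMesh:
    """Triangulate a near-surface point cloud into an open mesh containing
    the input points.

    The cloud is projected on its two leading principal axes and Delaunay
    triangulated there; triangles with an edge longer than
    ``max_edge_factor`` × the median nearest-neighbor spacing are dropped
    (removes hull slivers bridging concave parts of the outline). Any point-
    cloud reconstructor meeting the same contract can be substituted.

    Raises if the result has several components or several boundary loops —
    symptoms of a defective point cloud that needs fixing upstream.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 3:
        raise ValueError("need at least 3 points")
    centered = points - points.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("points are collinear")
    uv = centered @ vt[:2].T
    tri = Delaunay(uv)
    faces = tri.simplices
    # hull slivers bridging outline concavities are artifacts of the planar
    # triangulation, so the long-edge filter acts in the projection plane
    # (3D edges may legitimately be long where the surface is steep)
    from scipy.spatial import cKDTree

    nn, _ = cKDTree(uv).query(uv, k=2)
    uv_spacing = float(np.median(nn[:, 1]))
    edge_len = np.stack([
        np.linalg.norm(uv[faces[:, 0]] - uv[faces[:, 1]], axis=1),
        np.linalg.norm(uv[faces[:, 1]] - uv[faces[:, 2]], axis=1),
        np.linalg.norm(uv[faces[:, 2]] - uv[faces[:, 0]], axis=1),
    ], axis=1)
    faces = faces[edge_len.max(axis=1) <= max_edge_factor * uv_spacing]
    # drop degenerate (zero-area) triangles
    tm = trimesh.Trimesh(points, faces, process=False)
    faces = faces[tm.area_faces > 1e-12 * uv_spacing**2]
    if len(faces) == 0:
        raise ValueError("triangulation empty after filtering")
    # orient consistently and drop unreferenced vertices
    tm = trimesh.Trimesh(points, faces, process=False)
    trimesh.repair.fix_normals(tm)
    mesh = SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
    used = np.unique(mesh.faces)
    remap = -np.ones(len(mesh.vertices), dtype=np.int64)
    remap[used] = np.arange(len(used))
    mesh = SurfaceMesh(mesh.vertices[used], remap[mesh.faces])
    report = mesh.validate()
    if report["n_components"] != 1:
        raise ValueError(
            f"reconstruction produced {report['n_components']} components; "
            "fix the input point cloud (detached clusters?)")
    if report["n_boundary_loops"] != 1:
        raise ValueError(
            f"reconstruction produced {report['n_boundary_loops']} boundary "
            "loops; fix the input point cloud (holes?)")
    return mesh


def refine_mesh(mesh: SurfaceMesh, times: int = 1) -> SurfaceMesh:
    """Midpoint 1->4 subdivision, ``times`` passes. Parent vertices keep
    their indices (correspondence retained); geometry is unchanged because
    child triangles are coplanar with their parents."""
    if times < 0:
        raise ValueError("times must be >= 0")
    v, f = mesh.vertices, mesh.faces
    for _ in range(times):
        v, f = trimesh.remesh.subdivide(v, f)
    return SurfaceMesh(np.asarray(v), np.asarray(f))


def refine_to_target(mesh: SurfaceMesh, target_vertices: int,
                     max_passes: int = 6) -> tuple[SurfaceMesh, int]:
    """Subdivide until the vertex count reaches ``target_vertices`` (e.g. the
    source-volume voxel count) or ``max_passes`` is hit."""
    passes = 0
    while len(mesh.vertices) < target_vertices and passes < max_passes:
        mesh = refine_mesh(mesh, 1)
        passes += 1
    return mesh, passes


# ---------------------------------------------------------------------------
# flattening


def _loop_fractions(vertices: np.ndarray, loop: np.ndarray) -> np.ndarray:
    """Cumulative 3D arc-length fraction of each boundary vertex."""
    pts3 = vertices[loop]
    seg = np.linalg.norm(np.roll(pts3, -1, axis=0) - pts3, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    return cum[:-1] / cum[-1]


def _auto_corners(vertices: np.ndarray, loop: np.ndarray, k: int) -> np.ndarray:
    """Positions (in loop order) of the k boundary vertices with the
    sharpest turning angles, at least nb/(2k) apart along the loop."""
    nb = len(loop)
    pts = vertices[loop]
    # smooth over a few vertices so voxel staircase noise does not dominate
    win = max(1, nb // (8 * k))
    prev = pts[(np.arange(nb) - win) % nb]
    nxt = pts[(np.arange(nb) + win) % nb]
    v1 = pts - prev
    v2 = nxt - pts
    cosang = np.einsum("nd,nd->n", v1, v2) / np.maximum(
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1), 1e-30)
    turning = np.arccos(np.clip(cosang, -1.0, 1.0))
    min_sep = nb // (2 * k)
    chosen: list[int] = []
    for cand in np.argsort(-turning):
        if all(min(abs(cand - c), nb - abs(cand - c)) >= min_sep
               for c in chosen):
            chosen.append(int(cand))
        if len(chosen) == k:
            break
    if len(chosen) < k:
        raise ValueError("could not find enough distinct boundary corners")
    return np.sort(np.array(chosen))


def _boundary_to_border(mesh: SurfaceMesh, border: BorderSpec,
                        reverse: bool = False
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Map the mesh boundary loop onto the border polygon.

    Polygon corners are pinned to anchor boundary vertices — given
    explicitly, detected at the sharpest boundary corners (``anchors="auto"``)
    or placed at equal arc-length fractions from the shifted first vertex —
    and between anchors boundary vertices are spaced along the polygon edge
    proportionally to their cumulative 3D arc length.
    Returns (boundary vertex ids in loop order, their 2D border positions).
    """
    loops = mesh.boundary_loops()
    if len(loops) != 1:
        raise ValueError(f"mesh has {len(loops)} boundary loops, need exactly 1")
    loop = loops[0]
    if reverse:
        loop = loop[::-1]
    nb = len(loop)
    k = len(border.polygon)
    anchors = border.anchors

    if anchors is None:
        start = int(round((border.shift % 1.0) * nb)) % nb
        loop = np.roll(loop, -start)
        frac = _loop_fractions(mesh.vertices, loop)
        target = np.arange(k) / k
        anchor_pos = np.array(
            [int(np.argmin(np.abs(frac - t))) for t in target])
        anchor_pos[0] = 0
    elif isinstance(anchors, str) and anchors == "auto":
        frac = _loop_fractions(mesh.vertices, loop)
        anchor_pos = _auto_corners(mesh.vertices, loop, k)
        loop = np.roll(loop, -anchor_pos[0])
        anchor_pos = anchor_pos - anchor_pos[0]
        frac = _loop_fractions(mesh.vertices, loop)
    else:
        anchors = np.asarray(anchors)
        if len(anchors) != k:
            raise ValueError("need one anchor per border polygon corner")
        pos = []
        for a in anchors:
            where = np.where(loop == a)[0]
            if len(where) == 0:
                raise ValueError(f"anchor vertex {a} is not on the boundary loop")
            pos.append(int(where[0]))
        loop = np.roll(loop, -pos[0])
        anchor_pos = np.array(
            [int(np.where(loop == a)[0][0]) for a in anchors])
        if not np.all(np.diff(anchor_pos) > 0):
            if reverse:
                raise ValueError(
                    "anchor order does not follow the boundary loop")
            return _boundary_to_border(mesh, border, reverse=True)
        frac = _loop_fractions(mesh.vertices, loop)

    corner_frac = frac[anchor_pos]
    pos2d = np.zeros((nb, 2))
    for c in range(k):
        i0 = anchor_pos[c]
        i1 = anchor_pos[c + 1] if c + 1 < k else nb
        f0 = corner_frac[c]
        f1 = corner_frac[c + 1] if c + 1 < k else 1.0
        p0 = border.polygon[c]
        p1 = border.polygon[(c + 1) % k]
        idx = np.arange(i0, i1)
        t = (frac[idx] - f0) / max(f1 - f0, 1e-30)
        pos2d[idx] = p0 + t[:, None] * (p1 - p0)
    return loop, pos2d


def _authalic_weights(mesh: SurfaceMesh) -> sparse.csr_matrix:
    """Discrete authalic weight matrix W (nonsymmetric):
    w_ij = (cot γ + cot δ) / |x_i − x_j|², with γ, δ the angles adjacent to
    edge (i, j) at vertex j in the two incident triangles."""
    v = mesh.vertices
    n = len(v)
    rows, cols, vals = [], [], []
    f = mesh.faces
    for (a, b, c) in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
        i, j, k = f[:, a], f[:, b], f[:, c]
        # angle at j between edges (j->i) and (j->k) contributes to w_ij;
        # same angle contributes to w_kj for edge (k, j)
        e_ji = v[i] - v[j]
        e_jk = v[k] - v[j]
        cross = np.linalg.norm(np.cross(e_ji, e_jk), axis=1)
        dot = np.einsum("nd,nd->n", e_ji, e_jk)
        cot = dot / np.maximum(cross, 1e-30)
        len_ij2 = np.einsum("nd,nd->n", e_ji, e_ji)
        len_kj2 = np.einsum("nd,nd->n", v[k] - v[j], v[k] - v[j])
        rows.extend([i, k])
        cols.extend([j, j])
        vals.extend([cot / len_ij2, cot / len_kj2])
    W = sparse.coo_matrix(
        (np.concatenate(vals),
         (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)).tocsr()
    return W


def _solve_convex_combination(W: sparse.csr_matrix, boundary: np.ndarray,
                              boundary_pos: np.ndarray, n: int) -> np.ndarray:
    """Solve x_i = Σ_j w_ij x_j / Σ_j w_ij for interior i, boundary fixed."""
    is_b = np.zeros(n, dtype=bool)
    is_b[boundary] = True
    interior = np.where(~is_b)[0]
    x = np.zeros((n, 2))
    x[boundary] = boundary_pos
    rowsum = np.asarray(W.sum(axis=1)).ravel()
    D = sparse.diags(rowsum)
    L = (D - W).tocsr()
    A = L[interior][:, interior]
    B = L[interior][:, is_b]
    rhs = -B @ x[is_b]
    lu = sparse.linalg.splu(A.tocsc())
    x[interior] = np.column_stack([lu.solve(rhs[:, 0]), lu.solve(rhs[:, 1])])
    return x


def _triangle_areas_2d(x: np.ndarray, faces: np.ndarray) -> np.ndarray:
    p, q, r = x[faces[:, 0]], x[faces[:, 1]], x[faces[:, 2]]
    return 0.5 * ((q[:, 0] - p[:, 0]) * (r[:, 1] - p[:, 1])
                  - (q[:, 1] - p[:, 1]) * (r[:, 0] - p[:, 0]))


def _area_energy_grad(x: np.ndarray, faces: np.ndarray, target: np.ndarray
                      ) -> tuple[float, np.ndarray]:
    a = _triangle_areas_2d(x, faces)
    resid = (a - target) / np.sqrt(target)
    energy = float(np.sum(resid**2))
    coeff = 2.0 * resid / np.sqrt(target)  # dE/da per triangle
    grad = np.zeros_like(x)
    p, q, r = faces[:, 0], faces[:, 1], faces[:, 2]
    for corner, e0, e1 in ((p, q, r), (q, r, p), (r, p, q)):
        ga = 0.5 * np.stack(
            [x[e0][:, 1] - x[e1][:, 1], x[e1][:, 0] - x[e0][:, 0]], axis=1)
        np.add.at(grad, corner, coeff[:, None] * ga)
    return energy, grad


def flatten_mesh(mesh: SurfaceMesh, border: BorderSpec | None = None,
                 mode: str = "discrete", max_iter: int = 2000,
                 tol: float = 1e-9) -> FlatMesh:
    """Flatten a single-component, single-boundary-loop mesh onto a convex
    border with an authalic parameterization (see module docstring)."""
    if border is None:
        border = BorderSpec()
    check = mesh.validate()
    if check["n_components"] != 1:
        raise ValueError("mesh must have a single connected component")
    if check["n_degenerate"]:
        raise ValueError(f"mesh has {check['n_degenerate']} degenerate triangles")
    loop, pos2d = _boundary_to_border(mesh, border)
    W = _authalic_weights(mesh)
    x = _solve_convex_combination(W, loop, pos2d, len(mesh.vertices))
    # an orientation-reversing boundary walk mirrors the whole parameterization
    if _triangle_areas_2d(x, mesh.faces).sum() < 0:
        loop, pos2d = _boundary_to_border(mesh, border, reverse=True)
        x = _solve_convex_combination(W, loop, pos2d, len(mesh.vertices))

    n_iter = 0
    if mode == "iterative":
        from scipy.optimize import minimize

        tm_areas = mesh.trimesh.area_faces
        poly = border.polygon
        poly_area = 0.5 * abs(np.sum(
            poly[:, 0] * np.roll(poly[:, 1], -1)
            - np.roll(poly[:, 0], -1) * poly[:, 1]))
        target = tm_areas / tm_areas.sum() * poly_area
        is_b = np.zeros(len(x), dtype=bool)
        is_b[loop] = True
        interior = ~is_b
        x_work = x.copy()

        def fun(flat_vars):
            x_work[interior] = flat_vars.reshape(-1, 2)
            e, g = _area_energy_grad(x_work, mesh.faces, target)
            return e, g[interior].ravel()

        res = minimize(fun, x[interior].ravel(), jac=True, method="L-BFGS-B",
                       options={"maxiter": max_iter, "ftol": tol,
                                "gtol": 1e-12})
        x[interior] = res.x.reshape(-1, 2)
        n_iter = int(res.nit)
        if not res.success and res.nit >= max_iter:
            raise RuntimeError(
                f"iterative flattening did not converge in {max_iter} "
                f"iterations (residual energy {res.fun:.3g})")
    elif mode != "discrete":
        raise ValueError(f"unknown mode {mode!r}")

    a2 = _triangle_areas_2d(x, mesh.faces)
    a3 = mesh.trimesh.area_faces
    f2 = a2 / a2.sum()
    f3 = a3 / a3.sum()
    n_inverted = int((a2 <= 0).sum())
    report = {
        "n_inverted": n_inverted,
        "inverted_fraction": n_inverted / len(a2),
        "area_fraction_abs_diff_mean": float(np.mean(np.abs(f2 - f3))),
        "area_distortion_rel_mean": float(np.mean(np.abs(f2 - f3) / f3)),
        "area_distortion_rel_median": float(np.median(np.abs(f2 - f3) / f3)),
        "mode": mode,
        "n_iterations": n_iter,
    }
    if report["inverted_fraction"] > 1e-3:
        import warnings

        warnings.warn(
            f"{n_inverted} inverted triangles "
            f"({100 * report['inverted_fraction']:.2f}%) in flat mesh")
    return FlatMesh(x, mesh.faces.copy(), report)
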