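"""End-to-end orchestration: fields -> projection mesh -> streamlines ->
flatmap -> metrics, with sensible defaults for desk-scale volumes."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Flatmap, Volume
from .flatmap import PixelGrid, build_flatmap, discretize
from .meshing import (BorderSpec, FlatMesh, SurfaceMesh, flatten_mesh,
                      levelset_points, reconstruct_mesh, refine_to_target)
from .metrics import (calibrate_distance_from_grids, coverage,
                      field_smoothness, orthogonality, per_pixel_metrics,
                      usage_fraction)
from .streamlines import ContinuousFields, project_voxels


@dataclass
class FlatmapResult:
    flatmap: Flatmap
    mesh: SurfaceMesh
    flat_mesh: FlatMesh
    fields: ContinuousFields
    report: dict = field(default_factory=dict)


def make_flatmap(depth: Volume, orientation: Volume,
                 mask: np.ndarray | None = None, d_star: float = 0.5,
                 border: BorderSpec | None = None, mode: str = "discrete",
                 refine_target: int | None = None, max_refine: int = 3,
                 step: float | None = None, eps0: float = 0.01,
                 eps1: float = 0.01) -> FlatmapResult:
    """Run stages I-III on given depth/orientation fields."""
    if mask is None:
        mask = ~np.isnan(depth.data)
    fields = ContinuousFields(depth, orientation, mask)

    pts, ls_info = levelset_points(depth, d_star, mask)
    mesh = reconstruct_mesh(pts)
    base_vertices = len(mesh.vertices)
    if refine_target is None:
        refine_target = int(mask.sum())
    mesh, n_passes = refine_to_target(mesh, refine_target, max_refine)
    flat = flatten_mesh(mesh, border=border, mode=mode)

    proj = project_voxels(fields, d_star=d_star, step=step,
                          eps0=eps0, eps1=eps1, mask=mask)
    fm = build_flatmap(proj, mesh, flat, d_star,
                       depth.voxel_size, depth.origin)
    return FlatmapResult(
        flatmap=fm, mesh=mesh, flat_mesh=flat, fields=fields,
        report={
            "levelset": ls_info,
            "mesh_vertices_base": base_vertices,
            "mesh_vertices": len(mesh.vertices),
            "refine_passes": n_passes,
            "flatten": flat.report,
            "projection": proj.report,
        },
    )


def quality_report(result: FlatmapResult, depth: Volume, orientation: Volume,
                   mask: np.ndarray, resolutions=(8, 16, 32),
                   shells: Volume | None = None,
                   calibration_resolutions=None) -> dict:
    """Metric suite over a fitted flatmap at the given pixel resolutions."""
    fm = result.flatmap
    out: dict = {"coverage": coverage(fm, mask)}
    ortho = orthogonality(fm, orientation)
    vals = ortho[np.isfinite(ortho)]
    out["orthogonality_median"] = float(np.median(vals)) if len(vals) else np.nan
    sm = field_smoothness(depth, orientation, shells)
    out["smoothness"] = sm.stats
    out["per_resolution"] = {}
    grids: dict[int, PixelGrid] = {}
    for N in resolutions:
        grid = discretize(fm, N)
        grids[N] = grid
        ppm = per_pixel_metrics(grid, depth)
        out["per_resolution"][N] = {
            "usage_fraction": usage_fraction(grid),
            **ppm.summary(),
        }
    if calibration_resolutions:
        cal_grids = [grids.get(N) or discretize(fm, N)
                     for N in calibration_resolutions]
        vol = fm.as_volume()
        slope, err = calibrate_distance_from_grids(cal_grids, vol)
        out["distance_factor_um"] = slope
        out["distance_factor_stderr"] = err
    return out
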