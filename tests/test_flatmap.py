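"""Flatmap composition, discretization, preimages, mirroring, flat views."""

import numpy as np
import pytest

import laminaflat as lf
from laminaflat.flatmap import (build_flatmap, discretize, flat_points,
                                flat_view, mirror_two_hemispheres,
                                nearest_vertex, preimage)
from laminaflat.io import Flatmap
from laminaflat.meshing import SurfaceMesh


# ---------------------------------------------------------------------------
# nearest vertex (operator N)


def test_nearest_vertex_exact_match_and_brute_force(shell_result):
    mesh = shell_result.mesh
    # a query equal to a vertex returns that vertex at distance 0
    idx, dist = nearest_vertex(mesh.vertices[[10]], mesh)
    assert idx[0] == 10 and dist[0] == 0.0
    rng = np.random.default_rng(2)
    lo, hi = mesh.vertices.min(0), mesh.vertices.max(0)
    pts = rng.uniform(lo, hi, size=(1000, 3))
    got, _ = nearest_vertex(pts, mesh)
    brute = np.argmin(
        np.linalg.norm(pts[:, None, :] - mesh.vertices[None], axis=2), axis=1)
    np.testing.assert_array_equal(got, brute)


def test_nearest_vertex_tie_lowest_index():
    mesh = SurfaceMesh(np.array([[0.0, 0, 0], [2, 0, 0], [1, 5, 0]]),
                       np.array([[0, 1, 2]]))
    idx, _ = nearest_vertex(np.array([[1.0, 0.0, 0.0]]), mesh)  # tie 0 vs 1
    assert idx[0] == 0


# ---------------------------------------------------------------------------
# flatmap composition


def test_build_flatmap_slab_identity_like(slab_fx, slab_result):
    fm = slab_result.flatmap
    idx = np.argwhere(slab_fx.mask)
    centers = slab_fx.depth.world(idx)
    L = 16 * 50.0
    xy = fm.coords[tuple(idx.T)]
    expect = centers[:, :2] / L
    # agreement up to axis exchange/reflection of the square and a mesh edge
    cands = [expect, expect[:, ::-1], 1 - expect, (1 - expect)[:, ::-1],
             np.column_stack([expect[:, 0], 1 - expect[:, 1]]),
             np.column_stack([1 - expect[:, 0], expect[:, 1]]),
             np.column_stack([expect[:, 1], 1 - expect[:, 0]]),
             np.column_stack([1 - expect[:, 1], expect[:, 0]])]
    err = min(np.abs(xy - c).max() for c in cands)
    assert err <= 1.0 / 16 + 1e-9  # one mesh edge length in flat units


def test_build_flatmap_composition_matches_stepwise(slab_fx, slab_result):
    """Batch ℳ equals per-voxel ℱ(N(S(v)))."""
    fm = slab_result.flatmap
    mesh, flat = slab_result.mesh, slab_result.flat_mesh
    from laminaflat.streamlines import project_voxels

    proj = project_voxels(slab_result.fields, d_star=0.5)
    rng = np.random.default_rng(0)
    idx = np.argwhere(proj.eligible)
    for i in rng.choice(len(idx), 25, replace=False):
        v = tuple(idx[i])
        p = proj.points[v]
        vi, _ = nearest_vertex(p.reshape(1, 3), mesh)
        np.testing.assert_array_equal(fm.coords[v], flat.vertices2d[vi[0]])


def test_build_flatmap_ineligible_invalid(slab_fx, slab_result):
    from laminaflat.streamlines import project_voxels

    proj = project_voxels(slab_result.fields, d_star=0.5)
    proj.eligible[3, 3, 3] = False
    fm = build_flatmap(proj, slab_result.mesh, slab_result.flat_mesh, 0.5,
                       slab_fx.depth.voxel_size, slab_fx.depth.origin)
    assert np.isnan(fm.coords[3, 3, 3]).all()
    assert fm.n_eligible == proj.eligible.sum()


def test_build_flatmap_cardinality_mismatch():
    from laminaflat.meshing import FlatMesh
    from laminaflat.streamlines import ProjectionResult

    mesh = SurfaceMesh(np.zeros((3, 3)), np.array([[0, 1, 2]]))
    flat = FlatMesh(np.zeros((2, 2)), np.array([[0, 1, 2]]))
    proj = ProjectionResult(points=np.full((1, 1, 1, 3), np.nan),
                            eligible=np.zeros((1, 1, 1), bool))
    with pytest.raises(ValueError, match="vertex counts"):
        build_flatmap(proj, mesh, flat, 0.5, 50.0, np.zeros(3))


# ---------------------------------------------------------------------------
# discretization and preimages


def _toy_flatmap():
    coords = np.full((4, 4, 2, 2), np.nan)
    rng = np.random.default_rng(9)
    vals = rng.uniform(0, 1, size=(4, 4, 2, 2))
    coords[...] = vals
    coords[0, 0, 0] = np.nan  # one ineligible voxel
    return Flatmap(coords, voxel_size=50.0, origin=np.zeros(3))


def test_discretize_binning_rules():
    coords = np.zeros((3, 1, 1, 2))
    coords[0, 0, 0] = [0.0, 0.0]
    coords[1, 0, 0] = [1.0, 1.0]   # clamps into the last bin
    coords[2, 0, 0] = [0.5, 0.25]
    fm = Flatmap(coords, voxel_size=50.0, origin=np.zeros(3))
    grid = discretize(fm, 10)
    assert grid.assignment[0, 0, 0] == 0
    assert grid.assignment[1, 0, 0] == 9 * 10 + 9
    assert grid.assignment[2, 0, 0] == 5 * 10 + 2


def test_discretize_conservation_and_n1():
    fm = _toy_flatmap()
    n_elig = fm.n_eligible
    for N in (1, 2, 3, 7):
        grid = discretize(fm, N)
        assert grid.sizes.sum() == n_elig
    assert discretize(fm, 1).sizes[0, 0] == n_elig


def test_preimage_whole_space_and_disjointness():
    fm = _toy_flatmap()
    whole = preimage(fm, np.array([[-0.01, -0.01], [1.01, -0.01],
                                   [1.01, 1.01], [-0.01, 1.01]]))
    assert len(whole) == fm.n_eligible
    left = preimage(fm, np.array([[0, 0], [0.5, 0], [0.5, 1], [0, 1.0]]))
    right = preimage(fm, np.array([[0.51, 0], [1.01, 0], [1.01, 1],
                                   [0.51, 1.0]]))
    assert len(np.intersect1d(left, right)) == 0


def test_preimage_matches_point_in_polygon_brute_force(slab_result):
    fm = slab_result.flatmap
    poly = np.array([[0.2, 0.1], [0.8, 0.3], [0.6, 0.9], [0.1, 0.7]])
    got = np.sort(preimage(fm, poly))
    from matplotlib.path import Path

    valid = fm.valid_mask
    xy = fm.coords[valid]
    lin = np.ravel_multi_index(np.argwhere(valid).T, fm.shape)
    brute = np.sort(lin[Path(poly).contains_points(xy)])
    np.testing.assert_array_equal(got, brute)


def test_preimage_circle_area_fraction_on_slab(slab_result, slab_fx):
    """Uniform slab: preimage voxel count tracks flat area fraction.

    The flat square spans the (n-1) intervals between voxel-center columns,
    so a slab of n columns per axis maps them onto the lattice {i/(n-1)}:
    the count equals the analytic lattice count exactly and the continuum
    expectation f * eligible * ((n-1)/n)^2 within 10%.
    """
    fm = slab_result.flatmap
    th = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    rad = 0.3
    circle = np.column_stack([0.5 + rad * np.cos(th), 0.5 + rad * np.sin(th)])
    got = len(preimage(fm, circle))
    n = slab_fx.annotation.shape[0]
    nz = slab_fx.annotation.shape[2]
    i = np.arange(n) / (n - 1)
    inside = ((i[:, None] - 0.5) ** 2 + (i[None, :] - 0.5) ** 2) <= rad ** 2
    assert got == inside.sum() * nz
    f = np.pi * rad ** 2
    assert got == pytest.approx(f * fm.n_eligible * ((n - 1) / n) ** 2,
                                rel=0.10)


# ---------------------------------------------------------------------------
# mirroring


def test_mirror_two_hemispheres_coordinates_and_involution():
    coords = np.full((4, 2, 2, 2), np.nan)
    # right hemisphere = indices 2..3 along axis 0 carries the map
    coords[2, 0, 0] = [0.3, 0.4]
    coords[3, 1, 1] = [0.9, 0.2]
    fm = Flatmap(coords, voxel_size=50.0, origin=np.zeros(3))
    both = mirror_two_hemispheres(fm, axis=0)
    assert both.x_range == (0.0, 2.0)
    np.testing.assert_allclose(both.coords[1, 0, 0], [1.7, 0.4])
    np.testing.assert_allclose(both.coords[0, 1, 1], [1.1, 0.2])
    # hemisphere preimages disjoint: left x > 1, right x < 1 here
    assert both.coords[2, 0, 0][0] < 1.0 < both.coords[1, 0, 0][0]
    # mirroring an already two-hemisphere map changes nothing
    again = mirror_two_hemispheres(both, axis=0)
    np.testing.assert_array_equal(
        np.nan_to_num(again.coords), np.nan_to_num(both.coords))
    # the mirror of the mirror voxel carries the original coordinates
    np.testing.assert_allclose(2.0 - both.coords[1, 0, 0][0],
                               fm.coords[2, 0, 0][0])


def test_mirror_keeps_invalid_where_source_invalid():
    coords = np.full((2, 1, 1, 2), np.nan)
    coords[1, 0, 0] = [0.5, 0.5]
    fm = Flatmap(coords, voxel_size=50.0, origin=np.zeros(3))
    both = mirror_two_hemispheres(fm, axis=0)
    np.testing.assert_allclose(both.coords[0, 0, 0], [1.5, 0.5])
    # now make the source voxel invalid: its mirror stays invalid
    coords2 = np.full((2, 1, 1, 2), np.nan)
    fm2 = Flatmap(coords2, voxel_size=50.0, origin=np.zeros(3))
    both2 = mirror_two_hemispheres(fm2, axis=0)
    assert np.isnan(both2.coords).all()


# ---------------------------------------------------------------------------
# flat views and flat points


def test_flat_view_constant_and_mode_tie(slab_result, slab_fx):
    fm = slab_result.flatmap
    grid = discretize(fm, 4)
    img = flat_view(grid, np.full(fm.shape, 7.0), "mode")
    assert (img.compressed() == 7.0).all()
    # mode with a tie resolves to the smallest label
    labels = np.ones(fm.shape)
    labels[:, :, :8] = 2.0  # half the depth -> tie 1 vs 2 in early pixels?
    img2 = flat_view(discretize(fm, 1), labels, "mode")
    vals, counts = np.unique(labels[fm.valid_mask], return_counts=True)
    expect = vals[np.argmax(counts)] if counts[0] != counts[1] else 1.0
    assert img2[0, 0] == expect


def test_flat_view_max_matches_brute_force(slab_result, slab_fx):
    fm = slab_result.flatmap
    rng = np.random.default_rng(4)
    vol = rng.normal(size=fm.shape)
    grid = discretize(fm, 8)
    img = flat_view(grid, vol, "max")
    flat_vals = vol.reshape(-1)
    for i in range(8):
        for j in range(8):
            pre = grid.preimage(i, j)
            if len(pre):
                assert img[i, j] == flat_vals[pre].max()
            else:
                assert img.mask[i, j]


def test_flat_view_mean_and_unknown_aggregator(slab_result):
    grid = discretize(slab_result.flatmap, 2)
    vol = np.ones(slab_result.flatmap.shape)
    img = flat_view(grid, vol, "mean")
    np.testing.assert_allclose(img.compressed(), 1.0)
    with pytest.raises(ValueError, match="aggregator"):
        flat_view(grid, vol, "median")


def test_flat_points_lookup_and_drop(slab_fx, slab_result):
    fm = slab_result.flatmap
    idx = np.array([[4, 5, 6], [10, 2, 0]])
    pts = slab_fx.depth.world(idx)
    out_pt = np.array([[-500.0, 0.0, 0.0]])  # outside the volume
    xy, keep, dropped = flat_points(fm, np.vstack([pts, out_pt]))
    assert dropped == 1 and keep.sum() == 2
    np.testing.assert_array_equal(xy[0], fm.coords[4, 5, 6])
    np.testing.assert_array_equal(xy[1], fm.coords[10, 2, 0])
    # batch equals per-point lookup
    for p, x in zip(pts, xy):
        single, k, _ = flat_points(fm, p.reshape(1, 3))
        np.testing.assert_array_equal(single[0], x)
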