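"""Depth / thickness / orientation field generation, both routes."""

import numpy as np
import pytest

import laminaflat as lf
from laminaflat.fields import (extract_boundary_candidates,
                               fields_from_segments, laplace_depth,
                               orientation_from_gradient,
                               point_segment_distance, shortest_segments,
                               validate_shells)
from laminaflat.io import BOTTOM, EXTERIOR, INTERIOR, SIDE, TOP, Volume


# ---------------------------------------------------------------------------
# boundary candidates


def brute_force_boundary(mask):
    out = np.zeros_like(mask)
    n = mask.shape
    for i, j, k in np.argwhere(mask):
        touches = False
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    a, b, c = i + di, j + dj, k + dk
                    if not (0 <= a < n[0] and 0 <= b < n[1] and 0 <= c < n[2]):
                        touches = True
                    elif not mask[a, b, c]:
                        touches = True
        out[i, j, k] = touches
    return out


def test_boundary_candidates_cube_counts():
    mask = np.zeros((5, 5, 5), bool)
    mask[1:4, 1:4, 1:4] = True  # 3x3x3 solid cube
    b = extract_boundary_candidates(mask)
    assert b.sum() == 26
    assert (mask & ~b).sum() == 1


def test_boundary_candidates_matches_brute_force_scan():
    rng = np.random.default_rng(7)
    mask = rng.random((10, 10, 10)) < 0.6
    mask[0, 0, 0] = True  # guarantee nonempty
    got = extract_boundary_candidates(mask)
    np.testing.assert_array_equal(got, brute_force_boundary(mask))
    # a solid 10-cube has 10^3 - 8^3 = 488 boundary voxels
    solid = np.ones((10, 10, 10), bool)
    assert extract_boundary_candidates(solid).sum() == 488


def test_boundary_candidates_single_voxel_and_empty():
    mask = np.zeros((3, 3, 3), bool)
    with pytest.raises(ValueError):
        extract_boundary_candidates(mask)
    mask[1, 1, 1] = True
    b = extract_boundary_candidates(mask)
    assert b.sum() == 1 and (mask & ~b).sum() == 0


# ---------------------------------------------------------------------------
# shell validation


def test_validate_shells_correct_slab(slab_fx):
    rep = validate_shells(slab_fx.shells)
    assert rep.violations == [] and not rep.fatal
    assert rep.counts["top"] == 16 * 16


def test_validate_shells_flags_buried_top_and_empty_bottom(slab_fx):
    labels = slab_fx.shells.data.copy()
    labels[8, 8, 8] = TOP  # interior voxel mislabeled as top
    rep = validate_shells(slab_fx.shells.like(labels))
    assert any("not touching exterior" in v for v in rep.violations)
    labels = slab_fx.shells.data.copy()
    labels[labels == BOTTOM] = SIDE
    rep = validate_shells(slab_fx.shells.like(labels))
    assert rep.fatal and any("empty bottom" in v for v in rep.violations)


# ---------------------------------------------------------------------------
# shortest segments


def test_shortest_segments_slab_all_vertical(slab_fx):
    segs = shortest_segments(slab_fx.shells)
    H = (slab_fx.annotation.shape[2] - 1) * 50.0
    np.testing.assert_allclose(segs.lengths, H)
    np.testing.assert_allclose(segs.directions, [[0.0, 0.0, 1.0]] * len(segs))
    # one segment through every top voxel column, both pairing directions
    assert len(segs) == 2 * 16 * 16


def test_shortest_segments_match_all_pairs_brute_force():
    # random blob <= 10^3 voxels with top/bottom planes
    rng = np.random.default_rng(11)
    shape = (8, 8, 8)
    labels = np.full(shape, INTERIOR, np.uint8)
    top = rng.random((8, 8)) < 0.5
    bot = rng.random((8, 8)) < 0.5
    top[0, 0] = bot[0, 0] = True
    labels[:, :, 0][top] = TOP
    labels[:, :, 7][bot] = BOTTOM
    shells = Volume(labels, voxel_size=13.0, origin=[3.0, 1.0, 0.0])
    segs = shortest_segments(shells)

    tops = shells.world(np.argwhere(labels == TOP))
    bots = shells.world(np.argwhere(labels == BOTTOM))
    expect = []
    for p in tops:
        d = np.linalg.norm(bots - p, axis=1)
        expect.append((tuple(p), tuple(bots[np.argmin(d)])))
    for q in bots:
        d = np.linalg.norm(tops - q, axis=1)
        expect.append((tuple(tops[np.argmin(d)]), tuple(q)))
    got = sorted(zip(map(tuple, segs.p_top), map(tuple, segs.p_bottom)))
    assert got == sorted(expect)


def test_point_segment_distance_matches_naive():
    rng = np.random.default_rng(5)
    pts = rng.normal(size=(20, 3))
    p0 = rng.normal(size=(7, 3))
    p1 = rng.normal(size=(7, 3))
    got = point_segment_distance(pts, p0, p1)
    for i, x in enumerate(pts):
        for j in range(7):
            seg = p1[j] - p0[j]
            t = np.clip(np.dot(x - p0[j], seg) / np.dot(seg, seg), 0, 1)
            want = np.linalg.norm(x - (p0[j] + t * seg))
            assert got[i, j] == pytest.approx(want, abs=1e-12)


# ---------------------------------------------------------------------------
# fields from segments


def test_fields_from_segments_slab_exact(slab_fx):
    segs = shortest_segments(slab_fx.shells)
    fs = fields_from_segments(slab_fx.shells, segs, n_segments=8)
    np.testing.assert_allclose(fs.depth.data, slab_fx.depth.data, atol=1e-9)
    np.testing.assert_allclose(fs.orientation.data, slab_fx.orientation.data)
    np.testing.assert_allclose(fs.thickness.data, slab_fx.thickness.data)
    # midplane voxel sits at depth one half
    assert fs.depth.data[4, 4, 8] == pytest.approx(0.5, abs=1e-9)
    assert fs.report["n_side_exit"] == 0


def test_fields_from_segments_full_averaging_is_constant(slab_fx):
    """With n_segments = |segs| every voxel sees the same average."""
    segs = shortest_segments(slab_fx.shells)
    fs = fields_from_segments(slab_fx.shells, segs, n_segments=len(segs))
    o = fs.orientation.data[slab_fx.mask]
    assert np.allclose(o, o[0])
    t = fs.thickness.data[slab_fx.mask]
    assert np.allclose(t, t[0])


def test_fields_from_segments_curved_shell(shell_fx):
    segs = shortest_segments(shell_fx.shells)
    fs = fields_from_segments(shell_fx.shells, segs, n_segments=100)
    mask = shell_fx.mask
    o = fs.orientation.data[mask]
    radial = shell_fx.orientation.data[mask]
    cos = np.einsum("nd,nd->n", o, radial)
    ang = np.degrees(np.arccos(np.clip(cos, -1, 1)))
    assert np.median(ang) < 5.0
    # center-to-center thickness within 1 voxel of the analytic value
    span = np.nanmedian(shell_fx.thickness.data)
    assert abs(np.median(fs.thickness.data[mask]) - span) < 25.0


def test_fields_from_segments_rejects_bad_n(slab_fx):
    segs = shortest_segments(slab_fx.shells)
    with pytest.raises(ValueError):
        fields_from_segments(slab_fx.shells, segs, n_segments=0)
    with pytest.raises(ValueError):
        fields_from_segments(slab_fx.shells, segs, n_segments=len(segs) + 1)


# ---------------------------------------------------------------------------
# Laplace route


def test_laplace_depth_slab_is_linear(slab_fx):
    d = laplace_depth(slab_fx.shells)
    assert np.nanmax(np.abs(d.data - slab_fx.depth.data)) < 1e-6
    # defining property: interior discrete Laplacian ~ 0
    lap = (np.diff(d.data, 2, axis=2))[:, :, :].max()
    assert abs(lap) < 1e-9


def test_laplace_depth_shell_matches_closed_form(shell_fx, shell_laplace):
    interior = shell_fx.shells.data == INTERIOR
    err = np.abs(shell_laplace.data - shell_fx.depth.data)[interior]
    assert np.nanmax(err) < 0.02


def test_laplace_depth_errors():
    labels = np.full((6, 6, 6), EXTERIOR, np.uint8)
    labels[1:3, 1:3, 1:3] = INTERIOR
    labels[1, 1, 1] = TOP
    labels[2, 2, 2] = BOTTOM
    labels[5, 5, 5] = INTERIOR  # island touching neither shell
    with pytest.raises(ValueError, match="component"):
        laplace_depth(Volume(labels, 1.0))
    labels[5, 5, 5] = EXTERIOR
    labels[labels == TOP] = SIDE
    with pytest.raises(ValueError, match="nonempty"):
        laplace_depth(Volume(labels, 1.0))


# ---------------------------------------------------------------------------
# orientation from gradient


def test_orientation_from_gradient_slab(slab_fx):
    o = orientation_from_gradient(slab_fx.depth, slab_fx.mask)
    valid = ~np.isnan(o.data).any(axis=-1)
    assert valid.any()
    np.testing.assert_allclose(o.data[valid],
                               [[0.0, 0.0, 1.0]] * valid.sum(), atol=1e-12)


def test_orientation_from_gradient_shell_radial(shell_fx, shell_laplace):
    from scipy import ndimage

    o = orientation_from_gradient(shell_laplace, shell_fx.mask)
    interior = shell_fx.shells.data == INTERIOR
    away = ndimage.binary_erosion(interior, np.ones((3, 3, 3), bool),
                                  iterations=2, border_value=0)
    ov = o.data[away]
    rv = shell_fx.orientation.data[away]
    ok = ~np.isnan(ov).any(axis=1)
    ang = np.degrees(np.arccos(np.clip(
        np.einsum("nd,nd->n", ov[ok], rv[ok]), -1, 1)))
    assert ang.max() < 3.0


def test_orientation_from_gradient_constant_field_all_invalid():
    d = Volume(np.full((5, 5, 5), 0.5), 1.0)
    o = orientation_from_gradient(d)
    assert np.isnan(o.data).all()
    assert o.n_invalid == 125
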