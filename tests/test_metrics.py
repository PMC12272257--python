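"""Field-smoothness and flatmap quality metrics, radius fit, calibration."""

import numpy as np
import pytest
from scipy import stats

import laminaflat as lf
from laminaflat.flatmap import discretize
from laminaflat.io import Flatmap, Volume
from laminaflat.metrics import (calibrate_area, calibrate_distance, coverage,
                                field_smoothness, mean_preimage_radius,
                                orthogonality, per_pixel_metrics,
                                preimage_radius, pyramid_radial_density,
                                square_radial_arc, usage_fraction)


# ---------------------------------------------------------------------------
# global metrics


def test_coverage_values(slab_fx, slab_result):
    fm = slab_result.flatmap
    assert coverage(fm, slab_fx.mask) == 1.0
    # force 10 of the voxels ineligible -> arithmetic fraction
    coords = fm.coords.copy()
    idx = np.argwhere(slab_fx.mask)[:10]
    coords[tuple(idx.T)] = np.nan
    fm2 = Flatmap(coords, fm.voxel_size, fm.origin)
    n = slab_fx.mask.sum()
    assert coverage(fm2, slab_fx.mask) == pytest.approx((n - 10) / n)
    with pytest.raises(ValueError):
        coverage(fm, np.zeros_like(slab_fx.mask))


def test_usage_fraction_counting(slab_result):
    fm = slab_result.flatmap
    assert usage_fraction(discretize(fm, 1)) == 1.0
    grid = discretize(fm, 8)
    # brute-force distinct occupied pixels
    xy = fm.coords[fm.valid_mask]
    ij = np.clip((xy * 8).astype(int), 0, 7)
    brute = len(np.unique(ij[:, 0] * 8 + ij[:, 1])) / 64
    assert usage_fraction(grid) == brute
    # far above the lateral voxel count: pigeonhole forces holes
    assert usage_fraction(discretize(fm, 64)) < 1.0


# ---------------------------------------------------------------------------
# orthogonality


def test_orthogonality_slab_unity(slab_fx, slab_result):
    cosv = orthogonality(slab_result.flatmap, slab_fx.orientation)
    interior = np.isfinite(cosv)
    assert np.nanmedian(cosv[interior]) == pytest.approx(1.0, abs=1e-9)


def test_orthogonality_axis_swap_flips_sign(slab_fx, slab_result):
    fm = slab_result.flatmap
    swapped = Flatmap(fm.coords[..., ::-1], fm.voxel_size, fm.origin)
    a = orthogonality(fm, slab_fx.orientation)
    b = orthogonality(swapped, slab_fx.orientation)
    # the global sense is re-chosen toward the bottom shell in both cases
    assert np.nanmedian(a) > 0 and np.nanmedian(b) > 0


# ---------------------------------------------------------------------------
# smoothness


def test_field_smoothness_exact_zeros(slab_fx):
    rep = field_smoothness(slab_fx.depth, slab_fx.orientation, slab_fx.shells)
    assert rep.stats["laplacian"]["median"] == 0.0
    assert rep.stats["laplacian"]["iqr"] == 0.0
    assert rep.stats["divergence"]["median"] == 0.0
    interior = slab_fx.shells.data == lf.INTERIOR
    assert np.all(rep.laplacian[interior] == 0.0)  # dyadic depth: exact
    assert np.all(rep.divergence[interior] == 0.0)


def test_field_smoothness_harmonic_shell(shell_fx, shell_laplace):
    rep = field_smoothness(shell_laplace, shell_fx.orientation,
                           shell_fx.shells)
    # harmonic field: median |Laplacian| at solver tolerance, in 1/μm² units
    assert abs(rep.stats["laplacian"]["median"]) < 1e-9


# ---------------------------------------------------------------------------
# per-pixel metrics


def test_per_pixel_metrics_uniform_slab(slab_fx, slab_result):
    grid = discretize(slab_result.flatmap, 8)
    ppm = per_pixel_metrics(grid, slab_fx.depth)
    nonempty = np.isfinite(ppm.uniformity)
    assert np.nanmean(ppm.uniformity[nonempty]) == pytest.approx(100.0)
    assert np.all(ppm.connectedness[nonempty] == 1.0)
    assert np.all(ppm.continuity[nonempty] == 1.0)
    # cylinder-like preimages: conicity is a small fraction of the mean count
    assert np.all(np.abs(ppm.conicity_norm[nonempty]) < 0.05)


def test_connectedness_split_preimage_ratio():
    from laminaflat.metrics import _largest_component_fraction

    shape = (200, 10, 10)
    a = np.arange(70)              # 70-voxel run
    b = np.arange(100, 130)        # separated 30-voxel run
    lin = np.concatenate([np.ravel_multi_index((a, np.zeros_like(a),
                                                np.zeros_like(a)), shape),
                          np.ravel_multi_index((b, np.zeros_like(b),
                                                np.zeros_like(b)), shape)])
    assert _largest_component_fraction(lin, shape) == pytest.approx(0.70)


def test_conicity_sign_on_shell_with_top_outer(shell_fx_top_outer):
    """More volume at low depth (outer top) -> negative slope; sign verified
    against a Monte-Carlo wedge oracle."""
    from laminaflat.meshing import BorderSpec

    triangle = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
    fx = shell_fx_top_outer
    res = lf.make_flatmap(fx.depth, fx.orientation, mask=fx.mask, d_star=0.5,
                          border=BorderSpec(polygon=triangle, anchors="auto"),
                          eps0=0.05, eps1=0.05)
    grid = discretize(res.flatmap, 8)
    ppm = per_pixel_metrics(grid, fx.depth)
    con = ppm.conicity[np.isfinite(ppm.conicity)]
    assert np.median(con) < 0
    assert (con < 0).mean() > 0.9

    # Monte-Carlo wedge oracle: sample a radial wedge uniformly in volume,
    # bin by the same harmonic depth, fit a slope -> negative
    rng = np.random.default_rng(0)
    a, b = fx.meta["a_center_vox"], fx.meta["b_center_vox"]
    u = rng.random(20000)
    r = (a ** 3 + u * (b ** 3 - a ** 3)) ** (1 / 3)  # volume-uniform radii
    d = 1.0 - (1 / a - 1 / r) / (1 / a - 1 / b)      # top on the outer surface
    hist, edges = np.histogram(d, bins=10, range=(0, 1))
    centers = 0.5 * (edges[:-1] + edges[1:])
    slope = np.polyfit(centers, hist, 1)[0]
    assert slope < 0


# ---------------------------------------------------------------------------
# preimage radius: analytic density vs Monte-Carlo sampler, then recovery


def test_square_radial_density_matches_monte_carlo():
    rng = np.random.default_rng(12)
    a = 1.0
    xy = rng.uniform(-a, a, size=(200000, 2))
    r = np.linalg.norm(xy, axis=1)
    hist, edges = np.histogram(r, bins=30, range=(0, a * np.sqrt(2)),
                               density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    model = square_radial_arc(centers, a) / (4 * a ** 2)
    assert np.abs(hist - model).max() < 0.05 * model.max()


def test_pyramid_radial_density_matches_monte_carlo():
    rng = np.random.default_rng(13)
    r0, r1 = 1.0, 2.0
    z = rng.random(400000)
    az = r0 + (r1 - r0) * z
    keep = rng.random(400000) < (az / r1) ** 2   # volume-weight the slices
    az = az[keep][:150000]
    x = rng.uniform(-1, 1, len(az)) * az
    y = rng.uniform(-1, 1, len(az)) * az
    r = np.hypot(x, y)
    hist, edges = np.histogram(r, bins=30, range=(0, r1 * np.sqrt(2)),
                               density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    model = pyramid_radial_density(centers, r0, r1)
    assert np.abs(hist - model).max() < 0.05 * model.max()


def test_preimage_radius_recovers_prism_and_pyramid():
    rng = np.random.default_rng(42)
    n = 20000
    a = 100.0
    pts = np.column_stack([rng.uniform(-a, a, n), rng.uniform(-a, a, n),
                           rng.uniform(0, 400, n)])
    rad, r0, r1, flagged = preimage_radius(pts, 25.0)
    assert not flagged
    assert rad == pytest.approx(a, rel=0.05)

    # truncated pyramid with half-widths 2 and 4 voxels (voxel = 25 μm)
    z = rng.random(2 * n)
    az = 50.0 + 50.0 * z
    keep = rng.random(2 * n) < (az / 100.0) ** 2
    z, az = z[keep][:n], az[keep][:n]
    x = rng.uniform(-1, 1, n) * az
    y = rng.uniform(-1, 1, n) * az
    pts = np.column_stack([x, y, z * 400.0])
    rad, r0, r1, flagged = preimage_radius(pts, 25.0)
    assert not flagged
    assert rad == pytest.approx(75.0, rel=0.10)


def test_preimage_radius_degenerate_fallback():
    rad, r0, r1, flagged = preimage_radius(np.zeros((1, 3)), 50.0)
    assert flagged and rad == 25.0
    line = np.column_stack([np.zeros(10), np.zeros(10), np.arange(10.0)])
    rad, _, _, flagged = preimage_radius(line, 50.0)
    assert flagged and rad == 25.0


# ---------------------------------------------------------------------------
# calibration


def test_calibrate_distance_exact_line_and_errors():
    sizes = np.array([0.1, 0.2, 0.4])
    radii = 500.0 * sizes
    slope, err = calibrate_distance(radii, sizes)
    assert slope == pytest.approx(500.0)
    assert err == pytest.approx(0.0, abs=1e-4)  # fp noise of the exact fit
    with pytest.raises(ValueError):
        calibrate_distance(radii[:2], sizes[:2])


def test_calibrate_area_factor():
    coords = np.zeros((1, 1, 1, 2))
    fm = Flatmap(coords, 50.0, np.zeros(3), mesh_area=40.606)
    factor = calibrate_area(fm)
    assert factor(1.0) == pytest.approx(40.606)
    assert factor(0.25) == pytest.approx(40.606 / 4)
    # additivity over a tiling of flat space
    fractions = np.full(16, 1 / 16)
    assert sum(factor(f) for f in fractions) == pytest.approx(40.606)
    fm2 = Flatmap(coords, 50.0, np.zeros(3))
    with pytest.raises(ValueError):
        calibrate_area(fm2)
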