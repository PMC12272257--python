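"""Shared fixtures: synthetic atlases and pipeline results computed once per
session (the heavier geometries are reused across test modules)."""

import numpy as np
import pytest

import laminaflat as lf
from laminaflat.meshing import BorderSpec

SLAB_SHAPE = (16, 16, 17)   # nz - 1 a power of two: dyadic depth values
SLAB_VOXEL = 50.0
SHELL_A, SHELL_B = 20, 40   # voxels; 20 voxels across the shell
SHELL_VOXEL = 25.0

TRIANGLE_BORDER = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])


@pytest.fixture(scope="session")
def slab_fx():
    return lf.make_fixture(lf.FixtureSpec(kind="slab", shape=SLAB_SHAPE,
                                          voxel_size=SLAB_VOXEL))


@pytest.fixture(scope="session")
def slab_result(slab_fx):
    return lf.make_flatmap(slab_fx.depth, slab_fx.orientation,
                           mask=slab_fx.mask, d_star=0.5,
                           border=BorderSpec(anchors="auto"))


@pytest.fixture(scope="session")
def shell_fx():
    return lf.make_fixture(lf.FixtureSpec(
        kind="spherical_shell", inner_radius=SHELL_A, outer_radius=SHELL_B,
        voxel_size=SHELL_VOXEL))


@pytest.fixture(scope="session")
def shell_fx_top_outer():
    return lf.make_fixture(lf.FixtureSpec(
        kind="spherical_shell", inner_radius=SHELL_A, outer_radius=SHELL_B,
        voxel_size=SHELL_VOXEL, top_surface="outer"))


@pytest.fixture(scope="session")
def shell_laplace(shell_fx):
    return lf.laplace_depth(shell_fx.shells)


@pytest.fixture(scope="session")
def shell_result(shell_fx):
    return lf.make_flatmap(
        shell_fx.depth, shell_fx.orientation, mask=shell_fx.mask, d_star=0.5,
        border=BorderSpec(polygon=TRIANGLE_BORDER.copy(), anchors="auto"),
        eps0=0.05, eps1=0.05)


@pytest.fixture(scope="session")
def shell_rstar_um(shell_fx):
    """Closed-form radius of the d*=0.5 level surface, μm."""
    a, b = shell_fx.meta["a_center_vox"], shell_fx.meta["b_center_vox"]
    return 2 * a * b / (a + b) * SHELL_VOXEL


@pytest.fixture(scope="session")
def cube_result():
    """Cube of side 1000 μm (40³ voxels at 25 μm) through the full pipeline."""
    fx = lf.make_fixture(lf.FixtureSpec(kind="cube", shape=(40, 40, 40),
                                        voxel_size=25.0))
    res = lf.make_flatmap(fx.depth, fx.orientation, mask=fx.mask, d_star=0.5,
                          border=BorderSpec(anchors="auto"))
    return fx, res


@pytest.fixture(scope="session")
def barrel_setup(slab_fx):
    """A wider slab with two circular 'barrel' blobs in a mid-depth band."""
    fx = lf.make_fixture(lf.FixtureSpec(kind="slab", shape=(24, 24, 17),
                                        voxel_size=50.0))
    res = lf.make_flatmap(fx.depth, fx.orientation, mask=fx.mask, d_star=0.5,
                          border=BorderSpec(anchors="auto"))
    ii, jj, _ = np.indices(fx.annotation.shape)
    layer4 = (fx.depth.data >= 0.4) & (fx.depth.data < 0.6)
    blobs = np.zeros(fx.annotation.shape, np.int32)
    blobs[((ii - 7) ** 2 + (jj - 7) ** 2 <= 16) & layer4] = 1
    blobs[((ii - 16) ** 2 + (jj - 16) ** 2 <= 16) & layer4] = 2
    return fx, res, blobs, layer4
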