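"""Data model and I/O for voxel volumes and flatmaps.

Conventions used throughout the package:

* Voxel grids are numpy arrays indexed ``[i, j, k]``; world coordinates (μm)
  of voxel centers are ``origin + (index + 0.5) * voxel_size``.
* All fields (depth, orientation, flat coordinates) are sampled at voxel
  centers.
* Invalid / non-eligible values are NaN in float fields.
* Flat coordinates use half-open ``[0, 1)`` binning semantics; the value 1.0
  is clamped into the last bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np

from . import nrrdio

#: shell label values
EXTERIOR, INTERIOR, TOP, BOTTOM, SIDE = 0, 1, 2, 3, 4

SHELL_NAMES = {
    EXTERIOR: "exterior", INTERIOR: "interior",
    TOP: "top", BOTTOM: "bottom", SIDE: "side",
}


@dataclass
class Volume:
    """A voxel grid with world geometry.

    ``data`` may be integer labels (annotation/shell volumes) or a float
    field; an optional trailing axis holds channels (e.g. orientation
    vectors are stored as shape ``(nx, ny, nz, 3)``).
    """

    data: np.ndarray
    voxel_size: np.ndarray  # (3,) μm per voxel edge
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError("Volume data must be 3D (+ optional channel axis)")
        if min(self.data.shape[:3]) < 1:
            raise ValueError("all spatial dimensions must be >= 1")
        self.voxel_size = np.broadcast_to(
            np.atleast_1d(np.asarray(self.voxel_size, dtype=float)), (3,)
        ).copy()
        if np.any(self.voxel_size <= 0):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def like(self, data: np.ndarray) -> "Volume":
        """A new Volume on the same grid with different payload."""
        return Volume(data, self.voxel_size.copy(), self.origin.copy())

    # ---- geometry -------------------------------------------------------
    def world(self, indices: np.ndarray) -> np.ndarray:
        """World coordinates (μm) of voxel centers for integer indices (n,3)."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return self.origin + (idx + 0.5) * self.voxel_size

    def index_of(self, points: np.ndarray) -> np.ndarray:
        """Integer voxel index containing each world point (floor convention)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.floor((pts - self.origin) / self.voxel_size).astype(np.int64)

    def contains_index(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(idx)
        shape = np.array(self.shape)
        return np.all((idx >= 0) & (idx < shape), axis=1)

    def voxel_centers(self, mask: np.ndarray | None = None) -> np.ndarray:
        """World coordinates of all (or masked) voxel centers, (n, 3)."""
        if mask is None:
            idx = np.stack(
                np.meshgrid(*[np.arange(s) for s in self.shape], indexing="ij"),
                axis=-1,
            ).reshape(-1, 3)
        else:
            idx = np.argwhere(mask)
        return self.world(idx)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size)) * 1e-9


INVALID = np.nan  # sentinel for non-eligible flat coordinates


@dataclass
class Flatmap:
    """Per-voxel flat coordinates (the flatmap operator ℳ evaluated at voxel
    centers) plus metadata of the projection used to build it."""

    coords: np.ndarray        # (nx, ny, nz, 2) float, NaN where not eligible
    voxel_size: np.ndarray
    origin: np.ndarray
    d_star: float = 0.5
    mesh_area: float = np.nan        # projection mesh area, mm²
    distance_factor: float = np.nan  # μm per flat coordinate unit
    x_range: tuple[float, float] = (0.0, 1.0)
    y_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 4 or self.coords.shape[3] != 2:
            raise ValueError("flatmap coords must have shape (nx, ny, nz, 2)")
        self.voxel_size = np.broadcast_to(
            np.atleast_1d(np.asarray(self.voxel_size, dtype=float)), (3,)
        ).copy()
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        valid = self.valid_mask
        if valid.any():
            xy = self.coords[valid]
            if (xy[:, 0].min() < self.x_range[0] - 1e-9
                    or xy[:, 0].max() > self.x_range[1] + 1e-9
                    or xy[:, 1].min() < self.y_range[0] - 1e-9
                    or xy[:, 1].max() > self.y_range[1] + 1e-9):
                raise ValueError("valid flat coordinates outside declared range")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.coords.shape[:3]

    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.coords).any(axis=3)

    @property
    def n_eligible(self) -> int:
        return int(self.valid_mask.sum())

    def as_volume(self) -> Volume:
        return Volume(self.coords, self.voxel_size, self.origin)


# ---------------------------------------------------------------------------
# Volume I/O


def _detect_format(path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    name = str(path).lower()
    if name.endswith(".nrrd") or name.endswith(".nhdr"):
        return "nrrd"
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        return "nifti"
    raise ValueError(f"cannot infer volume format from {path!r}")


def read_volume(path, fmt: str | None = None) -> Volume:
    """Read a NRRD or NIfTI volume. Integer vs float payload is preserved.

    Raises if the file declares no grid spacing: distances in μm are load
    bearing everywhere downstream, so a silent default is never used.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, fmt)
    if fmt == "nrrd":
        data, header = nrrdio.read(path)
        voxel_size, origin = nrrdio.parse_spacing(header, min(data.ndim, 3))
        vs = np.ones(3)
        org = np.zeros(3)
        vs[: len(voxel_size)] = voxel_size
        org[: len(origin)] = origin
        return Volume(data, vs, org)
    elif fmt == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
        if np.any(zooms <= 0) or np.any(~np.isfinite(zooms)):
            raise ValueError(f"{path}: NIfTI header has no usable voxel spacing")
        data = np.asanyarray(img.dataobj)
        origin = np.asarray(img.affine[:3, 3], dtype=float)
        return Volume(data, zooms, origin)
    raise ValueError(f"unknown format {fmt!r}")


def write_volume(vol: Volume, path, fmt: str | None = None,
                 encoding: str = "raw") -> None:
    path = Path(path)
    fmt = _detect_format(path, fmt)
    if fmt == "nrrd":
        nrrdio.write(path, vol.data, voxel_size=vol.voxel_size,
                     origin=vol.origin, encoding=encoding)
    elif fmt == "nifti":
        import nibabel as nib

        affine = np.eye(4)
        affine[:3, :3] = np.diag(vol.voxel_size)
        affine[:3, 3] = vol.origin
        nib.save(nib.Nifti1Image(vol.data, affine), str(path))
    else:
        raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Flatmap I/O (single HDF5 container: /coords + attributes)


def write_flatmap(fm: Flatmap, path) -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("coords", data=fm.coords)
        ds.attrs["invalid"] = "nan"
        fh.attrs["voxel_size"] = fm.voxel_size
        fh.attrs["origin"] = fm.origin
        fh.attrs["d_star"] = fm.d_star
        fh.attrs["mesh_area"] = fm.mesh_area
        fh.attrs["distance_factor"] = fm.distance_factor
        fh.attrs["x_range"] = np.asarray(fm.x_range)
        fh.attrs["y_range"] = np.asarray(fm.y_range)


def read_flatmap(path) -> Flatmap:
    with h5py.File(path, "r") as fh:
        coords = fh["coords"][()]
        return Flatmap(
            coords=coords,
            voxel_size=fh.attrs["voxel_size"][()],
            origin=fh.attrs["origin"][()],
            d_star=float(fh.attrs["d_star"]),
            mesh_area=float(fh.attrs["mesh_area"]),
            distance_factor=float(fh.attrs["distance_factor"]),
            x_range=tuple(fh.attrs["x_range"][()]),
            y_range=tuple(fh.attrs["y_range"][()]),
        )
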