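"""Minimal NRRD (Nearly Raw Raster Data) reader/writer.

Supports the subset of NRRD needed for voxel atlases: raw / ascii / gzip
encodings, C-contiguous ("node") data, `space directions` restricted to
diagonal matrices (axis-aligned grids) and `space origin`. Header fields are
preserved verbatim in a dict so round-trips are lossless for the fields we
write.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np

_NRRD_TO_DTYPE = {
    "signed char": "i1", "int8": "i1", "int8_t": "i1",
    "uchar": "u1", "unsigned char": "u1", "uint8": "u1", "uint8_t": "u1",
    "short": "i2", "signed short": "i2", "int16": "i2", "int16_t": "i2",
    "ushort": "u2", "unsigned short": "u2", "uint16": "u2", "uint16_t": "u2",
    "int": "i4", "signed int": "i4", "int32": "i4", "int32_t": "i4",
    "uint": "u4", "unsigned int": "u4", "uint32": "u4", "uint32_t": "u4",
    "longlong": "i8", "int64": "i8", "int64_t": "i8",
    "ulonglong": "u8", "uint64": "u8", "uint64_t": "u8",
    "float": "f4", "double": "f8",
}

_DTYPE_TO_NRRD = {
    np.dtype("i1"): "int8", np.dtype("u1"): "uint8",
    np.dtype("i2"): "int16", np.dtype("u2"): "uint16",
    np.dtype("i4"): "int32", np.dtype("u4"): "uint32",
    np.dtype("i8"): "int64", np.dtype("u8"): "uint64",
    np.dtype("f4"): "float", np.dtype("f8"): "double",
}


class NrrdError(ValueError):
    pass


def _parse_vector(text: str) -> np.ndarray:
    text = text.strip()
    if not (text.startswith("(") and text.endswith(")")):
        raise NrrdError(f"malformed NRRD vector: {text!r}")
    return np.array([float(x) for x in text[1:-1].split(",")])


def _format_vector(vec) -> str:
    return "(" + ",".join(repr(float(x)) for x in vec) + ")"


def read(path) -> tuple[np.ndarray, dict]:
    """Read a NRRD file, returning (data, header).

    `data` is indexed [i, j, k(, channel...)] in the order the sizes field
    declares (C order on disk is the NRRD default for "node" centering).
    """
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.readline()
        if not magic.startswith(b"NRRD"):
            raise NrrdError(f"{path}: not a NRRD file")
        header: dict = {}
        while True:
            line = fh.readline()
            if line in (b"\n", b"\r\n"):
                break
            if not line:
                raise NrrdError(f"{path}: truncated header")
            text = line.decode("ascii", errors="replace").rstrip("\r\n")
            if text.startswith("#"):
                continue
            if ":=" in text:
                key, _, val = text.partition(":=")
            else:
                key, _, val = text.partition(":")
            header[key.strip()] = val.strip()
        payload = fh.read()

    if "type" not in header or "sizes" not in header:
        raise NrrdError(f"{path}: missing type/sizes header fields")
    try:
        dtype = np.dtype(_NRRD_TO_DTYPE[header["type"]])
    except KeyError:
        raise NrrdError(f"{path}: unsupported NRRD type {header['type']!r}")
    endian = header.get("endian", "little")
    dtype = dtype.newbyteorder("<" if endian == "little" else ">")
    sizes = tuple(int(s) for s in header["sizes"].split())
    count = int(np.prod(sizes))

    encoding = header.get("encoding", "raw")
    if encoding == "raw":
        data = np.frombuffer(payload, dtype=dtype, count=count)
    elif encoding in ("gzip", "gz"):
        data = np.frombuffer(gzip.decompress(payload), dtype=dtype, count=count)
    elif encoding in ("ascii", "text", "txt"):
        data = np.array(payload.split(), dtype=dtype.base)[:count].astype(dtype)
    else:
        raise NrrdError(f"{path}: unsupported encoding {encoding!r}")
    if data.size != count:
        raise NrrdError(f"{path}: payload has {data.size} values, expected {count}")
    # NRRD lists sizes fastest-first; C-order memory maps to reversed shape.
    data = data.reshape(tuple(reversed(sizes))).transpose(
        tuple(reversed(range(len(sizes))))
    )
    return np.ascontiguousarray(data), header


def parse_spacing(header: dict, ndim: int) -> tuple[np.ndarray, np.ndarray]:
    """Extract (voxel_size, origin) in world units from a NRRD header.

    Only diagonal `space directions` (axis-aligned grids) are supported.
    Raises NrrdError when no spacing information is present: a silent default
    would corrupt every downstream distance.
    """
    if "space directions" in header:
        rows = []
        for tok in header["space directions"].split():
            if tok == "none":
                continue
            rows.append(_parse_vector(tok))
        mat = np.array(rows)
        if mat.shape[0] < ndim:
            mat = np.vstack([mat] + [np.zeros(mat.shape[1])] * (ndim - mat.shape[0]))
        diag = np.array([mat[i, i] for i in range(min(ndim, mat.shape[1]))])
        off = mat[:ndim, :ndim] - np.diag(diag)
        if np.any(np.abs(off) > 1e-9 * max(1.0, np.abs(diag).max())):
            raise NrrdError("non-axis-aligned space directions are not supported")
        voxel_size = diag
    elif "spacings" in header:
        voxel_size = np.array(
            [float(s) for s in header["spacings"].split()[:ndim]]
        )
    else:
        raise NrrdError(
            "NRRD header declares no grid spacing "
            "('space directions' or 'spacings' required)"
        )
    if np.any(~np.isfinite(voxel_size)) or np.any(voxel_size <= 0):
        raise NrrdError(f"invalid voxel size {voxel_size}")
    if "space origin" in header:
        origin = _parse_vector(header["space origin"])[:ndim]
    else:
        origin = np.zeros(ndim)
    return voxel_size, origin


def write(path, data: np.ndarray, voxel_size=None, origin=None,
          encoding: str = "raw", extra_header: dict | None = None) -> None:
    """Write `data` as NRRD. Spatial axes are the leading 3 (or fewer);
    trailing axes are treated as non-spatial (channel) axes."""
    path = Path(path)
    data = np.asarray(data)
    if data.dtype == np.bool_:
        data = data.astype(np.uint8)
    try:
        type_name = _DTYPE_TO_NRRD[data.dtype.newbyteorder("=")]
    except KeyError:
        raise NrrdError(f"unsupported dtype {data.dtype}")
    nspace = min(data.ndim, 3)
    lines = [
        "NRRD0004",
        "# laminaflat minimal NRRD writer",
        f"type: {type_name}",
        f"dimension: {data.ndim}",
        "sizes: " + " ".join(str(s) for s in data.shape),
        f"encoding: {encoding}",
        "endian: little",
    ]
    if voxel_size is not None:
        voxel_size = np.broadcast_to(np.atleast_1d(voxel_size), (nspace,))
        dirs = []
        for i in range(data.ndim):
            if i < nspace:
                vec = np.zeros(nspace)
                vec[i] = voxel_size[i]
                dirs.append(_format_vector(vec))
            else:
                dirs.append("none")
        lines.append(f"space dimension: {nspace}")
        lines.append("space directions: " + " ".join(dirs))
        if origin is None:
            origin = np.zeros(nspace)
        lines.append("space origin: " + _format_vector(np.atleast_1d(origin)[:nspace]))
    for key, val in (extra_header or {}).items():
        lines.append(f"{key}:={val}")
    header = "\n".join(lines) + "\n\n"

    # write in C order with sizes listed fastest-first
    disk = data.transpose(tuple(reversed(range(data.ndim))))
    disk = np.ascontiguousarray(disk).astype(data.dtype.newbyteorder("<"))
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if encoding == "raw":
            fh.write(disk.tobytes())
        elif encoding in ("gzip", "gz"):
            fh.write(gzip.compress(disk.tobytes()))
        elif encoding in ("ascii", "text", "txt"):
            np.savetxt(fh, disk.reshape(-1, 1), fmt="%.17g")
        else:
            raise NrrdError(f"unsupported encoding {encoding!r}")
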