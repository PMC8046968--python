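"""Minimal MRC2014 volume I/O.

Only the subset of the format needed for integer label volumes is
supported: modes 0 (int8), 1 (int16), 2 (float32) and 6 (uint16),
little-endian, no extended header on write.  Data on disk follow the
MRC axis convention (section, row, column) = (z, y, x); in memory we
use arrays indexed ``[x, y, z]``.

Header cell dimensions are stored in ångström per MRC convention;
voxel size is ``cella / m`` (sampling grid), converted to nm by the
caller.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .errors import FormatError

_HEADER_SIZE = 1024
_MAP_ID = b"MAP "

_MODE_DTYPES = {
    0: np.dtype("<i1"),
    1: np.dtype("<i2"),
    2: np.dtype("<f4"),
    6: np.dtype("<u2"),
}


def read_mrc(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read an MRC2014 file.

    Returns
    -------
    data : ndarray indexed [x, y, z]
    voxel_size : (sx, sy, sz) in ångström per voxel
    """
    path = Path(path)
    try:
        raw = path.read_bytes()
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise FormatError(f"cannot read MRC file {path}: {exc}") from exc
    if len(raw) < _HEADER_SIZE:
        raise FormatError(f"{path}: truncated MRC header ({len(raw)} bytes)")

    nx, ny, nz, mode = struct.unpack_from("<4i", raw, 0)
    mx, my, mz = struct.unpack_from("<3i", raw, 28)
    xlen, ylen, zlen = struct.unpack_from("<3f", raw, 40)
    nsymbt = struct.unpack_from("<i", raw, 92)[0]
    map_id = raw[208:212]
    if map_id not in (_MAP_ID, b"MAP\x00"):
        # Pre-2014 files may omit the stamp; accept if geometry is sane.
        if not (0 < nx < 1 << 20 and 0 < ny < 1 << 20 and 0 < nz < 1 << 20):
            raise FormatError(f"{path}: not an MRC file (missing MAP stamp)")
    if mode not in _MODE_DTYPES:
        raise FormatError(f"{path}: unsupported MRC mode {mode}")

    dtype = _MODE_DTYPES[mode]
    offset = _HEADER_SIZE + max(nsymbt, 0)
    count = nx * ny * nz
    data = np.frombuffer(raw, dtype=dtype, count=count, offset=offset)
    if data.size != count:
        raise FormatError(f"{path}: data block shorter than header promises")
    vol = data.reshape(nz, ny, nx).transpose(2, 1, 0)

    def _pitch(length: float, m: int) -> float:
        return float(length) / m if m > 0 else 0.0

    voxel = (_pitch(xlen, mx or nx), _pitch(ylen, my or ny), _pitch(zlen, mz or nz))
    return np.ascontiguousarray(vol), voxel


def write_mrc(path: str | Path, volume: np.ndarray, voxel_size_angstrom: float) -> None:
    """Write ``volume`` (indexed [x, y, z]) as a little-endian MRC2014 file."""
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise FormatError("volume must be 3-dimensional")
    if np.issubdtype(volume.dtype, np.integer):
        if volume.min() >= -128 and volume.max() <= 127:
            mode, dtype = 0, np.dtype("<i1")
        elif volume.min() >= -32768 and volume.max() <= 32767:
            mode, dtype = 1, np.dtype("<i2")
        elif volume.min() >= 0 and volume.max() <= 65535:
            mode, dtype = 6, np.dtype("<u2")
        else:
            mode, dtype = 2, np.dtype("<f4")
    else:
        mode, dtype = 2, np.dtype("<f4")

    nx, ny, nz = volume.shape
    data = volume.transpose(2, 1, 0).astype(dtype)
    vs = float(voxel_size_angstrom)

    header = bytearray(_HEADER_SIZE)
    struct.pack_into("<4i", header, 0, nx, ny, nz, mode)
    struct.pack_into("<3i", header, 16, 0, 0, 0)  # nxstart
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # mx, my, mz
    struct.pack_into("<3f", header, 40, vs * nx, vs * ny, vs * nz)  # cella (Å)
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)  # cellb
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # mapc, mapr, maps
    fdata = data.astype(np.float64)
    struct.pack_into(
        "<3f", header, 76, float(fdata.min()), float(fdata.max()), float(fdata.mean())
    )
    struct.pack_into("<i", header, 88, 1)  # ispg: 3D volume
    struct.pack_into("<i", header, 92, 0)  # nsymbt
    struct.pack_into("<i", header, 108, 20140)  # nversion
    struct.pack_into("<3f", header, 196, 0.0, 0.0, 0.0)  # origin
    header[208:212] = _MAP_ID
    header[212:216] = bytes((0x44, 0x44, 0x00, 0x00))  # little-endian stamp
    struct.pack_into("<f", header, 216, float(fdata.std()))
    struct.pack_into("<i", header, 220, 0)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data.tobytes())
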