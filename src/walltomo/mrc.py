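"""Minimal MRC2014 volume reader/writer.

Implements the subset of the MRC2014 format the pipeline needs: modes 0
(int8), 1 (int16), 2 (float32) and 6 (uint16), single-volume files with
axis order column=x, row=y, section=z (mapc/mapr/maps = 1/2/3).  The
1024-byte header stores the cell dimension in Angstrom; voxel size in nm
is cella / m / 10.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .datatypes import DensityVolume

_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}
_DTYPE_MODES = {np.dtype(v).str: k for k, v in _MODE_DTYPES.items()}
HEADER_SIZE = 1024


def read_mrc(path: str | Path) -> DensityVolume:
    """Read an MRC2014 volume into a DensityVolume (data [z, y, x], nm units)."""
    path = Path(path)
    with open(path, "rb") as fh:
        header = fh.read(HEADER_SIZE)
        if len(header) < HEADER_SIZE:
            raise ValueError(f"{path}: truncated MRC header ({len(header)} bytes)")
        nx, ny, nz, mode = struct.unpack("<4i", header[0:16])
        mx, my, mz = struct.unpack("<3i", header[28:40])
        cella = struct.unpack("<3f", header[40:52])
        mapc, mapr, maps = struct.unpack("<3i", header[64:76])
        nsymbt = struct.unpack("<i", header[92:96])[0]
        if mode not in _MODE_DTYPES:
            raise ValueError(f"{path}: unsupported MRC mode {mode}")
        if (mapc, mapr, maps) != (1, 2, 3):
            raise ValueError(
                f"{path}: unsupported axis order mapc/mapr/maps = {mapc}/{mapr}/{maps}"
            )
        fh.seek(HEADER_SIZE + nsymbt)
        dtype = np.dtype(_MODE_DTYPES[mode]).newbyteorder("<")
        count = nx * ny * nz
        data = np.fromfile(fh, dtype=dtype, count=count)
        if data.size != count:
            raise ValueError(f"{path}: expected {count} voxels, file holds {data.size}")
    data = data.reshape(nz, ny, nx)
    if mx > 0 and cella[0] > 0:
        voxel_nm = cella[0] / mx / 10.0
    else:
        voxel_nm = 1.0
    return DensityVolume(np.ascontiguousarray(data), voxel_size_nm=voxel_nm)


def write_mrc(vol: DensityVolume, path: str | Path, mode: int | None = None) -> None:
    """Write a DensityVolume as a little-endian MRC2014 file.

    mode defaults to the closest match for the array dtype (float data ->
    mode 2).  Data are converted if an explicit mode is requested.
    """
    data = np.asarray(vol.data)
    if mode is None:
        mode = _DTYPE_MODES.get(np.dtype(data.dtype).str.replace(">", "<"), 2)
    if mode not in _MODE_DTYPES:
        raise ValueError(f"unsupported MRC mode {mode}")
    out = data.astype(np.dtype(_MODE_DTYPES[mode]).newbyteorder("<"), copy=False)
    nz, ny, nx = out.shape
    cell_a = nx * vol.voxel_size_nm * 10.0  # nm -> Angstrom
    cell_b = ny * vol.voxel_size_nm * 10.0
    cell_c = nz * vol.voxel_size_nm * 10.0
    dmin = float(out.min()) if out.size else 0.0
    dmax = float(out.max()) if out.size else 0.0
    dmean = float(out.mean()) if out.size else 0.0
    rms = float(out.std()) if out.size else 0.0

    header = bytearray(HEADER_SIZE)
    struct.pack_into("<4i", header, 0, nx, ny, nz, mode)
    struct.pack_into("<3i", header, 16, 0, 0, 0)  # nxstart
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # mx, my, mz
    struct.pack_into("<3f", header, 40, cell_a, cell_b, cell_c)
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # mapc, mapr, maps
    struct.pack_into("<3f", header, 76, dmin, dmax, dmean)
    struct.pack_into("<2i", header, 88, 0, 0)  # ispg, nsymbt
    header[208:212] = b"MAP "
    header[212:216] = bytes((0x44, 0x44, 0x00, 0x00))  # little-endian machine stamp
    struct.pack_into("<f", header, 216, rms)
    struct.pack_into("<i", header, 220, 1)  # nlabl
    label = b"walltomo volume"
    header[224 : 224 + len(label)] = label

    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(np.ascontiguousarray(out).tobytes())
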