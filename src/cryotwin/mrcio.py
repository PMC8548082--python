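"""Minimal MRC2014 volume/stack I/O with a per-image extended header.

Writes mode-2 (float32) files with the standard 1024-byte header and an
optional FEI-style extended header: one fixed-size little-endian record
per image carrying tilt angle (deg), defocus (A), exposure (s),
accumulated dose (e-/A^2) and pixel size (A).  The record layout is this
package's own (exttyp ``CTW1``) rather than a bit-exact FEI emulation;
the same metadata is mirrored into HDF5 by the simulator.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["ExtendedRecord", "EXT_DTYPE", "write_mrc", "read_mrc"]

HEADER_SIZE = 1024
EXT_DTYPE = np.dtype(
    [
        ("tilt_angle", "<f4"),
        ("defocus", "<f4"),
        ("exposure", "<f4"),
        ("accumulated_dose", "<f4"),
        ("pixel_size", "<f4"),
    ]
)
ExtendedRecord = EXT_DTYPE  # alias for discoverability


@dataclass
class MrcData:
    data: np.ndarray  # (nz, ny, nx) float32
    voxel_size: float  # A
    extended: Optional[np.ndarray]  # structured EXT_DTYPE records or None


def write_mrc(
    path: str,
    data: np.ndarray,
    voxel_size: float,
    extended: Optional[np.ndarray] = None,
    is_stack: bool = False,
) -> None:
    """Write a float32 MRC2014 file.

    ``data`` is (nz, ny, nx) (or 2D, stored as a single section);
    ``is_stack`` marks an image stack (ispg=0) versus a volume (ispg=1).
    """
    arr = np.asarray(data, dtype="<f4")
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError("data must be 2D or 3D")
    nz, ny, nx = arr.shape
    if extended is not None:
        extended = np.asarray(extended, dtype=EXT_DTYPE)
        if len(extended) != nz:
            raise ValueError("need one extended record per section")
        ext_bytes = extended.tobytes()
    else:
        ext_bytes = b""

    header = bytearray(HEADER_SIZE)
    struct.pack_into("<3i", header, 0, nx, ny, nz)  # NX NY NZ
    struct.pack_into("<i", header, 12, 2)  # MODE 2 = float32
    struct.pack_into("<3i", header, 16, 0, 0, 0)  # NXSTART..
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # MX MY MZ
    cell = (nx * voxel_size, ny * voxel_size, nz * voxel_size)
    struct.pack_into("<3f", header, 40, *cell)  # CELLA
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)  # CELLB
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # MAPC MAPR MAPS
    struct.pack_into(
        "<3f", header, 76, float(arr.min()), float(arr.max()), float(arr.mean())
    )
    struct.pack_into("<i", header, 88, 0 if is_stack else 1)  # ISPG
    struct.pack_into("<i", header, 92, len(ext_bytes))  # NSYMBT
    header[104:108] = b"CTW1" if ext_bytes else b"    "  # EXTTYP
    struct.pack_into("<i", header, 108, 20140)  # NVERSION
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])  # little-endian stamp
    struct.pack_into("<f", header, 216, float(arr.std()))  # RMS
    struct.pack_into("<i", header, 220, 1)  # NLABL
    label = b"cryotwin simulated data"
    header[224:224 + len(label)] = label

    with open(path, "wb") as f:
        f.write(bytes(header))
        f.write(ext_bytes)
        f.write(arr.tobytes())


def read_mrc(path: str) -> MrcData:
    """Read a mode-2 MRC file written by :func:`write_mrc` (or compatible)."""
    with open(path, "rb") as f:
        header = f.read(HEADER_SIZE)
        nx, ny, nz = struct.unpack_from("<3i", header, 0)
        mode = struct.unpack_from("<i", header, 12)[0]
        if mode != 2:
            raise ValueError(f"only mode-2 (float32) MRC supported, got mode {mode}")
        mx = struct.unpack_from("<i", header, 28)[0]
        cella_x = struct.unpack_from("<f", header, 40)[0]
        voxel = cella_x / mx if mx else 1.0
        nsymbt = struct.unpack_from("<i", header, 92)[0]
        exttyp = bytes(header[104:108])
        ext_bytes = f.read(nsymbt) if nsymbt else b""
        extended = None
        if exttyp == b"CTW1" and nsymbt == nz * EXT_DTYPE.itemsize:
            extended = np.frombuffer(ext_bytes, dtype=EXT_DTYPE).copy()
        data = np.frombuffer(f.read(nx * ny * nz * 4), dtype="<f4")
        data = data.reshape(nz, ny, nx).copy()
    return MrcData(data=data, voxel_size=float(voxel), extended=extended)
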