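"""Particle-stack and alignment-parameter I/O.

Stacks travel as MRC2014 files (the format EMPIAR deposits use): a fixed
1024-byte little-endian header followed by the image sections.  Only the
header words the pipeline needs are interpreted — grid size, mode, cell
dimensions (which encode the pixel size) and the density statistics.
Alignment parameters travel as a STAR data block with a single loop, the
de-facto particle-metadata convention of downstream classifiers.

Angles are degrees, shifts are pixels (pixel-size independent), and the
shift is applied *after* the in-plane rotation.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ParticleStack",
    "ParamTable",
    "StackIOError",
    "NonSquareImageError",
    "UnsupportedModeError",
    "MissingColumnError",
    "read_stack",
    "write_stack",
    "read_params",
    "write_params",
]


class StackIOError(ValueError):
    """Base class for stack/table I/O failures."""


class NonSquareImageError(StackIOError):
    """The file's sections are not square (nx != ny)."""


class UnsupportedModeError(StackIOError):
    """The MRC mode word is not one this reader converts to real."""


class MissingColumnError(StackIOError):
    """A required STAR column is absent."""


# MRC mode -> numpy dtype, for the modes we accept on read.
_MODE_DTYPES = {
    0: np.dtype("int8"),
    1: np.dtype("<i2"),
    2: np.dtype("<f4"),
    6: np.dtype("<u2"),
}

_MAP_ID = b"MAP "


@dataclass
class ParticleStack:
    """A stack of n square particle images plus its physical scale.

    Parameters
    ----------
    images
        Array of shape (n, H, W); any real dtype, converted to float32.
    pixel_size
        Angstrom per pixel, > 0.
    meta
        Optional per-particle table (defocus, group labels, ...) carried
        through the pipeline untouched.
    """

    images: np.ndarray
    pixel_size: float = 1.0
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.images = np.ascontiguousarray(self.images, dtype=np.float32)
        if self.images.ndim == 2:
            self.images = self.images[None]
        if self.images.ndim != 3:
            raise StackIOError(f"expected (n, H, W) images, got shape {self.images.shape}")
        n, h, w = self.images.shape
        if h != w:
            raise NonSquareImageError(f"particles must be square, got {h}x{w}")
        if not np.all(np.isfinite(self.images)):
            raise StackIOError("stack contains non-finite intensities")
        if not (self.pixel_size > 0):
            raise StackIOError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.meta is not None and len(self.meta) != n:
            raise StackIOError("meta row count does not match stack size")

    @property
    def n(self) -> int:
        return self.images.shape[0]

    @property
    def box(self) -> int:
        return self.images.shape[1]

    def copy(self) -> "ParticleStack":
        return ParticleStack(
            self.images.copy(),
            self.pixel_size,
            None if self.meta is None else self.meta.copy(),
        )


def _normalize_psi(psi: np.ndarray) -> np.ndarray:
    return np.mod(np.asarray(psi, dtype=float), 360.0)


@dataclass
class ParamTable:
    """Per-particle in-plane pose: rotate by psi (deg, CCW), then shift.

    ``psi`` is normalized to [0, 360); ``dx``/``dy`` are pixels; ``mirror``
    flags a left-right flip applied before the rotation.
    """

    psi: np.ndarray
    dx: np.ndarray
    dy: np.ndarray
    mirror: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.psi = _normalize_psi(np.atleast_1d(np.asarray(self.psi, dtype=float)))
        self.dx = np.atleast_1d(np.asarray(self.dx, dtype=float))
        self.dy = np.atleast_1d(np.asarray(self.dy, dtype=float))
        if self.mirror is None:
            self.mirror = np.zeros(self.psi.shape, dtype=bool)
        self.mirror = np.atleast_1d(np.asarray(self.mirror, dtype=bool))
        n = len(self.psi)
        for name in ("dx", "dy", "mirror"):
            if len(getattr(self, name)) != n:
                raise StackIOError(f"ParamTable column {name!r} has wrong length")
        if not (
            np.all(np.isfinite(self.psi))
            and np.all(np.isfinite(self.dx))
            and np.all(np.isfinite(self.dy))
        ):
            raise StackIOError("ParamTable contains non-finite values")

    def __len__(self) -> int:
        return len(self.psi)

    @classmethod
    def identity(cls, n: int) -> "ParamTable":
        z = np.zeros(n, dtype=float)
        return cls(z, z.copy(), z.copy())

    def row(self, i: int) -> tuple[float, float, float, bool]:
        return float(self.psi[i]), float(self.dx[i]), float(self.dy[i]), bool(self.mirror[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"psi": self.psi, "dx": self.dx, "dy": self.dy, "mirror": self.mirror}
        )


# ---------------------------------------------------------------------------
# MRC2014
# ---------------------------------------------------------------------------

def read_stack(path) -> ParticleStack:
    """Read an MRC/MRCS file into a :class:`ParticleStack`.

    Modes 0, 1, 2 and 6 are accepted; anything else raises
    :class:`UnsupportedModeError`.  The pixel size is cell-x / nx.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"no such stack file: {path}")
    with open(path, "rb") as fh:
        header = fh.read(1024)
        if len(header) < 1024:
            raise StackIOError(f"{path}: truncated MRC header")
        nx, ny, nz, mode = struct.unpack("<4i", header[:16])
        xlen, ylen, zlen = struct.unpack("<3f", header[40:52])
        nsymbt = struct.unpack("<i", header[92:96])[0]
        if mode not in _MODE_DTYPES:
            raise UnsupportedModeError(f"{path}: MRC mode {mode} not supported")
        if nx != ny:
            raise NonSquareImageError(f"{path}: sections are {nx}x{ny}, not square")
        if nx < 1 or nz < 1:
            raise StackIOError(f"{path}: empty volume ({nx}, {ny}, {nz})")
        fh.seek(1024 + max(nsymbt, 0))
        dtype = _MODE_DTYPES[mode]
        count = nx * ny * nz
        data = np.fromfile(fh, dtype=dtype, count=count)
    if data.size != count:
        raise StackIOError(f"{path}: file shorter than header promises")
    images = data.reshape(nz, ny, nx).astype(np.float32)
    pixel_size = float(xlen) / nx if xlen > 0 else 1.0
    return ParticleStack(images, pixel_size)


def write_stack(stack: ParticleStack, path) -> None:
    """Write a stack as MRC2014 mode 2 (32-bit real)."""
    path = Path(path)
    n, h, w = stack.images.shape
    if n < 1:
        raise StackIOError("cannot write an empty stack")
    data = np.ascontiguousarray(stack.images, dtype="<f4")
    header = bytearray(1024)
    struct.pack_into("<4i", header, 0, w, h, n, 2)          # nx ny nz mode
    struct.pack_into("<3i", header, 16, 0, 0, 0)            # nxstart..
    struct.pack_into("<3i", header, 28, w, h, n)            # mx my mz
    apix = stack.pixel_size
    struct.pack_into("<3f", header, 40, w * apix, h * apix, n * apix)
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)   # cell angles
    struct.pack_into("<3i", header, 64, 1, 2, 3)            # axis order
    struct.pack_into("<3f", header, 76, float(data.min()), float(data.max()),
                     float(data.mean()))
    struct.pack_into("<2i", header, 88, 1, 0)               # ispg, nsymbt
    header[104:108] = b"MRCO"                               # EXTTYP (unused)
    struct.pack_into("<i", header, 108, 20140)              # NVERSION
    header[208:212] = _MAP_ID
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])       # little-endian stamp
    struct.pack_into("<f", header, 216, float(data.std()))  # RMS
    with open(path, "wb") as fh:
        fh.write(header)
        data.tofile(fh)


# ---------------------------------------------------------------------------
# STAR parameter tables
# ---------------------------------------------------------------------------

_STAR_COLUMNS = {
    "_prepParticleIndex": "index",
    "_rlnAnglePsi": "psi",
    "_rlnOriginX": "dx",
    "_rlnOriginY": "dy",
    "_prepMirror": "mirror",
}
_REQUIRED = ("psi", "dx", "dy", "mirror")


def write_params(table: ParamTable, path) -> None:
    """Write a ParamTable as a one-loop STAR data block.

    Columns: ``_prepParticleIndex`` (1-based), ``_rlnAnglePsi`` (deg),
    ``_rlnOriginX``/``_rlnOriginY`` (px), ``_prepMirror`` (0/1).
    """
    lines = ["data_particles", "", "loop_"]
    lines += [f"{name} #{i + 1}" for i, name in enumerate(_STAR_COLUMNS)]
    for i in range(len(table)):
        psi, dx, dy, mirror = table.row(i)
        lines.append(f"{i + 1:d} {psi:.10g} {dx:.10g} {dy:.10g} {int(mirror):d}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_params(path, expected_n: int | None = None) -> ParamTable:
    """Parse a STAR parameter table back into a :class:`ParamTable`.

    ``psi`` is renormalized to [0, 360) on read.  ``expected_n`` enforces
    agreement with a companion stack.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"no such parameter file: {path}")
    columns: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("data_"):
            continue
        if line == "loop_":
            in_loop = True
            columns, rows = [], []
            continue
        if in_loop and line.startswith("_"):
            columns.append(line.split()[0])
            continue
        if in_loop:
            rows.append(line.split())
    name_map = {star: short for star, short in _STAR_COLUMNS.items() if star in columns}
    present = set(name_map.values())
    missing = [c for c in _REQUIRED if c not in present]
    if missing:
        raise MissingColumnError(f"{path}: missing STAR column(s) for {missing}")
    if not rows:
        raise StackIOError(f"{path}: parameter table has no rows")
    frame = pd.DataFrame(rows, columns=columns)
    get = lambda short: frame[[k for k, v in _STAR_COLUMNS.items() if v == short][0]]
    table = ParamTable(
        psi=get("psi").astype(float).to_numpy(),
        dx=get("dx").astype(float).to_numpy(),
        dy=get("dy").astype(float).to_numpy(),
        mirror=get("mirror").astype(float).astype(int).astype(bool).to_numpy(),
    )
    if expected_n is not None and len(table) != expected_n:
        raise StackIOError(
            f"{path}: {len(table)} parameter rows for a stack of {expected_n}"
        )
    return table
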