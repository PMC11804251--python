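"""Reading and writing the file formats of the picking pipeline.

Volumes are exchanged as MRC2014 files and held in memory as float32 arrays
in (Z, Y, X) axis order — the storage order of the MRC format, where X is the
fastest axis.  Particle coordinates travel as RELION-style STAR tables
(``rlnCoordinateX/Y/Z``) or as whitespace-separated ``x y z`` point text of the
kind exported from IMOD models with ``model2point``.  A point stored at array
index ``(z, y, x)`` is written to file as ``rlnCoordinateX=x`` etc., so file
and memory conventions are mutually consistent.

Coordinates are 0-based voxel indices and written as floating point without
rounding.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .peaks import CentroidSet

__all__ = [
    "Volume",
    "ParticleSet",
    "read_volume",
    "write_volume",
    "read_coordinates",
    "write_star",
    "read_star_table",
    "write_star_table",
]

# MRC data modes we accept -> numpy dtypes (all promoted to float32 in memory)
_MRC_MODE_DTYPES = {
    0: np.int8,
    1: np.int16,
    2: np.float32,
    12: np.float16,
}

_HEADER_SIZE = 1024


@dataclass
class Volume:
    """A 3D scalar field with isotropic voxel spacing.

    Parameters
    ----------
    data:
        Array of shape ``(nz, ny, nx)``; stored as float32.
    voxel_size:
        Voxel spacing in Angstrom per pixel (> 0, isotropic).
    origin:
        Physical offset of the volume in Angstrom, ``(x, y, z)``.
    """

    data: np.ndarray
    voxel_size: float = 1.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"volume must be 3D with all dims >= 1, got shape {self.data.shape}")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.voxel_size, self.origin)


@dataclass
class ParticleSet:
    """Ground-truth particle centroids sharing one particle diameter.

    ``coordinates`` is an ``(n, 3)`` array of ``(x, y, z)`` positions in voxel
    units of the reference tomogram; ``diameter`` is the physical particle
    diameter in Angstrom (the longest axis for non-spherical particles) and
    ``voxel_size`` the Angstrom-per-pixel sampling of the reference frame.
    """

    coordinates: np.ndarray
    diameter: float
    voxel_size: float = 1.0
    tomo_id: str = "tomo"

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=np.float64)
        if coords.size == 0:
            coords = coords.reshape(0, 3)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coordinates must be (n, 3), got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        if not self.diameter > 0:
            raise ValueError(f"diameter must be > 0, got {self.diameter}")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        self.coordinates = coords

    def __len__(self) -> int:
        return len(self.coordinates)

    @property
    def diameter_px(self) -> float:
        """Particle diameter in voxel units of the reference frame."""
        return self.diameter / self.voxel_size

    @property
    def radius_px(self) -> float:
        """Particle radius in voxel units; always positive."""
        return self.diameter / (2.0 * self.voxel_size)


def _pack_header(vol: Volume) -> bytes:
    nz, ny, nx = vol.data.shape
    vs = float(vol.voxel_size)
    header = bytearray(_HEADER_SIZE)
    struct.pack_into("<3i", header, 0, nx, ny, nz)          # nx, ny, nz
    struct.pack_into("<i", header, 12, 2)                   # mode 2: float32
    struct.pack_into("<3i", header, 28, nx, ny, nz)         # mx, my, mz
    struct.pack_into("<3f", header, 40, nx * vs, ny * vs, nz * vs)  # cella
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)   # cellb
    struct.pack_into("<3i", header, 64, 1, 2, 3)            # mapc, mapr, maps
    data = vol.data
    struct.pack_into("<3f", header, 76, float(data.min()), float(data.max()), float(data.mean()))
    struct.pack_into("<i", header, 88, 1)                   # ispg: volume
    struct.pack_into("<i", header, 108, 20140)              # nversion (MRC2014)
    struct.pack_into("<3f", header, 196, *[float(o) for o in vol.origin])
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])       # little-endian machine stamp
    struct.pack_into("<f", header, 216, float(data.std()))
    struct.pack_into("<i", header, 220, 1)                  # nlabl
    header[224:224 + 30] = b"Created by tomopick           "
    return bytes(header)


def write_volume(volume: Volume, path: str | Path) -> None:
    """Write ``volume`` as an MRC2014 file (mode 2, float32, X fastest axis)."""
    if not np.all(np.isfinite(volume.data)):
        raise ValueError("volume data contains non-finite values; refusing to write")
    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(_pack_header(volume))
        fh.write(np.ascontiguousarray(volume.data, dtype="<f4").tobytes())


def read_volume(path: str | Path) -> Volume:
    """Read an MRC file (modes 0/1/2/12) into a float32 :class:`Volume`.

    The voxel size is taken from the cell dimensions of the header
    (``xlen / mx``); a non-positive value is rejected since downstream
    physical-unit conversions would be meaningless.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such MRC file: {path}")
    with open(path, "rb") as fh:
        header = fh.read(_HEADER_SIZE)
        if len(header) < _HEADER_SIZE:
            raise ValueError(f"{path}: truncated MRC header ({len(header)} bytes)")
        # Machine stamp: 0x44 -> little endian, 0x11 -> big endian.
        endian = ">" if header[212] == 0x11 else "<"
        nx, ny, nz = struct.unpack_from(endian + "3i", header, 0)
        (mode,) = struct.unpack_from(endian + "i", header, 12)
        mx, my, mz = struct.unpack_from(endian + "3i", header, 28)
        xlen, ylen, zlen = struct.unpack_from(endian + "3f", header, 40)
        ox, oy, oz = struct.unpack_from(endian + "3f", header, 196)
        (nsymbt,) = struct.unpack_from(endian + "i", header, 92)
        if mode not in _MRC_MODE_DTYPES:
            raise ValueError(f"{path}: unsupported MRC mode {mode} (supported: 0, 1, 2, 12)")
        if min(nx, ny, nz) < 1:
            raise ValueError(f"{path}: invalid dimensions ({nx}, {ny}, {nz})")
        if mx <= 0 or xlen <= 0:
            raise ValueError(
                f"{path}: non-positive voxel size in header (mx={mx}, xlen={xlen}); "
                "fix the header before use"
            )
        voxel_size = xlen / mx
        fh.seek(_HEADER_SIZE + nsymbt)
        dtype = np.dtype(_MRC_MODE_DTYPES[mode]).newbyteorder(endian)
        data = np.frombuffer(fh.read(nx * ny * nz * dtype.itemsize), dtype=dtype)
        if data.size != nx * ny * nz:
            raise ValueError(f"{path}: truncated data section")
        data = data.reshape(nz, ny, nx).astype(np.float32)
    return Volume(data, voxel_size=voxel_size, origin=(ox, oy, oz))


# ---------------------------------------------------------------------------
# STAR tables
# ---------------------------------------------------------------------------

def read_star_table(path: str | Path) -> pd.DataFrame:
    """Parse the first ``loop_`` table of a STAR file into a DataFrame.

    Handles the single-data-block dialect used for coordinate files: one
    ``data_`` block, one ``loop_``, ``_rln...`` column declarations, then
    whitespace-separated rows.  Unknown columns are preserved.
    """
    path = Path(path)
    columns: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("data_"):
                if rows:
                    break  # only the first block is read
                continue
            if line == "loop_":
                in_loop = True
                columns = []
                continue
            if line.startswith("_"):
                if not in_loop:
                    continue  # key-value pairs outside loops are ignored
                columns.append(line.split()[0].lstrip("_"))
                continue
            if in_loop and columns:
                values = line.split()
                if len(values) != len(columns):
                    raise ValueError(
                        f"{path}: row has {len(values)} fields, expected {len(columns)}: {line!r}"
                    )
                rows.append(values)
    frame = pd.DataFrame(rows, columns=columns if columns else None)
    for col in frame.columns:
        try:
            frame[col] = pd.to_numeric(frame[col])
        except (ValueError, TypeError):
            pass  # non-numeric column (e.g. rlnTomoName) stays as strings
    return frame


def write_star_table(frame: pd.DataFrame, path: str | Path, block: str = "data_") -> None:
    """Write a DataFrame as a single-block STAR ``loop_`` table."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"\n{block}\n\nloop_\n")
        for i, col in enumerate(frame.columns, start=1):
            fh.write(f"_{col} #{i}\n")
        for _, row in frame.iterrows():
            fh.write(" ".join(_format_star_value(v) for v in row) + "\n")


def _format_star_value(value) -> str:
    if isinstance(value, (float, np.floating)):
        return f"{value:.6f}"
    return str(value)


_COORD_COLUMNS = ("rlnCoordinateX", "rlnCoordinateY", "rlnCoordinateZ")


def read_coordinates(
    path: str | Path,
    format: str = "star",
    voxel_size: float = 1.0,
    diameter: float = 1.0,
    tomo_id: str | None = None,
) -> ParticleSet:
    """Read particle centroids from a STAR file or an x-y-z point-text file.

    Coordinates are interpreted as 0-based voxel positions in the reference
    tomogram.  An empty file yields an empty set with a warning rather than
    an error, since empty picks are a legitimate (if suspicious) outcome.
    """
    path = Path(path)
    if format == "star":
        frame = read_star_table(path)
        missing = [c for c in _COORD_COLUMNS if c not in frame.columns]
        if len(missing) == len(_COORD_COLUMNS) and frame.empty:
            warnings.warn(f"{path}: empty coordinate file", stacklevel=2)
            coords = np.zeros((0, 3))
        elif missing:
            raise ValueError(f"{path}: missing required STAR column(s): {', '.join(missing)}")
        else:
            coords = frame[list(_COORD_COLUMNS)].to_numpy(dtype=np.float64)
            if len(coords) == 0:
                warnings.warn(f"{path}: empty coordinate file", stacklevel=2)
    elif format == "point_text":
        coords_list = []
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: expected 'x y z', got {line!r}")
                try:
                    coords_list.append([float(p) for p in parts[:3]])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: unparseable line {line!r}") from exc
        coords = np.asarray(coords_list, dtype=np.float64).reshape(-1, 3)
        if coords.size == 0:
            warnings.warn(f"{path}: empty coordinate file", stacklevel=2)
    else:
        raise ValueError(f"unknown coordinate format {format!r} (use 'star' or 'point_text')")
    return ParticleSet(
        coords, diameter=diameter, voxel_size=voxel_size, tomo_id=tomo_id or path.stem
    )


def write_star(
    centroids: "CentroidSet",
    path: str | Path,
    scale_to_original: float = 1.0,
    tomo_name: str | None = None,
) -> None:
    """Write predicted centroids as a RELION-style STAR coordinate file.

    ``scale_to_original`` multiplies the coordinates so they refer to the
    original (pre-resize) pixel grid; the per-point confidence goes to
    ``rlnAutopickFigureOfMerit``.
    """
    if not scale_to_original > 0:
        raise ValueError(f"scale_to_original must be > 0, got {scale_to_original}")
    points = np.asarray(centroids.points, dtype=np.float64).reshape(-1, 3)
    if points.size and not np.all(np.isfinite(points)):
        raise ValueError("centroid coordinates must be finite")
    scaled = points * scale_to_original
    frame = pd.DataFrame(
        {
            "rlnCoordinateX": scaled[:, 0],
            "rlnCoordinateY": scaled[:, 1],
            "rlnCoordinateZ": scaled[:, 2],
            "rlnAutopickFigureOfMerit": np.asarray(centroids.scores, dtype=np.float64),
        }
    )
    if tomo_name is not None:
        frame["rlnTomoName"] = tomo_name
    write_star_table(frame, path)
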