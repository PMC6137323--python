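"""Label-volume and metrics-table I/O.

This module owns the compartment-code convention used by every other module:
a segmented mitochondrion is a 3D integer grid (z, y, x order, z being the
tomographic/beam axis) in which each voxel carries one :class:`Compartment`
code. Volumes are exchanged as MRC2014 files (integer modes; the reference
dialect) or multi-page TIFF stacks, with an isotropic voxel size in Angstrom
taken from the MRC header or supplied explicitly.

Metric tables are plain CSV with ``#``-prefixed metadata lines.
"""

from __future__ import annotations

import dataclasses
import struct
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Compartment",
    "VALID_CODES",
    "LabelVolume",
    "LabelValidationError",
    "VoxelSizeError",
    "read_label_volume",
    "write_label_volume",
    "write_metrics_table",
    "read_metrics_table",
]


class Compartment(IntEnum):
    """Fixed compartment codes for a segmented mitochondrion.

    The intermembrane/peripheral space between MOM and IBM, like everything
    outside the organelle, is unlabelled (``BACKGROUND``).
    """

    BACKGROUND = 0
    MOM = 1            # mitochondrial outer membrane
    IBM = 2            # inner boundary membrane (non-crista part of the MIM)
    CRISTA_MEMBRANE = 3
    ICS = 4            # intracristal space (crista lumen)
    MATRIX = 5
    GRANULE = 6        # matrix granule (MG)


VALID_CODES = frozenset(int(c) for c in Compartment)


class LabelValidationError(ValueError):
    """A volume contains a voxel value outside the closed code set."""


class VoxelSizeError(ValueError):
    """Voxel size missing, non-positive or anisotropic without an override."""


def _validate_grid(grid: np.ndarray) -> None:
    if grid.ndim != 3 or grid.size == 0:
        raise ValueError(f"label grid must be a non-empty 3D array, got shape {grid.shape}")
    bad = (grid < 0) | (grid > max(VALID_CODES))
    if bad.any():
        z, y, x = (int(i) for i in np.argwhere(bad)[0])
        raise LabelValidationError(
            f"unknown compartment code {int(grid[z, y, x])} at voxel (z={z}, y={y}, x={x}); "
            f"valid codes are {sorted(VALID_CODES)}"
        )


@dataclass
class LabelVolume:
    """A compartment-labelled 3D grid with physical voxel size.

    Parameters
    ----------
    grid:
        3D integer array in (z, y, x) order; values must be valid
        :class:`Compartment` codes.
    voxel_size_A:
        Isotropic edge length of one voxel in Angstrom, > 0.
    provenance:
        Free-text source tag (file path, generator parameters, ...).
    """

    grid: np.ndarray
    voxel_size_A: float
    provenance: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if not np.issubdtype(self.grid.dtype, np.integer):
            if not np.all(self.grid == np.round(self.grid)):
                raise LabelValidationError("label grid contains non-integer values")
            self.grid = self.grid.astype(np.uint8)
        _validate_grid(self.grid)
        self.grid = self.grid.astype(np.uint8, copy=False)
        if not (float(self.voxel_size_A) > 0):
            raise VoxelSizeError(f"voxel_size_A must be > 0, got {self.voxel_size_A}")
        self.voxel_size_A = float(self.voxel_size_A)

    # -- convenience -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def mask(self, code: Compartment | int | Iterable[int]) -> np.ndarray:
        """Boolean mask of one code or a set of codes."""
        if isinstance(code, (int, np.integer, Compartment)):
            return self.grid == int(code)
        codes = [int(c) for c in code]
        return np.isin(self.grid, codes)

    def count(self, code: Compartment | int) -> int:
        return int(np.count_nonzero(self.grid == int(code)))

    def with_grid(self, grid: np.ndarray, note: str = "") -> "LabelVolume":
        prov = self.provenance if not note else f"{self.provenance} | {note}".strip(" |")
        return LabelVolume(grid, self.voxel_size_A, prov, dict(self.meta))


# ---------------------------------------------------------------------------
# Minimal MRC2014 support (integer label volumes only)
# ---------------------------------------------------------------------------

_MRC_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}


def _read_mrc(path: Path) -> tuple[np.ndarray, float | None]:
    with open(path, "rb") as fh:
        header = fh.read(1024)
        if len(header) < 1024:
            raise ValueError(f"{path}: truncated MRC header")
        nx, ny, nz, mode = struct.unpack("<4i", header[0:16])
        mx, my, mz = struct.unpack("<3i", header[28:40])
        xlen, ylen, zlen = struct.unpack("<3f", header[40:52])
        mapc, mapr, maps = struct.unpack("<3i", header[64:76])
        nsymbt = struct.unpack("<i", header[92:96])[0]
        if (mapc, mapr, maps) not in ((1, 2, 3), (0, 0, 0)):
            raise ValueError(f"{path}: unsupported MRC axis order {(mapc, mapr, maps)}")
        if mode not in _MRC_MODE_DTYPES:
            raise ValueError(f"{path}: unsupported MRC mode {mode} for a label volume")
        fh.seek(1024 + nsymbt)
        data = np.fromfile(fh, dtype=_MRC_MODE_DTYPES[mode], count=nx * ny * nz)
    if data.size != nx * ny * nz:
        raise ValueError(f"{path}: truncated MRC data block")
    grid = data.reshape(nz, ny, nx)
    voxel: float | None = None
    if mx > 0 and my > 0 and mz > 0 and xlen > 0:
        sizes = np.array([xlen / mx, ylen / my, zlen / mz])
        if not np.allclose(sizes, sizes[0], rtol=1e-3):
            raise VoxelSizeError(
                f"{path}: anisotropic voxel size {sizes} in header; pass voxel_size_override"
            )
        voxel = float(sizes[0])
    return grid, voxel


def _write_mrc(path: Path, vol: LabelVolume) -> None:
    grid = vol.grid.astype(np.int8)
    nz, ny, nx = grid.shape
    v = vol.voxel_size_A
    header = bytearray(1024)
    struct.pack_into("<4i", header, 0, nx, ny, nz, 0)            # mode 0 = int8
    struct.pack_into("<3i", header, 28, nx, ny, nz)              # mx, my, mz
    struct.pack_into("<3f", header, 40, nx * v, ny * v, nz * v)  # cella
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)        # cellb
    struct.pack_into("<3i", header, 64, 1, 2, 3)                 # mapc, mapr, maps
    struct.pack_into("<3f", header, 76, float(grid.min()), float(grid.max()),
                     float(grid.mean()))
    struct.pack_into("<i", header, 88, 1)                        # ispg
    header[208:212] = b"MAP "
    header[212:216] = bytes((0x44, 0x44, 0x00, 0x00))            # little-endian stamp
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        grid.tofile(fh)


# ---------------------------------------------------------------------------
# Public readers / writers
# ---------------------------------------------------------------------------

_TIFF_SUFFIXES = {".tif", ".tiff"}


def read_label_volume(path: str | Path, voxel_size_override: float | None = None) -> LabelVolume:
    """Read a segmentation from MRC or TIFF.

    Voxel size comes from ``voxel_size_override`` (Angstrom) when given,
    otherwise from the MRC header. TIFF stacks carry no trusted physical
    size, so the override is mandatory for them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        import tifffile

        grid = np.asarray(tifffile.imread(str(path)))
        header_voxel = None
    else:
        grid, header_voxel = _read_mrc(path)
    voxel = voxel_size_override if voxel_size_override is not None else header_voxel
    if voxel is None:
        raise VoxelSizeError(
            f"{path}: no voxel size in header and no voxel_size_override given"
        )
    return LabelVolume(grid, voxel, provenance=str(path))


def write_label_volume(vol: LabelVolume, path: str | Path) -> Path:
    """Write a label volume as MRC (mode 0) or TIFF, chosen by extension."""
    path = Path(path)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        import tifffile

        tifffile.imwrite(str(path), vol.grid, resolution=None)
    else:
        _write_mrc(path, vol)
    return path


# ---------------------------------------------------------------------------
# Metric tables
# ---------------------------------------------------------------------------


def _to_record_dict(rec) -> dict:
    if dataclasses.is_dataclass(rec) and not isinstance(rec, type):
        return dataclasses.asdict(rec)
    if isinstance(rec, Mapping):
        return dict(rec)
    raise TypeError(f"metric record must be a dataclass or mapping, got {type(rec)}")


def write_metrics_table(
    records: Sequence,
    path: str | Path,
    metadata: Mapping[str, object] | None = None,
    columns: Sequence[str] | None = None,
) -> Path:
    """Write one row per record to CSV, with ``#`` metadata lines up front.

    All records must share one schema (same keys); the output is bit-stable
    for a fixed input.
    """
    path = Path(path)
    dicts = [_to_record_dict(r) for r in records]
    if dicts:
        schema = list(dicts[0].keys())
        for i, d in enumerate(dicts[1:], start=1):
            if list(d.keys()) != schema:
                raise ValueError(
                    f"mixed record schemas: record 0 has columns {schema}, "
                    f"record {i} has {list(d.keys())}"
                )
        df = pd.DataFrame(dicts)
    else:
        df = pd.DataFrame(columns=list(columns or []))
    lines = []
    for key, val in (metadata or {}).items():
        lines.append(f"# {key}: {val}")
    with open(path, "w") as fh:
        for line in lines:
            fh.write(line + "\n")
        df.to_csv(fh, index=False)
    return path


def read_metrics_table(path: str | Path) -> pd.DataFrame:
    """Read a metrics CSV written by :func:`write_metrics_table`."""
    return pd.read_csv(path, comment="#")
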