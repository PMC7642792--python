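"""MRC volume and mask I/O and the geometric contracts shared by all modules.

All volumes are cubic (n × n × n, n even and ≥ 8) real-valued grids with a
pixel size in Å.  The in-memory axis convention is fixed: ``data[s, r, c]``
indexes (section, row, column), matching the storage order of maps written by
:func:`write_volume`.  Maps read from disk are reordered to this convention.

MRC2014 files are read and written through :mod:`gemmi`; mode-2 (float32) is
the native on-disk representation, other numeric modes are converted to float
with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np


class GeometryError(ValueError):
    """Volume/mask grids that violate the cubic, even-sized contract."""


class MapFormatError(ValueError):
    """Unreadable, truncated or otherwise malformed map files."""


class EmptyMaskError(ValueError):
    """A mask with no support: the mFSC is undefined on an empty region."""


def _validate_grid(data: np.ndarray, what: str = "volume") -> int:
    if data.ndim != 3:
        raise GeometryError(f"{what} must be 3D, got shape {data.shape}")
    nz, ny, nx = data.shape
    if not (nz == ny == nx):
        raise GeometryError(f"{what} must be cubic, got shape {data.shape}")
    if nz < 8:
        raise GeometryError(f"{what} linear size must be >= 8, got {nz}")
    if nz % 2:
        raise GeometryError(
            f"{what} linear size must be even (Nyquist index n/2, Friedel "
            f"symmetry), got {nz}"
        )
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{what} contains non-finite values")
    return nz


@dataclass
class Volume:
    """A cubic 3D density grid with its sampling in Å per voxel."""

    data: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.n = _validate_grid(self.data)
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")

    def same_geometry(self, other: "Volume | Mask") -> bool:
        return self.n == other.n and np.isclose(self.pixel_size, other.pixel_size)

    def require_same_geometry(self, other: "Volume | Mask") -> None:
        if not self.same_geometry(other):
            raise GeometryError(
                f"geometry mismatch: n={self.n}, p={self.pixel_size} vs "
                f"n={other.n}, p={other.pixel_size}"
            )


@dataclass
class Mask:
    """A real-space support region; weights in [0, 1].

    ``count`` is the number of strictly positive voxels of the binarized
    form (|m| in the ndf mask-fraction correction).  A soft mask can be used
    multiplicatively with the classical FSC; the mFSC requires the binary
    form (see :func:`binarize_mask`).
    """

    data: np.ndarray
    pixel_size: float = 1.0
    count: int = field(init=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.n = _validate_grid(self.data, "mask")
        if self.data.min() < 0 or self.data.max() > 1:
            raise ValueError("mask weights must lie in [0, 1]")
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        # |m| of the binarized form; if the mask is so shallow that the 0.5
        # threshold would empty it, fall back to counting any positive weight
        self.count = int(np.count_nonzero(self.data > 0.5)) or \
            int(np.count_nonzero(self.data > 0))

    @property
    def is_binary(self) -> bool:
        return bool(np.isin(self.data, (0.0, 1.0)).all())

    @property
    def fraction(self) -> float:
        """|m|/n³ — the fraction of the volume inside the binary mask."""
        return self.count / self.n**3

    def boolean(self) -> np.ndarray:
        """Binary support as a boolean array (weights > 0.5)."""
        return self.data > 0.5


def binarize_values(data: np.ndarray, threshold: float) -> np.ndarray:
    return (data > threshold).astype(np.float64)


def binarize_mask(m: Mask, threshold: float = 0.5) -> Mask:
    """Threshold a (possibly soft) mask to {0, 1}.

    Idempotent on already-binary masks and monotone in the threshold.
    Raises :class:`EmptyMaskError` if nothing survives.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    out = binarize_values(m.data, threshold)
    if not out.any():
        raise EmptyMaskError(
            f"mask is empty after binarization at {threshold} "
            f"(max weight {m.data.max():g})"
        )
    return Mask(out, pixel_size=m.pixel_size)


def _read_grid(path: str | Path) -> tuple[np.ndarray, float]:
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise MapFormatError(f"cannot read MRC map {path!r}: {exc}") from exc
    mode = ccp4.header_i32(4)
    if mode != 2:
        warnings.warn(
            f"{path}: MRC mode {mode} converted to float32", stacklevel=3
        )
    # normalize on-disk axis permutations to the fixed in-memory convention
    ccp4.setup(0.0, gemmi.MapSetup.ReorderOnly)
    data = np.array(ccp4.grid, copy=True).astype(np.float64)
    spacing = ccp4.grid.spacing
    pixel = float(spacing[0]) if spacing[0] > 0 else 0.0
    if pixel <= 0:
        warnings.warn(
            f"{path}: pixel size missing or zero in header; assuming 1.0 Å",
            stacklevel=3,
        )
        pixel = 1.0
    return data, pixel


def read_volume(path: str | Path) -> Volume:
    """Read a cubic MRC map as a :class:`Volume`.

    The pixel size is taken from the header (cell edge / sampling); a zero
    pixel size falls back to 1.0 Å with a warning.  Non-cubic maps raise
    :class:`GeometryError`.
    """
    data, pixel = _read_grid(path)
    return Volume(data, pixel_size=pixel)


def read_mask(path: str | Path) -> Mask:
    """Read an MRC map as a :class:`Mask` (weights clipped to [0, 1])."""
    data, pixel = _read_grid(path)
    if data.min() < -1e-6 or data.max() > 1 + 1e-6:
        warnings.warn(f"{path}: mask weights outside [0, 1] were clipped")
    return Mask(np.clip(data, 0.0, 1.0), pixel_size=pixel)


def _write_grid(data: np.ndarray, pixel_size: float, path: str | Path) -> None:
    n = data.shape[0]
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = gemmi.FloatGrid(np.ascontiguousarray(data, dtype=np.float32))
    edge = n * pixel_size
    ccp4.grid.unit_cell = gemmi.UnitCell(edge, edge, edge, 90.0, 90.0, 90.0)
    ccp4.grid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))


def write_volume(v: Volume, path: str | Path) -> None:
    """Write a :class:`Volume` as an MRC2014 mode-2 (float32) map."""
    _write_grid(v.data, v.pixel_size, path)


def write_mask(m: Mask, path: str | Path) -> None:
    """Write a :class:`Mask` as an MRC2014 mode-2 map."""
    _write_grid(m.data, m.pixel_size, path)
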