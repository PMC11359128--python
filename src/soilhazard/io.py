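"""Sample-table container and plain-text I/O (sample CSV, ESRI ASCII grid).

The sample CSV dialect is comma-separated UTF-8 with a header row and "."
decimal separator.  Required columns are ``id``, ``x``, ``y`` (planar km);
every remaining numeric column is treated as a metal concentration in
mg kg^-1.  Column order beyond ``id,x,y`` is free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "SampleSet",
    "read_sample_csv",
    "write_sample_csv",
    "write_ascii_grid",
    "read_ascii_grid",
]

#: canonical metal order used throughout the package
METALS = ["As", "Cd", "Co", "Cr", "Cu", "Mn", "Ni", "Pb", "V", "Fe", "Zn"]

_COORD_COLS = ("id", "x", "y")


class ValidationError(ValueError):
    """Raised when an input table or configuration violates a contract."""


@dataclass
class SampleSet:
    """Georeferenced table of topsoil metal concentrations.

    Attributes
    ----------
    frame : pandas.DataFrame
        One row per sample with columns ``id, x, y`` plus one column per
        metal (mg kg^-1).  Coordinates are planar kilometres.
    zones : numpy.ndarray or None
        True contamination-zone labels (1/2) for synthetic sets; ``None``
        for field data.  Used only by recovery tests, never by the
        analysis itself.
    """

    frame: pd.DataFrame
    zones: np.ndarray | None = field(default=None, repr=False)
    #: set False for derived tables (z-scores, residuals) that may go negative
    nonnegative: bool = True

    def __post_init__(self) -> None:
        self.frame = self.frame.copy()
        _validate_frame(self.frame, nonnegative=self.nonnegative)

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def metals(self) -> list[str]:
        return [c for c in self.frame.columns if c not in _COORD_COLS]

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of x/y coordinates in km."""
        return self.frame[["x", "y"]].to_numpy(dtype=float)

    def values(self, metal: str) -> np.ndarray:
        if metal not in self.metals:
            raise ValidationError(f"unknown metal column {metal!r}; have {self.metals}")
        return self.frame[metal].to_numpy(dtype=float)

    def subset_metals(self, metals: list[str]) -> "SampleSet":
        missing = [m for m in metals if m not in self.metals]
        if missing:
            raise ValidationError(f"metals not present in sample table: {missing}")
        cols = ["id", "x", "y", *metals]
        return SampleSet(self.frame[cols].copy(), zones=self.zones)

    def matrix(self, metals: list[str] | None = None) -> np.ndarray:
        """(n, p) concentration matrix in the given metal order."""
        metals = metals if metals is not None else self.metals
        return np.column_stack([self.values(m) for m in metals])


def _validate_frame(frame: pd.DataFrame, nonnegative: bool = True) -> None:
    if len(frame) == 0:
        raise ValidationError("no samples")
    for col in _COORD_COLS:
        if col not in frame.columns:
            raise ValidationError(f"missing required column {col!r}")
    if frame["id"].duplicated().any():
        dups = frame.loc[frame["id"].duplicated(), "id"].tolist()
        raise ValidationError(f"duplicate sample ids: {dups}")
    metal_cols = [c for c in frame.columns if c not in _COORD_COLS]
    for col in ("x", "y", *metal_cols):
        vals = pd.to_numeric(frame[col], errors="coerce")
        if vals.isna().any():
            bad = frame.loc[vals.isna(), "id"].tolist()
            raise ValidationError(f"non-numeric value in column {col!r} for ids {bad}")
        frame[col] = vals.astype(float)
    for col in metal_cols if nonnegative else []:
        if (frame[col] < 0).any():
            bad = frame.loc[frame[col] < 0, "id"].tolist()
            raise ValidationError(
                f"negative concentration in column {col!r} for ids {bad}"
            )


def read_sample_csv(path) -> SampleSet:
    """Read a sample CSV, validating ids, coordinates and concentrations."""
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError("no samples") from exc
    return SampleSet(frame)


def write_sample_csv(samples: SampleSet, path) -> None:
    """Write a sample table; values round-trip to 6 significant digits."""
    samples.frame.to_csv(path, index=False, float_format="%.6g")


def write_ascii_grid(path, grid: np.ndarray, origin: tuple[float, float],
                     cell_size: float, nodata: float = -9999.0) -> None:
    """Write a 2-D array as an ESRI ASCII grid (.asc).

    ``grid`` is row-major with row 0 at the *south* edge (matching the
    package's raster convention); the .asc format stores rows north-first,
    so rows are flipped on write.  ``origin`` is the (x, y) lower-left
    corner in km.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2:
        raise ValidationError("grid must be 2-D")
    out = np.where(np.isfinite(grid), grid, nodata)
    nrows, ncols = grid.shape
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {origin[0]:.6f}\n")
        fh.write(f"yllcorner {origin[1]:.6f}\n")
        fh.write(f"cellsize {cell_size:.6f}\n")
        fh.write(f"NODATA_value {nodata:g}\n")
        for row in out[::-1]:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def read_ascii_grid(path) -> tuple[np.ndarray, tuple[float, float], float]:
    """Read an ESRI ASCII grid; returns (grid south-row-first, origin, cell_size)."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    grid = np.array(rows, dtype=float)[::-1]
    nodata = header.get("nodata_value", -9999.0)
    grid[grid == nodata] = np.nan
    if grid.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValidationError("ASCII grid dimensions inconsistent with header")
    return grid, (header["xllcorner"], header["yllcorner"]), header["cellsize"]
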