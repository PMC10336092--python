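"""Raster I/O and analysis-grid construction.

Forest maps are binary lattices (1 = forest, 0 = non-forest, NODATA masked)
on a projected equal-area coordinate system with square pixels.  Maps are
read and written in the Esri AAIGrid (ASCII grid) format, with the CRS
carried in an optional WKT ``.prj`` sidecar.  The study extent is tiled into
fixed-size square analysis cells ("landscapes"); each cell is later treated
as an independent landscape for metric computation.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field, replace

import numpy as np

#: Internal nodata code inside ``BinaryForestMap.values``.
NODATA = -1

#: Default nodata sentinel written to AAIGrid files.
AAIGRID_NODATA = -9999


class RasterFormatError(ValueError):
    """Raised for unreadable or unsupported raster input."""


class CRSError(ValueError):
    """Raised when a raster's coordinate system is unusable (e.g. degrees)."""


@dataclass
class BinaryForestMap:
    """A georeferenced binary forest/non-forest lattice.

    Parameters
    ----------
    values
        2-D int8 array with entries in {0, 1, NODATA}.
    pixel_size
        Ground size of one (square) pixel in metres.
    origin
        (x, y) of the upper-left corner of the upper-left pixel, in
        projected metres.
    crs_id
        Free-text identifier of the projected reference system.
    epoch
        Year label (e.g. 2000); not compared during co-registration checks.
    """

    values: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    crs_id: str = "unspecified-projected"
    epoch: object = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] < 1 or v.shape[1] < 1:
            raise ValueError("values must be a 2-D lattice with >= 1 row and column")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        bad = ~np.isin(v, (0, 1, NODATA))
        if bad.any():
            raise ValueError("values must contain only {0, 1, nodata}")
        self.values = v.astype(np.int8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def forest_mask(self) -> np.ndarray:
        return self.values == 1

    @property
    def valid_mask(self) -> np.ndarray:
        return self.values != NODATA

    @property
    def forest_pixels(self) -> int:
        return int(self.forest_mask.sum())

    def with_values(self, values: np.ndarray) -> "BinaryForestMap":
        """Copy of this map with replaced pixel values (same georeferencing)."""
        return replace(self, values=values)


@dataclass(frozen=True)
class GridCell:
    """One analysis cell: a half-open pixel window [row0:row1, col0:col1]."""

    cell_id: int
    row0: int
    row1: int
    col0: int
    col1: int
    partial: bool = False

    @property
    def window(self) -> tuple[slice, slice]:
        return (slice(self.row0, self.row1), slice(self.col0, self.col1))


@dataclass
class AnalysisGrid:
    """Tiling of a raster extent into square analysis cells.

    ``cell_area`` is the landscape area *A* (m^2) used as the denominator of
    the edge-density and patch-density metrics; for full cells it equals
    ``cell_size ** 2``.
    """

    cell_size: float
    pixel_size: float
    n_cell_rows: int
    n_cell_cols: int
    cells: list[GridCell] = field(default_factory=list)

    @property
    def cell_area(self) -> float:
        return float(self.cell_size) ** 2

    @property
    def pixels_per_side(self) -> int:
        return int(round(self.cell_size / self.pixel_size))

    def cell_row_col(self, cell_id: int) -> tuple[int, int]:
        """Cell-grid (row, col) of a cell_id (row-major from top-left)."""
        return divmod(cell_id, self.n_cell_cols)


# ---------------------------------------------------------------------------
# AAIGrid I/O

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def _read_prj(path: str) -> str | None:
    prj = os.path.splitext(path)[0] + ".prj"
    if os.path.exists(prj):
        with open(prj) as fh:
            return fh.read().strip()
    return None


def _crs_is_geographic(wkt: str) -> bool:
    head = wkt.lstrip().upper()
    if head.startswith("GEOGCS") or head.startswith("GEOGCRS"):
        return True
    return bool(re.search(r'UNIT\s*\[\s*"degree', wkt, flags=re.IGNORECASE))


def read_ascii_grid(path: str) -> tuple[np.ndarray, dict]:
    """Read an Esri AAIGrid file into a float array plus header metadata."""
    header: dict = {}
    data_lines: list[str] = []
    try:
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                key = parts[0].lower()
                if not data_lines and key in _HEADER_KEYS + ("nodata_value", "dx", "dy"):
                    header[key] = float(parts[1])
                else:
                    data_lines.append(line)
    except OSError as exc:
        raise RasterFormatError(f"cannot read raster file {path!r}: {exc}") from exc
    for key in _HEADER_KEYS:
        if key not in header:
            raise RasterFormatError(f"{path!r}: missing AAIGrid header field {key!r}")
    if "dx" in header or "dy" in header:
        if header.get("dx") != header.get("dy"):
            raise RasterFormatError(f"{path!r}: non-square pixels (dx != dy) are not supported")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    values = np.loadtxt(data_lines, dtype=float)
    values = np.atleast_2d(values)
    if values.shape != (nrows, ncols):
        values = values.reshape(nrows, ncols)
    return values, header


def read_forest_map(path: str, epoch: object = None) -> BinaryForestMap:
    """Read and binarize a forest raster.

    Any valid value >= 0.5 becomes forest (1); values below 0.5 become
    non-forest (0); the file's nodata sentinel is preserved as a mask.  A
    geographic (degree-unit) CRS in the ``.prj`` sidecar is rejected: metrics
    are defined per unit ground area and require a projected equal-area
    system — reproject before use.
    """
    raw, header = read_ascii_grid(path)
    wkt = _read_prj(path)
    crs_id = "unspecified-projected"
    if wkt is not None:
        if _crs_is_geographic(wkt):
            raise CRSError(
                f"{path!r} is in a geographic (degree) CRS; reproject to a "
                "projected equal-area system with metre units first"
            )
        crs_id = wkt.splitlines()[0][:200]
    nodata = header.get("nodata_value")
    values = np.where(raw >= 0.5, 1, 0).astype(np.int8)
    if nodata is not None:
        values[raw == nodata] = NODATA
    cellsize = header["cellsize"]
    nrows = int(header["nrows"])
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cellsize)
    return BinaryForestMap(values, pixel_size=cellsize, origin=origin,
                           crs_id=crs_id, epoch=epoch)


def write_ascii_grid(path: str, values: np.ndarray, pixel_size: float,
                     origin: tuple[float, float] = (0.0, 0.0),
                     nodata: float = AAIGRID_NODATA, crs_wkt: str | None = None,
                     fmt: str = "%.6g") -> None:
    """Write a 2-D array as Esri AAIGrid (+ optional ``.prj`` sidecar).

    NaN entries are written as the nodata sentinel.
    """
    values = np.asarray(values, dtype=float)
    nrows, ncols = values.shape
    out = np.where(np.isnan(values), nodata, values)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {origin[0]:.6f}\n")
        fh.write(f"yllcorner {origin[1] - nrows * pixel_size:.6f}\n")
        fh.write(f"cellsize {pixel_size:.6f}\n")
        fh.write(f"NODATA_value {nodata:g}\n")
        np.savetxt(fh, out, fmt=fmt)
    if crs_wkt is not None:
        with open(os.path.splitext(path)[0] + ".prj", "w") as fh:
            fh.write(crs_wkt)


def write_forest_map(path: str, fmap: BinaryForestMap,
                     nodata: float = AAIGRID_NODATA) -> None:
    vals = fmap.values.astype(float)
    vals[fmap.values == NODATA] = np.nan
    crs = fmap.crs_id if fmap.crs_id != "unspecified-projected" else None
    write_ascii_grid(path, vals, fmap.pixel_size, fmap.origin,
                     nodata=nodata, crs_wkt=crs, fmt="%d")


# ---------------------------------------------------------------------------
# Co-registration and gridding

def check_coregistration(map_a: BinaryForestMap, map_b: BinaryForestMap,
                         tol: float = 1e-6) -> tuple[bool, list[str]]:
    """Check two maps share shape, pixel size, origin and CRS.

    Epoch labels are deliberately not compared.  Returns ``(ok, report)``
    where *report* lists the mismatched attributes.
    """
    report: list[str] = []
    if map_a.shape != map_b.shape:
        report.append(f"shape: {map_a.shape} != {map_b.shape}")
    if abs(map_a.pixel_size - map_b.pixel_size) > tol:
        report.append(f"pixel_size: {map_a.pixel_size} != {map_b.pixel_size}")
    if (abs(map_a.origin[0] - map_b.origin[0]) > tol
            or abs(map_a.origin[1] - map_b.origin[1]) > tol):
        report.append(f"origin: {map_a.origin} != {map_b.origin}")
    if map_a.crs_id != map_b.crs_id:
        report.append(f"crs_id: {map_a.crs_id!r} != {map_b.crs_id!r}")
    return (not report, report)


def build_grid(fmap: BinaryForestMap, cell_size: float,
               keep_partial: bool = False) -> AnalysisGrid:
    """Tile a map's extent into square analysis cells of ``cell_size`` metres.

    ``cell_size`` must be a positive integer multiple of the pixel size so
    that cell windows land exactly on pixel boundaries.  Partial cells at the
    right/bottom edges are excluded by default because their ground area
    differs from ``cell_size**2``, the denominator of the density metrics.
    Cell ids are assigned row-major from the top-left and are deterministic.
    """
    ratio = cell_size / fmap.pixel_size
    npix = int(round(ratio))
    if npix < 1 or abs(ratio - npix) > 1e-9:
        raise ValueError(
            f"cell_size ({cell_size}) must be a positive integer multiple of "
            f"pixel_size ({fmap.pixel_size})"
        )
    nrows, ncols = fmap.shape
    n_cell_rows = -(-nrows // npix) if keep_partial else nrows // npix
    n_cell_cols = -(-ncols // npix) if keep_partial else ncols // npix
    cells: list[GridCell] = []
    cid = 0
    for cr in range(n_cell_rows):
        for cc in range(n_cell_cols):
            r0, c0 = cr * npix, cc * npix
            r1, c1 = min(r0 + npix, nrows), min(c0 + npix, ncols)
            partial = (r1 - r0 != npix) or (c1 - c0 != npix)
            if partial and not keep_partial:
                continue
            cells.append(GridCell(cid, r0, r1, c0, c1, partial))
            cid += 1
    return AnalysisGrid(cell_size=cell_size, pixel_size=fmap.pixel_size,
                        n_cell_rows=n_cell_rows, n_cell_cols=n_cell_cols,
                        cells=cells)


def read_zone_map(path: str) -> np.ndarray:
    """Read an integer zone/category raster (AAIGrid); nodata becomes -1."""
    raw, header = read_ascii_grid(path)
    zones = raw.astype(int)
    nodata = header.get("nodata_value")
    if nodata is not None:
        zones[raw == nodata] = -1
    return zones


def zones_per_cell(zone_pixels: np.ndarray, grid: AnalysisGrid) -> dict[int, int]:
    """Majority-vote zone code per analysis cell (-1/nodata ignored)."""
    out: dict[int, int] = {}
    for cell in grid.cells:
        win = zone_pixels[cell.window]
        valid = win[win >= 0]
        if valid.size == 0:
            continue
        codes, counts = np.unique(valid, return_counts=True)
        out[cell.cell_id] = int(codes[np.argmax(counts)])
    return out
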