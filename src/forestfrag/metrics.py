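"""Class-level landscape fragmentation metrics per analysis cell.

For each cell ("landscape") of ground area A (m^2) the three classic
class-level metrics of the forest class are computed from the binary window:

    ED  = (total forest/non-forest edge length, m) / A * 10,000     [m/ha]
    PD  = (number of forest patches) / A * 10,000 * 100             [/100 ha]
    MPA = mean forest patch area                                    [ha]

together with forest coverage FC = forest area / A.  ED proxies the edge
effect, PD the isolation effect, MPA the patch-size effect.  Patches are
maximal connected components of forest pixels (8-connectivity by default)
evaluated per cell window independently: patches spanning a cell border are
truncated at the window, since each grid cell is treated as a landscape in
its own right.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import NODATA, AnalysisGrid, BinaryForestMap

#: square metres per hectare
M2_PER_HA = 10_000.0

_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCT8 = np.ones((3, 3), dtype=bool)

METRICS_COLUMNS = ["cell_id", "epoch", "ED", "PD", "MPA", "FC",
                   "forest_pixels", "n_patches", "e_total", "is_forest"]


@dataclass
class PatchLabeling:
    """Connected-component labelling of forest pixels in one window.

    ``labels`` holds 0 for non-forest/nodata and k >= 1 for patch k; labels
    are assigned in row-major order of each patch's first pixel, so the
    labelling is deterministic.  ``patch_areas`` is in hectares.
    """

    labels: np.ndarray
    n_patches: int
    patch_areas: np.ndarray
    connectivity: int


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return _STRUCT4
    if connectivity == 8:
        return _STRUCT8
    raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")


def label_patches(window: np.ndarray, connectivity: int = 8,
                  pixel_size: float = 1.0) -> PatchLabeling:
    """Label maximal connected components of forest pixels.

    nodata is treated as non-forest for labelling.  Labels follow row-major
    first-pixel order regardless of the underlying labelling algorithm.
    """
    window = np.asarray(window)
    if window.size == 0:
        raise ValueError("empty window")
    forest = window == 1
    raw, n = ndimage.label(forest, structure=_structure(connectivity))
    if n > 0:
        flat = raw.ravel()
        nz = np.flatnonzero(flat)
        first = np.full(n + 1, flat.size, dtype=np.int64)
        # reverse scan leaves the first (lowest flat index) occurrence
        first[flat[nz][::-1]] = nz[::-1]
        order = np.argsort(first[1:], kind="stable")
        remap = np.zeros(n + 1, dtype=raw.dtype)
        remap[1 + order] = np.arange(1, n + 1)
        raw = remap[raw]
    areas_px = np.bincount(raw.ravel(), minlength=n + 1)[1:].astype(float)
    areas_ha = areas_px * pixel_size ** 2 / M2_PER_HA
    return PatchLabeling(labels=raw, n_patches=int(n),
                         patch_areas=areas_ha, connectivity=connectivity)


def edge_length(window: np.ndarray, pixel_size: float,
                count_boundary: bool = False) -> float:
    """Total forest/non-forest edge length in metres within a window.

    An edge segment is a shared side between a forest pixel and a non-forest
    pixel (4-neighbourhood); each contributes one pixel_size of length.
    Forest/nodata adjacencies are not edges.  With ``count_boundary`` the
    window-border sides of forest pixels are added as well (off by default:
    a fully forested landscape should read as edge-free).
    """
    w = np.asarray(window)
    forest = w == 1
    open_ = w == 0  # nodata excluded on purpose
    n = 0
    n += np.count_nonzero(forest[:, :-1] & open_[:, 1:])
    n += np.count_nonzero(open_[:, :-1] & forest[:, 1:])
    n += np.count_nonzero(forest[:-1, :] & open_[1:, :])
    n += np.count_nonzero(open_[:-1, :] & forest[1:, :])
    if count_boundary:
        n += np.count_nonzero(forest[0, :]) + np.count_nonzero(forest[-1, :])
        n += np.count_nonzero(forest[:, 0]) + np.count_nonzero(forest[:, -1])
    return n * pixel_size


def compute_cell_metrics(window: np.ndarray, pixel_size: float,
                         cell_area: float, connectivity: int = 8,
                         count_boundary: bool = False) -> dict:
    """Compute one metrics row (ED, PD, MPA, FC, counts) for a cell window.

    Cells with no forest get ED = PD = FC = 0 and MPA = NaN, and are flagged
    ``is_forest = False``.
    """
    if cell_area <= 0:
        raise ValueError("cell_area must be positive")
    lab = label_patches(window, connectivity=connectivity, pixel_size=pixel_size)
    e_total = edge_length(window, pixel_size, count_boundary=count_boundary)
    forest_pixels = int(np.count_nonzero(np.asarray(window) == 1))
    if lab.n_patches == 0:
        ed = pd_ = fc = 0.0
        mpa = np.nan
    else:
        ed = e_total / cell_area * 10_000.0
        pd_ = lab.n_patches / cell_area * 10_000.0 * 100.0
        # mean patch area == total patch area / n, computed from the integer
        # pixel count so the identity MPA * n = forest area holds exactly
        mpa = forest_pixels * pixel_size ** 2 / M2_PER_HA / lab.n_patches
        fc = forest_pixels * pixel_size ** 2 / cell_area
    return {"ED": ed, "PD": pd_, "MPA": mpa, "FC": fc,
            "forest_pixels": forest_pixels, "n_patches": lab.n_patches,
            "e_total": e_total, "is_forest": lab.n_patches > 0}


def compute_metrics_grid(fmap: BinaryForestMap, grid: AnalysisGrid,
                         connectivity: int = 8, count_boundary: bool = False,
                         max_nodata_frac: float = 0.5) -> pd.DataFrame:
    """Per-cell metrics table for one epoch of a forest map.

    Cells whose window exceeds ``max_nodata_frac`` of nodata pixels are
    dropped (their densities would not be comparable: A is kept at
    cell_size^2 rather than shrunk per cell).  Cell computations are
    mutually independent, so results do not depend on evaluation order.
    """
    if abs(grid.pixel_size - fmap.pixel_size) > 1e-9:
        raise ValueError("grid was built for a different pixel size")
    rows = []
    A = grid.cell_area
    for cell in grid.cells:
        win = fmap.values[cell.window]
        if cell.partial:
            A_cell = win.size * fmap.pixel_size ** 2
        else:
            A_cell = A
        nodata_frac = np.count_nonzero(win == NODATA) / win.size
        if nodata_frac > max_nodata_frac:
            continue
        row = compute_cell_metrics(win, fmap.pixel_size, A_cell,
                                   connectivity=connectivity,
                                   count_boundary=count_boundary)
        row["cell_id"] = cell.cell_id
        row["epoch"] = fmap.epoch
        rows.append(row)
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)
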