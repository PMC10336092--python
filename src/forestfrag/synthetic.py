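"""Synthetic bi-temporal forest landscapes with known change processes.

Initial maps come from a modified-random-clusters neutral landscape model:
seed pixels are sown at a density set by the autocorrelation parameter and
grown by random neighbour accretion until the forest proportion hits the
target, giving spatially autocorrelated binary maps with a single
"clumpiness" knob.  A second epoch is produced by applying spatial change
operators — the canonical fragmentation/recovery processes — to regions of
the map:

    edge_erosion  shave patch boundaries            (forest loss)
    dissection    cut 1-pixel transects through patches (fragmenting loss)
    perforation   open interior holes               (forest loss)
    attrition     delete the smallest patches       (forest loss)
    infill        fill gaps adjacent to forest      (coalescing gain)
    seeding       add new small patches             (dispersed gain)
    expansion     grow all patch boundaries         (forest gain)

Each operator has a known expected effect on the metric changes
(``OPERATOR_EFFECTS``), so every downstream stage can be validated against
planted truth.  Everything is deterministic under the scenario seed; each
operator application draws from its own named stream derived from
(seed, schedule index), so editing one schedule entry does not perturb the
draws of later entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import ndimage

from .raster import BinaryForestMap
from .metrics import label_patches

OPERATORS = ("edge_erosion", "dissection", "perforation", "attrition",
             "infill", "seeding", "expansion")

#: Expected sign (+1/-1) of each change quantity per operator; only the
#: signs that are reliable consequences of the operator's geometry are
#: asserted.  dFFI signs follow from the metric signs through the index.
OPERATOR_EFFECTS: dict[str, dict[str, int]] = {
    "dissection": {"dED": +1, "dPD": +1, "dMPA": -1, "dFC": -1, "dFFI": +1},
    "infill": {"dED": -1, "dPD": -1, "dMPA": +1, "dFC": +1, "dFFI": -1},
    "edge_erosion": {"dFC": -1},
    "perforation": {"dED": +1, "dFC": -1},
    "attrition": {"dPD": -1, "dFC": -1},
    "seeding": {"dPD": +1, "dFC": +1},
    "expansion": {"dFC": +1},
}


@dataclass
class OperatorStep:
    """One schedule entry: operator name, intensity in [0,1], target region.

    ``region`` is either None (whole map), a (row0, row1, col0, col1)
    half-open rectangle, or a boolean mask array.
    """

    operator: str
    intensity: float
    region: object = None

    def __post_init__(self) -> None:
        if self.operator not in OPERATORS:
            raise ValueError(
                f"unknown operator {self.operator!r}; valid: {OPERATORS}")
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError(f"intensity must be in [0,1], got {self.intensity}")


@dataclass
class ScenarioSpec:
    """Full specification of a two-epoch synthetic scenario."""

    rows: int
    cols: int
    pixel_size: float = 30.0
    forest_proportion: float = 0.5
    autocorrelation: float = 0.7
    operators: list[OperatorStep] = field(default_factory=list)
    seed: int = 0
    epochs: tuple = (2000, 2020)

    def __post_init__(self) -> None:
        if not 0.0 < self.forest_proportion < 1.0:
            raise ValueError("forest_proportion must be in (0,1)")
        if not 0.0 <= self.autocorrelation < 1.0:
            raise ValueError("autocorrelation must be in [0,1)")
        self.operators = [
            op if isinstance(op, OperatorStep) else OperatorStep(**op)
            for op in self.operators]

    @classmethod
    def from_yaml(cls, path: str) -> "ScenarioSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "operators" in d:
            d["operators"] = [
                OperatorStep(op["operator"], op["intensity"],
                             tuple(op["region"]) if op.get("region") else None)
                for op in d["operators"]]
        if "epochs" in d:
            d["epochs"] = tuple(d["epochs"])
        return cls(**d)


def _region_mask(region, shape) -> np.ndarray:
    if region is None:
        return np.ones(shape, dtype=bool)
    if isinstance(region, np.ndarray):
        if region.shape != shape:
            raise ValueError("region mask shape mismatch")
        return region.astype(bool)
    r0, r1, c0, c1 = region
    m = np.zeros(shape, dtype=bool)
    m[r0:r1, c0:c1] = True
    return m


_GROW_STRUCT = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def _neighbour_count(mask: np.ndarray) -> np.ndarray:
    """Number of 4-neighbours of each pixel that are True."""
    n = np.zeros(mask.shape, dtype=np.int8)
    n[1:, :] += mask[:-1, :]
    n[:-1, :] += mask[1:, :]
    n[:, 1:] += mask[:, :-1]
    n[:, :-1] += mask[:, 1:]
    return n


def generate_initial_map(spec: ScenarioSpec) -> BinaryForestMap:
    """Modified-random-clusters map at the requested forest proportion.

    Seeds are sown at density ``~ p * (1 - autocorrelation)^2 / 4`` and grown
    by batched random accretion of 4-neighbour frontier pixels until the
    forest count equals ``round(p * n_pixels)`` exactly, so the realized
    proportion is within one pixel of the request.  Higher autocorrelation
    means fewer seeds, hence fewer and larger patches at equal cover.
    """
    rng = np.random.default_rng([int(spec.seed) % (2**31), 1])
    shape = (spec.rows, spec.cols)
    total = spec.rows * spec.cols
    target = int(round(spec.forest_proportion * total))
    target = max(1, min(target, total - 1))
    n_seeds = max(1, int(round(total * spec.forest_proportion
                               * (1.0 - spec.autocorrelation) ** 2 / 4.0)))
    n_seeds = min(n_seeds, target)
    forest = np.zeros(shape, dtype=bool)
    seeds = rng.choice(total, size=n_seeds, replace=False)
    forest.ravel()[seeds] = True
    count = n_seeds
    max_iter = 4 * (spec.rows + spec.cols) + 1000
    for _ in range(max_iter):
        if count >= target:
            break
        frontier = ndimage.binary_dilation(forest, structure=_GROW_STRUCT) & ~forest
        idx = np.flatnonzero(frontier.ravel())
        if idx.size == 0:  # pragma: no cover - only if map saturates
            raise RuntimeError("cluster growth stalled before reaching target cover")
        need = target - count
        accept = idx[rng.random(idx.size) < 0.6]
        if accept.size > need:
            accept = rng.choice(accept, size=need, replace=False)
        forest.ravel()[accept] = True
        count += accept.size
    else:  # pragma: no cover
        raise RuntimeError("target forest proportion not reached within iteration cap")
    return BinaryForestMap(forest.astype(np.int8), pixel_size=spec.pixel_size,
                           epoch=spec.epochs[0], crs_id="synthetic-equal-area")


def _remove_random(forest: np.ndarray, eligible: np.ndarray, frac: float,
                   rng: np.random.Generator, value: bool) -> None:
    idx = np.flatnonzero(eligible.ravel())
    k = int(round(frac * idx.size))
    if k <= 0 or idx.size == 0:
        return
    chosen = rng.choice(idx, size=min(k, idx.size), replace=False)
    forest.ravel()[chosen] = value


def apply_operator(fmap: BinaryForestMap, operator: str, intensity: float,
                   seed, region=None) -> BinaryForestMap:
    """Apply one spatial change operator and return the modified map.

    ``intensity`` is, for pixel-wise operators, the fraction of eligible
    pixels converted; for attrition the fraction of patches deleted; for
    dissection and seeding it scales the number of cuts/new patches with the
    region size.  Intensity 0 is the identity.  Nothing eligible is a
    silent no-op.
    """
    step = OperatorStep(operator, intensity, region)
    rng = np.random.default_rng(seed)
    forest = fmap.forest_mask.copy()
    mask = _region_mask(step.region, forest.shape)
    if intensity > 0:
        if operator == "edge_erosion":
            edge = forest & mask & (_neighbour_count(~forest & fmap.valid_mask) > 0)
            _remove_random(forest, edge, intensity, rng, False)
        elif operator == "perforation":
            interior = forest & mask & (_neighbour_count(forest) == 4)
            _remove_random(forest, interior, intensity, rng, False)
        elif operator == "dissection":
            _dissect(forest, mask, intensity, rng)
        elif operator == "attrition":
            _attrit(forest, mask, intensity, rng)
        elif operator == "infill":
            # true gap pixels: >= 2 forest 4-neighbours, so each conversion
            # closes more edge than it opens and can merge patches
            gaps = ~forest & mask & fmap.valid_mask & (_neighbour_count(forest) >= 2)
            _remove_random(forest, gaps, intensity, rng, True)
        elif operator == "expansion":
            ring = (ndimage.binary_dilation(forest, structure=np.ones((3, 3), bool))
                    & ~forest & mask & fmap.valid_mask)
            _remove_random(forest, ring, intensity, rng, True)
        elif operator == "seeding":
            _seed_patches(forest, mask & fmap.valid_mask, intensity, rng)
    values = forest.astype(np.int8)
    values[~fmap.valid_mask] = fmap.values[~fmap.valid_mask]
    return fmap.with_values(values)


def _dissect(forest: np.ndarray, mask: np.ndarray, intensity: float,
             rng: np.random.Generator) -> None:
    """Carve 1-pixel straight transects across the region's bounding box."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        return
    r0, r1, c0, c1 = rows[0], rows[-1] + 1, cols[0], cols[-1] + 1
    n_cuts = max(1, int(round(intensity * ((r1 - r0) + (c1 - c0)) / 40.0)))
    for _ in range(n_cuts):
        if rng.random() < 0.5:
            r = rng.integers(r0, r1)
            line = np.zeros_like(forest)
            line[r, c0:c1] = True
        else:
            c = rng.integers(c0, c1)
            line = np.zeros_like(forest)
            line[r0:r1, c] = True
        forest[line & mask] = False


def _attrit(forest: np.ndarray, mask: np.ndarray, intensity: float,
            rng: np.random.Generator) -> None:
    """Delete the smallest patches until a fraction of patches is removed."""
    lab = label_patches((forest & mask).astype(np.int8), connectivity=8)
    if lab.n_patches == 0:
        return
    k = int(np.ceil(intensity * lab.n_patches))
    order = np.argsort(lab.patch_areas, kind="stable")  # smallest first
    doomed = order[:k] + 1
    forest[np.isin(lab.labels, doomed)] = False


def _seed_patches(forest: np.ndarray, mask: np.ndarray, intensity: float,
                  rng: np.random.Generator) -> None:
    """Add small new patches on open ground away from existing forest."""
    open_far = ~forest & mask & (_neighbour_count(forest) == 0)
    idx = np.flatnonzero(open_far.ravel())
    if idx.size == 0:
        return
    region_px = int(mask.sum())
    n_new = max(1, int(round(intensity * region_px / 400.0)))
    centers = rng.choice(idx, size=min(n_new, idx.size), replace=False)
    nrows, ncols = forest.shape
    for flat in centers:
        r, c = divmod(int(flat), ncols)
        size = int(rng.integers(1, 6))
        forest[r, c] = True
        for _ in range(size - 1):
            dr, dc = rng.integers(-1, 2), rng.integers(-1, 2)
            rr, cc = min(max(r + dr, 0), nrows - 1), min(max(c + dc, 0), ncols - 1)
            if mask[rr, cc]:
                forest[rr, cc] = True


def generate_scenario(spec: ScenarioSpec,
                      ) -> tuple[BinaryForestMap, BinaryForestMap, "pd.DataFrame"]:
    """Initial map, second-epoch map, and the planted-truth table.

    The truth table lists, per schedule entry, the operator, its region and
    the expected signs of the metric and index changes from
    ``OPERATOR_EFFECTS``.
    """
    import pandas as pd

    map_t1 = generate_initial_map(spec)
    current = map_t1
    truth_rows = []
    base = int(spec.seed) % (2**31)
    for i, step in enumerate(spec.operators):
        current = apply_operator(current, step.operator, step.intensity,
                                 seed=[base, 1000 + i], region=step.region)
        row = {"schedule_index": i, "operator": step.operator,
               "intensity": step.intensity,
               "region": "full" if step.region is None else str(step.region)}
        row.update({k: OPERATOR_EFFECTS[step.operator].get(k, 0)
                    for k in ("dED", "dPD", "dMPA", "dFC", "dFFI")})
        truth_rows.append(row)
    map_t2 = BinaryForestMap(current.values, pixel_size=spec.pixel_size,
                             origin=map_t1.origin, crs_id=map_t1.crs_id,
                             epoch=spec.epochs[1])
    truth = pd.DataFrame(truth_rows, columns=[
        "schedule_index", "operator", "intensity", "region",
        "dED", "dPD", "dMPA", "dFC", "dFFI"])
    return map_t1, map_t2, truth


def generate_driver_fields(n_cell_rows: int, n_cell_cols: int,
                           coefficients, noise_sd: float = 0.05,
                           seed: int = 0, smooth_sigma: float = 3.0,
                           ) -> tuple["pd.DataFrame", np.ndarray]:
    """Smooth random driver covariates with a planted linear response.

    Seven covariate fields (the driver set: cropland mean/change, nighttime
    light mean/change, population mean/change, fire frequency) are drawn as
    Gaussian-smoothed white noise on the cell grid and min–max rescaled to
    [0, 1]; the response is their linear combination under ``coefficients``
    plus N(0, noise_sd) noise.  Returns the cell table (with cell_id,
    cell_row, cell_col, covariates and ``dFFI`` response) and the planted
    coefficient vector.
    """
    import pandas as pd
    from .drivers import DRIVER_COLUMNS

    beta = np.asarray(coefficients, dtype=float)
    if beta.shape != (len(DRIVER_COLUMNS),):
        raise ValueError(f"expected {len(DRIVER_COLUMNS)} coefficients")
    if np.ndim(seed) == 0:
        entropy = [int(seed) % (2**31)]
    else:
        entropy = [int(s) % (2**31) for s in seed]
    rng = np.random.default_rng(entropy + [7])
    shape = (n_cell_rows, n_cell_cols)
    fields = {}
    for name in DRIVER_COLUMNS:
        f = ndimage.gaussian_filter(rng.standard_normal(shape), smooth_sigma)
        f = (f - f.min()) / (f.max() - f.min())
        fields[name] = f.ravel()
    X = np.column_stack([fields[name] for name in DRIVER_COLUMNS])
    y = X @ beta + rng.normal(0.0, noise_sd, size=X.shape[0])
    rr, cc = np.divmod(np.arange(X.shape[0]), n_cell_cols)
    table = pd.DataFrame(fields)
    table.insert(0, "cell_id", np.arange(X.shape[0]))
    table["cell_row"] = rr
    table["cell_col"] = cc
    table["dFFI"] = y
    return table, beta
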