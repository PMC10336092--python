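"""The composite Forest Fragmentation Index (FFI) and its change.

The three cell metrics are min–max normalized with bounds fitted on the two
epochs *pooled*, so normalized values — and hence FFI — are directly
comparable between years.  The static index is a weighted mean

    FFI = w_ED * ED_nor + w_PD * PD_nor + w_MPA * (1 - MPA_nor)

with equal default weights; MPA enters inverted because larger mean patch
area means *less* fragmentation.  FFI lies in [0, 1]: 0 is a fully intact
landscape, 1 a maximally fragmented one.  The dynamic index is the change

    dFFI = FFI(epoch 2) - FFI(epoch 1)   in [-1, 1]

computed only for cells forested in both epochs; negative dFFI means
defragmentation.  dFC is the forest-coverage change on the same cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

NORMALIZED_METRICS = ("ED", "PD", "MPA")
DEFAULT_WEIGHTS = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)


@dataclass
class NormalizationParams:
    """Per-metric (lower, upper) bounds plus the percentiles that made them."""

    bounds: dict[str, tuple[float, float]]
    clip_percentiles: tuple[float, float] = (0.0, 100.0)
    pooled_epochs: bool = True

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "NormalizationParams":
        with open(path) as fh:
            d = json.load(fh)
        d["bounds"] = {k: tuple(v) for k, v in d["bounds"].items()}
        d["clip_percentiles"] = tuple(d["clip_percentiles"])
        return cls(**d)


def fit_normalization(metrics: pd.DataFrame,
                      clip_percentiles: tuple[float, float] = (0.0, 100.0),
                      ) -> NormalizationParams:
    """Fit per-metric normalization bounds on pooled two-epoch data.

    Bounds are the (low, high) percentiles of each metric over forest-flagged
    cells of *both* epochs jointly; the default (0, 100) is plain min–max.
    A clip such as (0.5, 99.5) trades a little saturation for robustness to
    outliers.  Identical bounds are then applied to both epochs, which is
    what makes FFI values comparable across years.
    """
    lo_p, hi_p = clip_percentiles
    if not (0 <= lo_p < hi_p <= 100):
        raise ValueError("clip_percentiles must satisfy 0 <= low < high <= 100")
    forest = metrics[metrics["is_forest"].astype(bool)]
    if len(forest) < 2:
        raise ValueError("need at least 2 forest-flagged cells to fit normalization")
    bounds: dict[str, tuple[float, float]] = {}
    for m in NORMALIZED_METRICS:
        vals = forest[m].dropna().to_numpy(dtype=float)
        lo, hi = np.percentile(vals, [lo_p, hi_p])
        if not hi > lo:
            raise ValueError(f"degenerate bounds for metric {m!r}: all values equal")
        bounds[m] = (float(lo), float(hi))
    return NormalizationParams(bounds=bounds, clip_percentiles=(lo_p, hi_p))


def normalize_metrics(metrics: pd.DataFrame,
                      params: NormalizationParams) -> pd.DataFrame:
    """Append clamped min–max columns ED_nor, PD_nor, MPA_nor in [0, 1]."""
    out = metrics.copy()
    for m in NORMALIZED_METRICS:
        lo, hi = params.bounds[m]
        out[m + "_nor"] = np.clip((out[m] - lo) / (hi - lo), 0.0, 1.0)
    return out


def _check_weights(weights) -> tuple[float, float, float]:
    w = tuple(float(x) for x in weights)
    if len(w) != 3 or any(x < 0 for x in w):
        raise ValueError("weights must be three non-negative numbers")
    if abs(sum(w) - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {sum(w)!r}")
    return w


def compose_ffi(normalized: pd.DataFrame,
                weights=DEFAULT_WEIGHTS) -> pd.Series:
    """Weighted mean of ED_nor, PD_nor and inverted MPA_nor.

    Non-forest cells (missing MPA) yield NaN.
    """
    w_ed, w_pd, w_mpa = _check_weights(weights)
    return (w_ed * normalized["ED_nor"] + w_pd * normalized["PD_nor"]
            + w_mpa * (1.0 - normalized["MPA_nor"]))


def compute_delta(ffi_1: pd.Series, ffi_2: pd.Series,
                  fc_1: pd.Series, fc_2: pd.Series) -> pd.DataFrame:
    """dFFI and dFC on the cell intersection of two epochs.

    Cells missing (NaN) in either epoch are excluded.
    """
    df = pd.DataFrame({"FFI_1": ffi_1, "FFI_2": ffi_2, "FC_1": fc_1, "FC_2": fc_2})
    df = df.dropna(subset=["FFI_1", "FFI_2"])
    df["dFFI"] = df["FFI_2"] - df["FFI_1"]
    df["dFC"] = df["FC_2"] - df["FC_1"]
    return df


def compute_ffi_layers(metrics: pd.DataFrame,
                       params: NormalizationParams | None = None,
                       weights=DEFAULT_WEIGHTS,
                       clip_percentiles: tuple[float, float] = (0.0, 100.0),
                       ) -> tuple[pd.DataFrame, NormalizationParams]:
    """Full static+dynamic index table from a two-epoch metrics table.

    Returns one row per cell with per-epoch normalized metrics, FFI and FC
    (wide columns suffixed by epoch), and dFFI/dFC on the intersection of
    cells forested in both epochs.
    """
    epochs = sorted(metrics["epoch"].unique(), key=str)
    if len(epochs) != 2:
        raise ValueError(f"expected exactly 2 epochs, found {epochs}")
    if params is None:
        params = fit_normalization(metrics, clip_percentiles)
    norm = normalize_metrics(metrics, params)
    norm["FFI"] = compose_ffi(norm, weights)
    norm.loc[~norm["is_forest"].astype(bool), "FFI"] = np.nan

    e1, e2 = epochs
    piv = norm.set_index(["cell_id", "epoch"])[
        ["ED_nor", "PD_nor", "MPA_nor", "FFI", "FC"]].unstack("epoch")
    piv.columns = [f"{c}_{e}" for c, e in piv.columns]
    piv["dFFI"] = piv[f"FFI_{e2}"] - piv[f"FFI_{e1}"]
    piv["dFC"] = piv[f"FC_{e2}"] - piv[f"FC_{e1}"]
    # the dynamic indexes only exist where both epochs are forested
    both = piv[f"FFI_{e1}"].notna() & piv[f"FFI_{e2}"].notna()
    piv.loc[~both, ["dFFI", "dFC"]] = np.nan
    piv.attrs["epochs"] = (e1, e2)
    return piv.reset_index(), params
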