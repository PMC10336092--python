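"""Categorical classification of fragmentation change, and summaries.

Two classifiers operate on per-cell changes between the epochs:

* the **fragmentation-process mode** — one of the 8 sign combinations of
  (dED, dPD, dMPA), e.g. ``ED_up PD_up MPA_down`` (classic fragmentation by
  dissection) or ``ED_down PD_down MPA_up`` (coalescence/defragmentation);
* the **landscape-dynamic pattern** — one of the 4 sign combinations of
  (dFC, dFFI), read as successional stages: gaining cover while
  defragmenting is deep recovery, losing cover while fragmenting is deep
  degradation, and the two mixed quadrants are the early stages.

"up" means strictly positive change; an exact zero is classified "down" so
the classifiers stay total and exhaustive over the 8/4 categories (exact
zeros have measure zero on continuous data; ``drop_zeros`` excludes them
instead if preferred).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _updown(x) -> np.ndarray:
    return np.asarray(x) > 0


def _mode_label(ed_up: bool, pd_up: bool, mpa_up: bool) -> str:
    return (f"ED_{'up' if ed_up else 'down'} "
            f"PD_{'up' if pd_up else 'down'} "
            f"MPA_{'up' if mpa_up else 'down'}")


#: code -> label for the 8 fragmentation-process modes; the code packs the
#: sign triple as bits (ED, PD, MPA), up = 1.
MODE_LABELS: dict[int, str] = {
    (e << 2) | (p << 1) | m: _mode_label(bool(e), bool(p), bool(m))
    for e in (0, 1) for p in (0, 1) for m in (0, 1)
}

#: code -> (label, stage) for the 4 landscape-dynamic patterns; the code
#: packs (FC, FFI) signs as bits, up = 1.
PATTERN_LABELS: dict[int, tuple[str, str]] = {
    (1 << 1) | 0: ("FC_up FFI_down", "deep recovery"),
    (1 << 1) | 1: ("FC_up FFI_up", "early recovery"),
    (0 << 1) | 0: ("FC_down FFI_down", "early degradation"),
    (0 << 1) | 1: ("FC_down FFI_up", "deep degradation"),
}


def classify_mode(d_ed, d_pd, d_mpa) -> np.ndarray:
    """Mode codes (0-7) from the sign triple of metric changes.

    Inputs may be scalars or aligned arrays; non-finite entries (e.g. MPA
    undefined in one epoch) yield code -1 (unclassified).
    """
    d_ed = np.atleast_1d(np.asarray(d_ed, dtype=float))
    d_pd = np.atleast_1d(np.asarray(d_pd, dtype=float))
    d_mpa = np.atleast_1d(np.asarray(d_mpa, dtype=float))
    code = ((_updown(d_ed).astype(int) << 2)
            | (_updown(d_pd).astype(int) << 1)
            | _updown(d_mpa).astype(int))
    finite = np.isfinite(d_ed) & np.isfinite(d_pd) & np.isfinite(d_mpa)
    return np.where(finite, code, -1)


def classify_pattern(d_fc, d_ffi) -> np.ndarray:
    """Pattern codes (0-3) from the sign pair (dFC, dFFI); -1 if non-finite."""
    d_fc = np.atleast_1d(np.asarray(d_fc, dtype=float))
    d_ffi = np.atleast_1d(np.asarray(d_ffi, dtype=float))
    code = (_updown(d_fc).astype(int) << 1) | _updown(d_ffi).astype(int)
    finite = np.isfinite(d_fc) & np.isfinite(d_ffi)
    return np.where(finite, code, -1)


def mode_label(code: int) -> str:
    return MODE_LABELS.get(int(code), "unclassified")


def pattern_label(code: int) -> str:
    return PATTERN_LABELS.get(int(code), ("unclassified", "unclassified"))[0]


def pattern_stage(code: int) -> str:
    return PATTERN_LABELS.get(int(code), ("unclassified", "unclassified"))[1]


def classify_cells(layers: pd.DataFrame, metrics: pd.DataFrame,
                   stable_eps: float = 0.005) -> pd.DataFrame:
    """Classify every cell of an FFI layer table.

    ``layers`` is the wide per-cell table from :func:`forestfrag.ffi.
    compute_ffi_layers`; ``metrics`` the long two-epoch metrics table (for
    the raw-metric deltas).  Adds mode and pattern codes/labels plus a
    descriptive ``stable`` flag for \\|dFFI\\| < ``stable_eps`` (no extra
    class is created for it).
    """
    epochs = sorted(metrics["epoch"].unique(), key=str)
    e1, e2 = epochs
    raw = metrics.set_index(["cell_id", "epoch"])[["ED", "PD", "MPA"]].unstack("epoch")
    d_ed = raw[("ED", e2)] - raw[("ED", e1)]
    d_pd = raw[("PD", e2)] - raw[("PD", e1)]
    d_mpa = raw[("MPA", e2)] - raw[("MPA", e1)]
    out = layers.set_index("cell_id").copy()
    out["dED"] = d_ed
    out["dPD"] = d_pd
    out["dMPA"] = d_mpa
    out["mode_code"] = classify_mode(out["dED"], out["dPD"], out["dMPA"])
    out.loc[out["dFFI"].isna(), "mode_code"] = -1
    out["pattern_code"] = classify_pattern(out["dFC"], out["dFFI"])
    out["mode"] = out["mode_code"].map(mode_label)
    out["pattern"] = out["pattern_code"].map(pattern_label)
    out["stage"] = out["pattern_code"].map(pattern_stage)
    out["stable"] = out["dFFI"].abs() < stable_eps
    return out.reset_index()


def mode_composition(classified: pd.DataFrame,
                     cell_area: float = 1.0) -> pd.DataFrame:
    """Area share of each mode within the dFFI<0 and dFFI>0 strata.

    Mirrors the composition-proportion analysis: defragmenting and
    fragmenting landscapes are stratified by the sign of dFFI and the area
    fraction of each process mode is reported within each stratum (fractions
    sum to 1 per non-empty stratum).
    """
    rows = []
    for stratum, sel in (("dFFI<0", classified["dFFI"] < 0),
                         ("dFFI>0", classified["dFFI"] > 0)):
        sub = classified[sel & (classified["mode_code"] >= 0)]
        if sub.empty:
            continue
        counts = sub.groupby("mode_code").size()
        for code, n in counts.items():
            rows.append({"stratum": stratum, "mode_code": int(code),
                         "mode": mode_label(code), "n_cells": int(n),
                         "area": n * cell_area,
                         "area_fraction": n / len(sub)})
    return pd.DataFrame(rows, columns=["stratum", "mode_code", "mode",
                                       "n_cells", "area", "area_fraction"])


def zonal_summary(classified: pd.DataFrame, zones: dict[int, int] | pd.Series,
                  cell_area: float = 1.0,
                  zone_labels: dict[int, str] | None = None) -> pd.DataFrame:
    """Per-zone statistics of FFI, dFFI, dFC and pattern composition.

    ``zones`` maps cell_id -> integer zone code (cells without a zone are
    dropped).  One row per zone: cell count, mean/sd of dFFI, mean dFC,
    mean/sd of per-epoch FFI, and the area percentage of each of the four
    landscape-dynamic patterns (summing to 100% over classified cells).
    The (mean dFC, mean dFFI) columns support the country-level
    defragmentation-vs-regrowth correlation.
    """
    zser = pd.Series(zones, name="zone")
    df = classified.merge(zser.rename_axis("cell_id").reset_index(), on="cell_id")
    ffi_cols = [c for c in df.columns if c.startswith("FFI_")]
    rows = []
    for zone, sub in df.groupby("zone"):
        row: dict = {"zone": int(zone), "n_cells": len(sub),
                     "area": len(sub) * cell_area}
        if zone_labels:
            row["zone_label"] = zone_labels.get(int(zone), str(zone))
        for c in ffi_cols:
            row[f"mean_{c}"] = sub[c].mean()
            row[f"sd_{c}"] = sub[c].std()
        row["mean_dFFI"] = sub["dFFI"].mean()
        row["sd_dFFI"] = sub["dFFI"].std()
        row["mean_dFC"] = sub["dFC"].mean()
        classified_sub = sub[sub["pattern_code"] >= 0]
        n_cl = len(classified_sub)
        for code, (label, _stage) in PATTERN_LABELS.items():
            n = int((classified_sub["pattern_code"] == code).sum())
            row[f"pct {label}"] = 100.0 * n / n_cl if n_cl else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def hotspot_summary(metrics: pd.DataFrame, cell_ids) -> pd.DataFrame:
    """Per-metric change report over a hotspot selection of cells.

    For each of ED, PD, MPA, FC: mean, median and quartiles per epoch, and
    the percent change of the mean, (mean_2 - mean_1)/mean_1 * 100 — the
    convention used to report, e.g., a +73% MPA increase in a
    defragmentation hotspot.
    """
    cell_ids = list(cell_ids)
    if not cell_ids:
        raise ValueError("empty hotspot selection")
    sub = metrics[metrics["cell_id"].isin(cell_ids)]
    epochs = sorted(sub["epoch"].unique(), key=str)
    if len(epochs) != 2:
        raise ValueError("hotspot summary needs both epochs present")
    e1, e2 = epochs
    rows = []
    for m in ("ED", "PD", "MPA", "FC"):
        row: dict = {"metric": m}
        for e in (e1, e2):
            vals = sub.loc[sub["epoch"] == e, m].dropna()
            row[f"mean_{e}"] = vals.mean()
            row[f"median_{e}"] = vals.median()
            row[f"q25_{e}"] = vals.quantile(0.25)
            row[f"q75_{e}"] = vals.quantile(0.75)
        m1, m2 = row[f"mean_{e1}"], row[f"mean_{e2}"]
        row["pct_change_mean"] = (m2 - m1) / m1 * 100.0 if m1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
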