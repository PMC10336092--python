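"""End-to-end orchestration: from a pair of forest maps to all output layers.

The pipeline sequences the stages — gridding, per-cell metrics, index
construction, change classification, summaries, optional driver fits — and
writes every artifact (CSV tables, AAIGrid layers, JSON sidecars) to an
output directory together with a manifest of SHA-256 content hashes.
Reruns with identical inputs and configuration reproduce the hashes
bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import classify, drivers, ffi, metrics, raster, synthetic


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    forest_epoch1: str = ""
    forest_epoch2: str = ""
    epoch1: object = 2000
    epoch2: object = 2020
    zones: str | None = None
    drivers_table: str | None = None
    cell_size: float = 5000.0
    connectivity: int = 8
    count_boundary: bool = False
    max_nodata_frac: float = 0.5
    clip_percentiles: tuple[float, float] = (0.0, 100.0)
    weights: tuple[float, float, float] = ffi.DEFAULT_WEIGHTS
    stable_eps: float = 0.005
    coarse_size: float | None = None
    n_min: int = 30
    output_dir: str = "forestfrag_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        lo, hi = self.clip_percentiles
        if not 0 <= lo < hi <= 100:
            raise ValueError("clip_percentiles must satisfy 0 <= low < high <= 100")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if not 0 <= self.max_nodata_frac <= 1:
            raise ValueError("max_nodata_frac must be in [0,1]")
        if self.coarse_size is not None and self.cell_size > 0:
            ratio = self.coarse_size / self.cell_size
            if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
                raise ValueError("coarse_size must be an integer multiple of cell_size")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("clip_percentiles", "weights"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _cell_layer(values: pd.Series, cell_ids: pd.Series,
                grid: raster.AnalysisGrid) -> np.ndarray:
    arr = np.full((grid.n_cell_rows, grid.n_cell_cols), np.nan)
    rows, cols = np.divmod(cell_ids.to_numpy(dtype=int), grid.n_cell_cols)
    arr[rows, cols] = values.to_numpy(dtype=float)
    return arr


def run_full_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the output manifest (also written to disk)."""
    os.makedirs(config.output_dir, exist_ok=True)
    out = lambda name: os.path.join(config.output_dir, name)  # noqa: E731

    map1 = raster.read_forest_map(config.forest_epoch1, epoch=config.epoch1)
    map2 = raster.read_forest_map(config.forest_epoch2, epoch=config.epoch2)
    ok, report = raster.check_coregistration(map1, map2)
    if not ok:
        raise ValueError(f"input maps are not co-registered: {report}")
    grid = raster.build_grid(map1, config.cell_size)

    mtab = pd.concat([
        metrics.compute_metrics_grid(m, grid, connectivity=config.connectivity,
                                     count_boundary=config.count_boundary,
                                     max_nodata_frac=config.max_nodata_frac)
        for m in (map1, map2)], ignore_index=True)
    mtab.to_csv(out("metrics.csv"), index=False)

    layers, params = ffi.compute_ffi_layers(
        mtab, weights=config.weights, clip_percentiles=config.clip_percentiles)
    params.to_json(out("normalization.json"))
    classified = classify.classify_cells(layers, mtab, stable_eps=config.stable_eps)
    classified.to_csv(out("ffi_layers.csv"), index=False)

    e1, e2 = config.epoch1, config.epoch2
    for col in (f"FFI_{e1}", f"FFI_{e2}", "dFFI", "dFC",
                "mode_code", "pattern_code"):
        arr = _cell_layer(classified[col], classified["cell_id"], grid)
        raster.write_ascii_grid(out(f"{col}.asc"), arr, config.cell_size,
                                origin=map1.origin)
    with open(out("class_labels.json"), "w") as fh:
        json.dump({"modes": classify.MODE_LABELS,
                   "patterns": {k: v[0] for k, v in classify.PATTERN_LABELS.items()},
                   "stages": {k: v[1] for k, v in classify.PATTERN_LABELS.items()}},
                  fh, indent=2)

    comp = classify.mode_composition(classified, cell_area=grid.cell_area)
    comp.to_csv(out("mode_composition.csv"), index=False)

    if config.zones:
        zpix = raster.read_zone_map(config.zones)
        zmap = raster.zones_per_cell(zpix, grid)
        zsum = classify.zonal_summary(classified, zmap, cell_area=grid.cell_area)
        zsum.to_csv(out("zonal_summary.csv"), index=False)

    if config.drivers_table:
        dtab = pd.read_csv(config.drivers_table)
        merged = dtab.merge(classified[["cell_id", "dFFI"]], on="cell_id",
                            how="inner", suffixes=("_drv", ""))
        covs = [c for c in drivers.DRIVER_COLUMNS if c in merged.columns]
        fit_rows = merged[covs + ["dFFI"]].dropna()
        std = drivers.standardize_01(fit_rows, columns=covs + ["dFFI"])
        res = drivers.fit_standardized_lm(std, covariates=covs)
        res.table.to_csv(out("driver_coefficients.csv"))
        res.to_json(out("driver_fit.json"))
        if config.coarse_size:
            rows, cols = np.divmod(merged["cell_id"].to_numpy(dtype=int),
                                   grid.n_cell_cols)
            dmap, labels = drivers.major_driver_map(
                merged, pd.Series(rows), pd.Series(cols), config.cell_size,
                config.coarse_size, n_min=config.n_min, covariates=covs)
            raster.write_ascii_grid(out("major_driver.asc"), dmap.astype(float),
                                    config.coarse_size, origin=map1.origin,
                                    fmt="%d")
            with open(out("major_driver_labels.json"), "w") as fh:
                json.dump(dict(enumerate(labels)), fh, indent=2)

    with open(out("config.yaml"), "w") as fh:
        yaml.safe_dump(asdict(config), fh)
    artifacts = sorted(f for f in os.listdir(config.output_dir)
                       if f != "manifest.json")
    manifest = {"artifacts": {f: _sha256(out(f)) for f in artifacts}}
    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def run_simulate(spec_path: str, output_dir: str) -> list[str]:
    """Generate a scenario from a YAML spec and write its map pair + truth."""
    spec = synthetic.ScenarioSpec.from_yaml(spec_path)
    os.makedirs(output_dir, exist_ok=True)
    m1, m2, truth = synthetic.generate_scenario(spec)
    files = []
    for m, tag in ((m1, spec.epochs[0]), (m2, spec.epochs[1])):
        path = os.path.join(output_dir, f"forest_{tag}.asc")
        raster.write_forest_map(path, m)
        files.append(path)
    tpath = os.path.join(output_dir, "truth.csv")
    truth.to_csv(tpath, index=False)
    files.append(tpath)
    return files
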