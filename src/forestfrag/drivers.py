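"""Driver attribution of fragmentation change by standardized linear models.

dFFI per cell is regressed on seven covariates — mean cropland coverage and
its change, mean nighttime light and its change, mean population density and
its change, and fire frequency — after rescaling every variable to [0, 1],
so the coefficient magnitudes are comparable across drivers.  The "general
linear model" here is ordinary least squares with an intercept (Gaussian
GLM, identity link); confidence intervals follow the +/- 1.645 SE (90%) and
+/- 1.960 SE (95%) convention.  A coarse-grid major-driver map labels each
coarse cell with the covariate of largest absolute coefficient in a local
fit over its member cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

DRIVER_COLUMNS = [
    "cropland_mean", "cropland_change",
    "light_mean", "light_change",
    "pop_mean", "pop_change",
    "fire_freq",
]

RESPONSE_COLUMN = "dFFI"


@dataclass
class RegressionResult:
    """Standardized-coefficient fit of dFFI on the driver covariates."""

    table: pd.DataFrame  # index: covariate; columns: coef, se, t, p, CI bounds
    n: int
    r_squared: float
    intercept: float

    @property
    def coefs(self) -> pd.Series:
        return self.table["coef"]

    def major_driver(self) -> str:
        """Covariate with the largest absolute standardized coefficient."""
        return self.table["coef"].abs().idxmax()

    def to_json(self, path: str) -> None:
        out = {"n": self.n, "r_squared": self.r_squared,
               "intercept": self.intercept,
               "coefficients": self.table.round(10).to_dict(orient="index")}
        pd.Series(out).to_json(path)


def standardize_01(table: pd.DataFrame,
                   columns: list[str] | None = None) -> pd.DataFrame:
    """Min–max rescale each column to [0, 1] over the given rows.

    Applied after dropping incomplete rows, so the bounds come from exactly
    the rows that will be fitted.
    """
    out = table.copy()
    for col in columns if columns is not None else table.columns:
        x = out[col].to_numpy(dtype=float)
        lo, hi = np.nanmin(x), np.nanmax(x)
        if not hi > lo:
            raise ValueError(f"column {col!r} is constant; cannot standardize")
        out[col] = (x - lo) / (hi - lo)
    return out


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    # flag near-duplicate pairs for the error message
    c = np.corrcoef(X, rowvar=False)
    bad = set()
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if abs(c[i, j]) > 1 - 1e-10:
                bad.update((names[i], names[j]))
    return sorted(bad)


def fit_standardized_lm(table: pd.DataFrame,
                        covariates: list[str] | None = None,
                        response: str = RESPONSE_COLUMN) -> RegressionResult:
    """OLS of the response on the covariates, with an intercept.

    Expects variables already on the [0, 1] scale (see
    :func:`standardize_01`); rows with any missing value are dropped.
    Standard errors are classical; 90%/95% CIs are +/- 1.645/1.960 SE.
    """
    covariates = list(covariates) if covariates is not None else [
        c for c in DRIVER_COLUMNS if c in table.columns]
    cols = covariates + [response]
    df = table[cols].dropna()
    n, k = len(df), len(covariates)
    if n <= k + 1:
        raise ValueError(f"need n > {k + 1} complete rows, have {n}")
    X = df[covariates].to_numpy(dtype=float)
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) < k + 1:
        bad = _collinear_columns(X, covariates)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    model = sm.OLS(df[response].to_numpy(dtype=float), sm.add_constant(X))
    res = model.fit()
    coef = res.params[1:]
    se = res.bse[1:]
    tab = pd.DataFrame({
        "coef": coef, "se": se, "t": res.tvalues[1:], "p": res.pvalues[1:],
        "ci90_lo": coef - 1.645 * se, "ci90_hi": coef + 1.645 * se,
        "ci95_lo": coef - 1.960 * se, "ci95_hi": coef + 1.960 * se,
    }, index=pd.Index(covariates, name="covariate"))
    return RegressionResult(table=tab, n=n, r_squared=float(res.rsquared),
                            intercept=float(res.params[0]))


def major_driver_map(table: pd.DataFrame, cell_rows: pd.Series,
                     cell_cols: pd.Series, cell_size: float,
                     coarse_size: float, n_min: int = 30,
                     covariates: list[str] | None = None,
                     response: str = RESPONSE_COLUMN,
                     ) -> tuple[np.ndarray, list[str]]:
    """Coarse-grid categorical map of the locally dominant driver.

    The analysis cells are grouped into coarse blocks of
    ``coarse_size x coarse_size`` (a multiple of ``cell_size``); within each
    block with at least ``n_min`` complete rows a standardized fit is run
    and the index of the covariate with the largest \\|coefficient\\| is
    emitted.  Blocks below ``n_min`` or with a failed fit get -1 (nodata).

    Returns the integer block raster and the covariate label list (the code
    of covariate *i* is *i*).
    """
    ratio = coarse_size / cell_size
    f = int(round(ratio))
    if f < 1 or abs(ratio - f) > 1e-9:
        raise ValueError("coarse_size must be a positive integer multiple of cell_size")
    covariates = list(covariates) if covariates is not None else [
        c for c in DRIVER_COLUMNS if c in table.columns]
    df = table.copy()
    df["_block_r"] = (np.asarray(cell_rows) // f).astype(int)
    df["_block_c"] = (np.asarray(cell_cols) // f).astype(int)
    n_br = df["_block_r"].max() + 1
    n_bc = df["_block_c"].max() + 1
    out = np.full((n_br, n_bc), -1, dtype=int)
    for (br, bc), sub in df.groupby(["_block_r", "_block_c"]):
        sub = sub[covariates + [response]].dropna()
        if len(sub) < n_min:
            continue
        try:
            res = fit_standardized_lm(sub, covariates=covariates, response=response)
        except (ValueError, np.linalg.LinAlgError):
            continue
        out[br, bc] = covariates.index(res.major_driver())
    return out, covariates
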