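"""Chronology vs gridded ocean fields and annual index series.

Monthly gridded fields (EN4-style: time x depth x lat x lon on a 1-degree
grid) are reduced to annual series per grid cell by seasonal averaging
(winter = DJF with December taken from the prior calendar year and the mean
assigned to the January year) and thickness-weighted depth averaging over a
stated depth range. Each cell's annual series is then correlated with the
chronology over a stated period, giving per-cell Pearson r and the
two-sided regression p-value; because ocean series are strongly
autocorrelated, candidate cells are re-tested with the Ebisuzaki surrogate
(EMC) approach. Multiple predictors are combined with ordinary least
squares, reported with the adjusted R-squared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .chronology import Chronology
from .spectral import SurrogateSpec, emc_correlation_test

__all__ = [
    "SeasonSpec",
    "SEASONS",
    "open_field",
    "seasonal_mean",
    "point_correlation_map",
    "emc_cell_test",
    "multiple_regression",
    "RegressionResult",
]


@dataclass(frozen=True)
class SeasonSpec:
    """A named month set plus an optional depth range in metres.

    If the month set crosses the year boundary (contains both December and
    January), December is taken from the *prior* calendar year and the mean
    is assigned to the January year. ``depth_range=(z, z)`` selects the
    single nearest depth level; a proper range is averaged with
    layer-thickness weights.
    """

    months: tuple[int, ...]
    depth_range: tuple[float, float] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if not self.months:
            raise ValueError("month set must be non-empty")
        if any(m < 1 or m > 12 for m in self.months):
            raise ValueError("months must be in 1..12")
        if self.depth_range is not None and self.depth_range[0] > self.depth_range[1]:
            raise ValueError("depth_range must satisfy z1 <= z2")

    @property
    def crosses_year(self) -> bool:
        return 12 in self.months and 1 in self.months


SEASONS: dict[str, tuple[int, ...]] = {
    "DJF": (12, 1, 2),
    "MAM": (3, 4, 5),
    "JJA": (6, 7, 8),
    "SON": (9, 10, 11),
    "JA": (7, 8),
    "annual": tuple(range(1, 13)),
}


def open_field(path, variable: str) -> xr.DataArray:
    """Open one variable of a CF-style NetCDF field (scipy/NETCDF3 backend)."""
    ds = xr.open_dataset(path, engine="scipy")
    return ds[variable]


def _depth_weights(levels: np.ndarray, z1: float, z2: float) -> np.ndarray:
    """Thickness of each layer's overlap with [z1, z2]; layer bounds are the
    midpoints between adjacent level centres (first bound at 0)."""
    levels = np.asarray(levels, dtype=float)
    mids = 0.5 * (levels[1:] + levels[:-1])
    upper = np.concatenate([[0.0], mids])
    lower = np.concatenate([mids, [levels[-1] + (levels[-1] - upper[-1])]])
    w = np.maximum(
        0.0, np.minimum(lower, z2) - np.maximum(upper, z1)
    )
    return w


def seasonal_mean(field: xr.DataArray, spec: SeasonSpec) -> xr.DataArray:
    """Annual per-cell series: mean over the season's months (year-boundary
    aware) and thickness-weighted over the depth range.

    Years missing any season month are dropped.
    """
    da = field
    if "depth" in da.dims:
        if spec.depth_range is None:
            raise ValueError("field has a depth dimension; give a depth_range")
        z1, z2 = spec.depth_range
        levels = da["depth"].to_numpy()
        if z1 == z2:
            nearest = levels[np.argmin(np.abs(levels - z1))]
            da = da.sel(depth=nearest)
        else:
            w = _depth_weights(levels, z1, z2)
            if w.sum() == 0:
                raise ValueError(
                    f"no depth levels intersect [{z1}, {z2}] m; available "
                    f"levels: {np.round(levels, 1).tolist()}"
                )
            weights = xr.DataArray(w, coords={"depth": da["depth"]}, dims="depth")
            da = da.weighted(weights).mean("depth")
    elif spec.depth_range is not None and spec.depth_range[0] != spec.depth_range[1]:
        pass  # surface-only field; depth range ignored

    time = pd.DatetimeIndex(da["time"].to_numpy())
    month = time.month
    year = time.year.to_numpy().copy()
    if spec.crosses_year:
        year[month == 12] += 1  # December counts toward the January year
    sel = np.isin(month, spec.months)
    da = da.isel(time=np.flatnonzero(sel))
    da = da.assign_coords(season_year=("time", year[sel]))

    grouped = da.groupby("season_year")
    mean = grouped.mean("time")
    count = grouped.count("time")
    complete = count >= len(spec.months)
    mean = mean.where(complete)
    # drop years incomplete everywhere
    other = [d for d in mean.dims if d != "season_year"]
    any_ok = complete.any(other) if other else complete
    mean = mean.sel(season_year=any_ok)
    return mean.rename(season_year="year")


def _chron_series(chron) -> pd.Series:
    if isinstance(chron, Chronology):
        return chron.index
    if isinstance(chron, pd.Series):
        return chron
    raise TypeError("chron must be a Chronology or pandas Series")


def point_correlation_map(
    chron,
    annual_field: xr.DataArray,
    period: tuple[int, int] | None = None,
    min_overlap: int = 10,
) -> xr.Dataset:
    """Per-cell Pearson correlation of the chronology with an annual field.

    Returns an ``xr.Dataset`` with variables ``r``, ``p`` (two-sided
    regression p-value) and ``n`` (joint years); cells with fewer than
    ``min_overlap`` joint years are missing.
    """
    cs = _chron_series(chron).dropna()
    if period is not None:
        cs = cs.loc[(cs.index >= period[0]) & (cs.index <= period[1])]
        annual_field = annual_field.sel(
            year=(annual_field["year"] >= period[0])
            & (annual_field["year"] <= period[1])
        )
    common = np.intersect1d(cs.index.to_numpy(), annual_field["year"].to_numpy())
    if common.size == 0:
        raise ValueError("no joint years between chronology and field")
    x = cs.loc[common].to_numpy(dtype=float)
    fld = annual_field.sel(year=common)

    other_dims = [d for d in fld.dims if d != "year"]
    stacked = fld.transpose("year", *other_dims).to_numpy()
    shape = stacked.shape[1:]
    flat = stacked.reshape(stacked.shape[0], -1)

    valid = np.isfinite(flat)
    xcol = x[:, None]
    xmask = np.where(valid, xcol, np.nan)
    n = valid.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        xm = np.nanmean(xmask, axis=0)
        ym = np.nanmean(flat, axis=0)
        xd = np.where(valid, xcol - xm, 0.0)
        yd = np.where(valid, flat - ym, 0.0)
        r = (xd * yd).sum(axis=0) / np.sqrt(
            (xd**2).sum(axis=0) * (yd**2).sum(axis=0)
        )
        t = r * np.sqrt(np.maximum(n - 2, 0) / np.maximum(1 - r**2, 1e-300))
        p = 2.0 * stats.t.sf(np.abs(t), df=np.maximum(n - 2, 1))
    bad = n < min_overlap
    r[bad] = np.nan
    p[bad] = np.nan
    if np.all(bad):
        raise ValueError("no cells with sufficient joint coverage")

    coords = {d: fld[d] for d in other_dims}
    return xr.Dataset(
        {
            "r": (other_dims, r.reshape(shape)),
            "p": (other_dims, p.reshape(shape)),
            "n": (other_dims, n.reshape(shape)),
        },
        coords=coords,
    )


def emc_cell_test(
    chron,
    cell_series: pd.Series,
    spec: SurrogateSpec = SurrogateSpec(),
) -> tuple[float, float]:
    """Ebisuzaki surrogate re-test of one grid cell's correlation with the
    chronology (see :func:`scleropipe.spectral.emc_correlation_test`)."""
    return emc_correlation_test(_chron_series(chron), cell_series, spec)


@dataclass
class RegressionResult:
    params: pd.Series
    r_squared: float
    adj_r_squared: float
    f_pvalue: float
    nobs: int
    vif: pd.Series | None = None
    condition_number: float = np.nan


def multiple_regression(
    response,
    predictors: dict[str, pd.Series],
    cond_threshold: float = 1000.0,
) -> RegressionResult:
    """OLS of the chronology on named annual predictor series.

    Complete cases only; reports coefficients, R^2, adjusted R^2
    (``1 - (1-R^2)(n-1)/(n-k-1)``) and the overall F-test p-value. If the
    design matrix condition number exceeds ``cond_threshold`` a collinearity
    warning with variance inflation factors is issued.
    """
    import statsmodels.api as sm

    y = _chron_series(response).rename("response")
    frame = pd.DataFrame({"response": y, **predictors}).dropna()
    k = len(predictors)
    if len(frame) < k + 5:
        raise ValueError(
            f"only {len(frame)} complete cases for {k} predictors (need >= {k + 5})"
        )
    X = sm.add_constant(frame[list(predictors)])
    model = sm.OLS(frame["response"], X).fit()

    vif = None
    if model.condition_number > cond_threshold and k > 1:
        import warnings
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        Xv = X.to_numpy()
        vif = pd.Series(
            [variance_inflation_factor(Xv, i + 1) for i in range(k)],
            index=list(predictors),
            name="VIF",
        )
        warnings.warn(
            f"collinear predictors (condition number "
            f"{model.condition_number:.1f}); VIFs: {vif.to_dict()}",
            stacklevel=2,
        )
    return RegressionResult(
        params=model.params,
        r_squared=float(model.rsquared),
        adj_r_squared=float(model.rsquared_adj),
        f_pvalue=float(model.f_pvalue),
        nobs=int(model.nobs),
        vif=vif,
        condition_number=float(model.condition_number),
    )
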