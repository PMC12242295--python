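"""Regional curve standardization (RCS).

RCS removes the ontogenetic growth trend from increment series while
preserving common low-frequency variability: all series are aligned by
biological age (position in the series plus the pith offset), an arithmetic
mean population growth curve is computed, a smooth generalized curve (an
n-yr smoothing spline or a negative exponential) is fitted through it, and
each series is detrended by dividing its widths by the curve at the
corresponding ages. Division (rather than subtraction) keeps the index
variance free of ontogenetic trends under a multiplicative error model.

Uncertainty from unknown pith offsets is quantified with a Monte Carlo: each
replicate re-aligns every shell with an independent random extra offset
(uniform on 0..10 increments by default), recomputes the mean curve and
refits the generalized curve; the ensemble envelope summarizes the spread,
which is widest at the youngest ontogenetic ages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .crossdating import DetrendedSeries, smoothing_spline
from .increment_io import IncrementSeries, SeriesCollection

__all__ = [
    "OntogeneticMatrix",
    "RegionalCurveEnsemble",
    "align_ontogenetic",
    "regional_curve",
    "fit_generalized_curve",
    "pith_offset_mc",
    "rcs_detrend",
    "detrend_collection",
]


@dataclass
class OntogeneticMatrix:
    """Shell x ontogenetic-age width matrix with per-age sample depth.

    Age is 1-based: a shell's first measured increment sits at age
    ``pith_offset + 1``.
    """

    table: pd.DataFrame  # rows: shell_id, columns: age, values: width or NaN
    depth: pd.Series  # age -> number of shells with a width at that age

    @property
    def ages(self) -> np.ndarray:
        return self.table.columns.to_numpy()


def align_ontogenetic(
    collection: SeriesCollection | list[IncrementSeries],
) -> OntogeneticMatrix:
    """Place each shell's widths at ontogenetic ages ``offset+1 .. offset+n``."""
    series = list(collection)
    if not series:
        raise ValueError("empty collection")
    for s in series:
        if s.pith_offset < 0:
            raise ValueError(f"{s.shell_id}: negative pith offset")
    max_age = max(s.pith_offset + s.n for s in series)
    ages = pd.RangeIndex(1, max_age + 1, name="age")
    data = np.full((len(series), max_age), np.nan)
    for i, s in enumerate(series):
        data[i, s.pith_offset : s.pith_offset + s.n] = s.widths
    table = pd.DataFrame(data, index=[s.shell_id for s in series], columns=ages)
    depth = table.notna().sum(axis=0)
    depth.name = "depth"
    return OntogeneticMatrix(table=table, depth=depth)


def regional_curve(matrix: OntogeneticMatrix) -> pd.Series:
    """Arithmetic mean width at each ontogenetic age with depth >= 1."""
    if matrix.table.empty:
        raise ValueError("empty ontogenetic matrix")
    mean = matrix.table.mean(axis=0, skipna=True)
    mean.name = "mean_width"
    return mean[matrix.depth >= 1]


def _negexp(a, amp, k, c):
    return amp * np.exp(-k * a) + c


def fit_generalized_curve(
    mean_curve: pd.Series,
    curve_kind: str = "spline",
    cutoff: float = 50.0,
    depth: pd.Series | None = None,
    depth_floor: int = 3,
) -> pd.Series:
    """Fit a smooth, strictly positive generalized curve to the mean curve.

    ``curve_kind='spline'`` fits an n-yr smoothing spline (``cutoff`` years,
    default 50); ``'negative_exponential'`` least-squares fits
    ``A*exp(-k*a) + c`` with non-negative parameters. When a ``depth``
    profile is given, ages in the old-age tail with depth below
    ``depth_floor`` are excluded from the fit (individual trends dominate
    there) and the curve is extended over them — flat for the spline, by the
    closed form for the exponential.
    """
    mc = mean_curve.dropna()
    if len(mc) < 10:
        raise ValueError("mean curve too short to fit (need >= 10 ages)")
    ages_all = mc.index.to_numpy(dtype=float)

    fit_mask = np.ones(len(mc), dtype=bool)
    if depth is not None:
        d = depth.reindex(mc.index).to_numpy(dtype=float)
        deep = np.flatnonzero(d >= depth_floor)
        if deep.size >= 10:
            fit_mask[deep[-1] + 1 :] = False  # drop shallow old-age tail
    a_fit = ages_all[fit_mask]
    y_fit = mc.to_numpy(dtype=float)[fit_mask]

    if curve_kind == "spline":
        fitted = smoothing_spline(y_fit, cutoff)
        values = np.concatenate(
            [fitted, np.full((~fit_mask).sum(), fitted[-1])]
        )
    elif curve_kind == "negative_exponential":
        p0 = (max(y_fit.max() - y_fit.min(), 1e-6), 0.02, max(y_fit.min(), 1e-6))
        try:
            popt, _ = curve_fit(
                _negexp, a_fit, y_fit, p0=p0,
                bounds=([0, 0, 0], [np.inf, np.inf, np.inf]), maxfev=10000,
            )
        except RuntimeError as exc:
            raise RuntimeError(
                "negative-exponential fit did not converge; try "
                "curve_kind='spline'"
            ) from exc
        values = _negexp(ages_all, *popt)
    else:
        raise ValueError(f"unknown curve_kind {curve_kind!r}")

    if np.any(values <= 0):
        raise ValueError("fitted generalized curve not strictly positive")
    out = pd.Series(values, index=mc.index, name=f"rcs_{curve_kind}")
    out.attrs["curve_kind"] = curve_kind
    out.attrs["cutoff"] = cutoff
    return out


@dataclass
class RegionalCurveEnsemble:
    """Pith-offset Monte Carlo ensemble of regional growth curves."""

    ages: np.ndarray
    mean_curve: pd.Series  # raw arithmetic mean at nominal offsets
    zero_offset_curve: pd.Series  # generalized curve at nominal offsets
    fitted_curves: np.ndarray  # (n_mc, n_ages), NaN outside a replicate's range
    envelope: pd.DataFrame  # columns: min, central, max
    curve_kind: str
    n_mc: int
    max_offset: int
    seed: int


def pith_offset_mc(
    collection: SeriesCollection | list[IncrementSeries],
    max_offset: int = 10,
    n_mc: int = 1000,
    curve_kind: str = "spline",
    cutoff: float = 50.0,
    seed: int = 0,
    depth_floor: int = 3,
) -> RegionalCurveEnsemble:
    """Monte Carlo over random extra pith offsets.

    Each replicate shifts every shell's alignment by an independent uniform
    integer in ``[0, max_offset]`` on top of its nominal pith offset, then
    recomputes the mean population curve and refits the generalized curve.
    The envelope (min/central/max per age, over the replicates plus the
    zero-extra-offset curve) quantifies the alignment uncertainty, which
    concentrates in the earliest years of growth.
    """
    series = list(collection)
    rng = np.random.default_rng(seed)
    base_starts = np.array([s.pith_offset for s in series])
    lengths = np.array([s.n for s in series])
    widths = [s.widths for s in series]
    max_age = int((base_starts + lengths).max()) + max_offset

    matrix = align_ontogenetic(series)
    mean_curve = regional_curve(matrix)
    zero_fit = fit_generalized_curve(
        mean_curve, curve_kind, cutoff, depth=matrix.depth,
        depth_floor=depth_floor,
    )

    fitted = np.full((n_mc, max_age), np.nan)
    for rep in range(n_mc):
        extra = rng.integers(0, max_offset + 1, size=len(series))
        sums = np.zeros(max_age)
        counts = np.zeros(max_age, dtype=int)
        for w, s0, e in zip(widths, base_starts, extra):
            i0 = s0 + e
            sums[i0 : i0 + w.size] += w
            counts[i0 : i0 + w.size] += 1
        covered = counts >= 1
        mc_mean = pd.Series(
            sums[covered] / counts[covered],
            index=pd.RangeIndex(1, max_age + 1, name="age")[covered],
        )
        depth = pd.Series(counts[covered], index=mc_mean.index)
        fit = fit_generalized_curve(
            mc_mean, curve_kind, cutoff, depth=depth, depth_floor=depth_floor
        )
        fitted[rep, fit.index.to_numpy() - 1] = fit.to_numpy()

    all_ages = pd.RangeIndex(1, max_age + 1, name="age")
    zero_full = np.full(max_age, np.nan)
    zero_full[zero_fit.index.to_numpy() - 1] = zero_fit.to_numpy()
    stack = np.vstack([fitted, zero_full])
    covered = np.isfinite(stack).any(axis=0)
    env = pd.DataFrame(
        np.nan, index=all_ages, columns=["min", "central", "max"]
    )
    env.loc[covered, "min"] = np.nanmin(stack[:, covered], axis=0)
    env.loc[covered, "max"] = np.nanmax(stack[:, covered], axis=0)
    covered_f = np.isfinite(fitted).any(axis=0)
    env.loc[covered_f, "central"] = np.nanmedian(fitted[:, covered_f], axis=0)
    env = env.dropna(how="all")
    return RegionalCurveEnsemble(
        ages=all_ages.to_numpy(),
        mean_curve=mean_curve,
        zero_offset_curve=zero_fit,
        fitted_curves=fitted,
        envelope=env,
        curve_kind=curve_kind,
        n_mc=n_mc,
        max_offset=max_offset,
        seed=seed,
    )


def extend_curve(curve: pd.Series, max_age: int, min_age: int = 1) -> pd.Series:
    """Flat-extend a regional curve beyond its covered age range.

    The old-age end is asymptotic so a flat hold is natural; the young-age
    end is held flat too (only ever a few ages, when no retained shell has a
    zero pith offset).
    """
    first, last = int(curve.index.min()), int(curve.index.max())
    pieces = [curve]
    if min_age < first:
        pieces.insert(
            0,
            pd.Series(
                curve.iloc[0],
                index=pd.RangeIndex(min_age, first, name="age"),
            ),
        )
    if max_age > last:
        pieces.append(
            pd.Series(
                curve.iloc[-1],
                index=pd.RangeIndex(last + 1, max_age + 1, name="age"),
            )
        )
    out = pd.concat(pieces) if len(pieces) > 1 else curve
    out.attrs.update(curve.attrs)
    return out


def rcs_detrend(series: IncrementSeries, curve: pd.Series) -> DetrendedSeries:
    """Divide a series by the regional curve at its ontogenetic ages."""
    ages = np.arange(series.pith_offset + 1, series.pith_offset + series.n + 1)
    missing = np.setdiff1d(ages, curve.index.to_numpy())
    if missing.size:
        raise ValueError(
            f"{series.shell_id}: regional curve does not cover ages "
            f"{missing[:5].tolist()}..."
        )
    cv = curve.loc[ages].to_numpy(dtype=float)
    if np.any(cv <= 0):
        raise ValueError(f"{series.shell_id}: curve non-positive at needed ages")
    return DetrendedSeries(
        shell_id=series.shell_id,
        indices=series.widths / cv,
        first_year=series.first_year,
        wavelength=None,
    )


def detrend_collection(
    collection: SeriesCollection | list[IncrementSeries],
    curve: pd.Series,
) -> list[DetrendedSeries]:
    return [rcs_detrend(s, curve) for s in collection]
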