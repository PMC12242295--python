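"""Frequency-domain analysis of annual chronologies.

Three tools, all built around the same AR(1) "red noise" null that annual
biological series typically follow:

* **Multitaper (MTM) spectra** — eigenspectra from discrete prolate
  spheroidal (Slepian) tapers are averaged; peak significance is judged
  against the theoretical AR(1) spectrum scaled by chi-squared quantiles
  with 2K degrees of freedom.
* **Morlet continuous wavelet transform** — time-resolved power on a
  log-spaced period grid, with the cone of influence at the e-folding
  distance of the wavelet response, and pointwise significance from a
  surrogate ensemble.
* **Surrogate-based correlation testing** — the Ebisuzaki approach:
  phase-randomized (or AR(1)-simulated) surrogates preserve each series'
  autocorrelation/spectral structure, so the null distribution of the
  correlation coefficient accounts for the serial dependence that makes the
  naive t-test anticonservative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.fft import fft, ifft, irfft, next_fast_len, rfft, rfftfreq
from scipy.signal.windows import dpss

__all__ = [
    "AR1Fit",
    "SpectrumResult",
    "WaveletResult",
    "SurrogateSpec",
    "ar1_fit",
    "mtm_spectrum",
    "significant_peaks",
    "morlet_wavelet",
    "surrogate_ensemble",
    "wavelet_significance",
    "emc_correlation_test",
]


def _as_values(x) -> np.ndarray:
    if isinstance(x, pd.Series):
        x = x.to_numpy()
    v = np.asarray(x, dtype=float)
    if v.ndim != 1:
        raise ValueError("expected a 1-D annual series")
    if not np.all(np.isfinite(v)):
        raise ValueError("series contains non-finite values")
    return v


# ---------------------------------------------------------------------------
# AR(1) red-noise background
# ---------------------------------------------------------------------------


@dataclass
class AR1Fit:
    phi: float
    sigma: float  # innovation standard deviation
    variance: float  # total series variance

    def background(self, freqs: np.ndarray) -> np.ndarray:
        """One-sided theoretical AR(1) power spectral density, scaled so it
        integrates (over 0..0.5 cycles/yr) to the series variance."""
        f = np.asarray(freqs, dtype=float)
        return (
            2.0
            * self.variance
            * (1.0 - self.phi**2)
            / (1.0 - 2.0 * self.phi * np.cos(2.0 * np.pi * f) + self.phi**2)
        )


def ar1_fit(series) -> AR1Fit:
    """Fit an AR(1) null: lag-1 sample autocorrelation and innovation sd.

    The mean is removed internally; ``sigma^2 = var * (1 - phi^2)``.
    """
    x = _as_values(series)
    if x.size < 10:
        raise ValueError("need at least 10 points to fit AR(1)")
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0:
        raise ValueError("zero-variance series")
    phi = float((x[:-1] @ x[1:]) / denom)
    if abs(phi) >= 1:
        raise ValueError(f"|phi| = {abs(phi):.3f} >= 1 (nonstationary)")
    var = float(x.var())
    return AR1Fit(phi=phi, sigma=float(np.sqrt(var * (1 - phi**2))), variance=var)


# ---------------------------------------------------------------------------
# Multitaper spectrum
# ---------------------------------------------------------------------------


@dataclass
class SpectrumResult:
    freqs: np.ndarray  # cycles/yr, > 0
    power: np.ndarray
    nw: float
    k: int
    phi: float
    background: np.ndarray
    conf95: np.ndarray
    conf99: np.ndarray

    @property
    def periods(self) -> np.ndarray:
        return 1.0 / self.freqs


def mtm_spectrum(series, nw: float = 2.0, k: int = 3) -> SpectrumResult:
    """Multitaper PSD with red-noise significance curves.

    ``k`` Slepian tapers at time-bandwidth ``nw`` (requires
    ``k <= 2*nw - 1``); eigenspectra are averaged and the result rescaled so
    the spectrum integrates to the series variance (Parseval). The 95%/99%
    curves are the AR(1) background times the chi-squared quantile with
    ``2k`` degrees of freedom over ``2k``.
    """
    x = _as_values(series)
    n = x.size
    if n < 50:
        raise ValueError("need at least 50 points for a multitaper spectrum")
    if k > 2 * nw - 1:
        raise ValueError(f"k={k} exceeds 2*nw-1={2 * nw - 1:g}")
    x = x - x.mean()
    var = float(x.var())
    fit = ar1_fit(series)

    npad = next_fast_len(2 * n)
    tapers = np.atleast_2d(dpss(n, nw, Kmax=k))
    tapers = tapers / np.sqrt((tapers**2).sum(axis=1, keepdims=True))
    spec = np.zeros(npad // 2 + 1)
    for taper in tapers:
        xk = rfft(taper * x, n=npad)
        spec += np.abs(xk) ** 2
    spec /= k

    freqs = rfftfreq(npad, d=1.0)
    pos = freqs > 0
    freqs = freqs[pos]
    power = spec[pos]
    # rescale so sum(power) * df = variance
    df = freqs[1] - freqs[0]
    power *= var / (power.sum() * df)

    bg = fit.background(freqs)
    bg *= var / (bg.sum() * df)
    dof = 2 * k
    conf95 = bg * stats.chi2.ppf(0.95, dof) / dof
    conf99 = bg * stats.chi2.ppf(0.99, dof) / dof
    return SpectrumResult(
        freqs=freqs, power=power, nw=nw, k=k, phi=fit.phi,
        background=bg, conf95=conf95, conf99=conf99,
    )


def significant_peaks(result: SpectrumResult, level: str = "conf99") -> pd.DataFrame:
    """Local spectral maxima exceeding a confidence curve.

    Returns a table of (period, frequency, power, threshold) sorted by
    power, one row per contiguous above-threshold excursion (its maximum).
    """
    thr = getattr(result, level)
    above = result.power > thr
    rows = []
    i = 0
    while i < above.size:
        if above[i]:
            j = i
            while j + 1 < above.size and above[j + 1]:
                j += 1
            seg = slice(i, j + 1)
            arg = i + int(np.argmax(result.power[seg]))
            rows.append(
                (
                    1.0 / result.freqs[arg],
                    result.freqs[arg],
                    result.power[arg],
                    thr[arg],
                )
            )
            i = j + 1
        else:
            i += 1
    return (
        pd.DataFrame(rows, columns=["period", "frequency", "power", "threshold"])
        .sort_values("power", ascending=False)
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# Morlet continuous wavelet transform
# ---------------------------------------------------------------------------


def _fourier_factor(omega0: float) -> float:
    return 4.0 * np.pi / (omega0 + np.sqrt(2.0 + omega0**2))


@dataclass
class WaveletResult:
    years: np.ndarray
    periods: np.ndarray  # log-spaced, ascending
    power: np.ndarray  # (n_periods, n_years)
    coi: np.ndarray  # per-year maximum trustworthy period
    omega0: float
    signif_mask: np.ndarray | None = None
    pvalues: np.ndarray | None = None

    def in_coi(self) -> np.ndarray:
        """Boolean (n_periods, n_years) mask of cells inside the cone of
        influence (i.e. *not* edge-affected)."""
        return self.periods[:, None] <= self.coi[None, :]


def _morlet_transform(
    X: np.ndarray, npad: int, scales: np.ndarray, omega0: float
) -> np.ndarray:
    """Batch CWT. ``X``: (m, npad) FFTs of zero-padded rows. Returns power
    (m, n_scales, npad) — callers slice off the padding."""
    omega = 2.0 * np.pi * np.fft.fftfreq(npad, d=1.0)
    out = np.empty((X.shape[0], scales.size, npad))
    for j, s in enumerate(scales):
        psi = np.zeros(npad)
        posit = omega > 0
        psi[posit] = (
            np.pi**-0.25
            * np.sqrt(2.0 * np.pi * s)
            * np.exp(-0.5 * (s * omega[posit] - omega0) ** 2)
        )
        out[:, j, :] = np.abs(ifft(X * psi, axis=1)) ** 2
    return out


def morlet_wavelet(
    series,
    omega0: float = 6.0,
    periods: np.ndarray | None = None,
    dj: float = 0.25,
    years: np.ndarray | None = None,
) -> WaveletResult:
    """Continuous Morlet wavelet power of an annual series.

    The Fourier period of scale ``s`` is ``4 pi s / (omega0 +
    sqrt(2 + omega0^2))`` (~1.033 s for omega0 = 6). Periods default to a
    log grid (``dj`` octave fraction spacing) from 2 yr to half the series
    length; requested periods outside [2, n/2] are trimmed. The cone of
    influence marks, per year, the longest period whose e-folding distance
    ``sqrt(2) * s`` fits within the record.
    """
    if isinstance(series, pd.Series) and years is None:
        years = series.index.to_numpy()
    x = _as_values(series)
    n = x.size
    if years is None:
        years = np.arange(n)
    x = x - x.mean()

    ff = _fourier_factor(omega0)
    user_grid = periods is not None
    if periods is None:
        n_oct = np.log2((n / 2.0) / 2.0)
        periods = 2.0 * 2.0 ** (np.arange(0, n_oct + dj, dj))
    periods = np.asarray(periods, dtype=float)
    keep = (periods >= 2.0) & (periods <= n / 2.0)
    if user_grid and not keep.all():
        import warnings

        warnings.warn("period grid trimmed to [2, n/2] yr", stacklevel=2)
    periods = periods[keep]
    if periods.size == 0:
        raise ValueError("no valid periods in [2, n/2]")
    scales = periods / ff

    npad = next_fast_len(2 * n)
    X = fft(np.pad(x, (0, npad - n))[None, :], axis=1)
    power = _morlet_transform(X, npad, scales, omega0)[0, :, :n]

    dist = np.minimum(np.arange(n), np.arange(n)[::-1]).astype(float)
    coi = ff * dist / np.sqrt(2.0)
    return WaveletResult(
        years=np.asarray(years), periods=periods, power=power, coi=coi,
        omega0=omega0,
    )


# ---------------------------------------------------------------------------
# Surrogates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurrogateSpec:
    method: str = "phase_randomization"  # or "ar1"
    n_surrogates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("phase_randomization", "ar1"):
            raise ValueError(f"unknown surrogate method {self.method!r}")
        if self.n_surrogates < 1:
            raise ValueError("n_surrogates must be >= 1")


def surrogate_ensemble(series, spec: SurrogateSpec) -> np.ndarray:
    """Generate ``(n_surrogates, n)`` surrogate series.

    ``phase_randomization`` (Ebisuzaki): the FFT phases of the original are
    replaced by uniform random phases while the amplitude spectrum, the DC
    component and (for even n) the Nyquist component's realness are
    preserved, so each surrogate shares the original's full power spectrum
    and hence its autocorrelation. ``ar1``: simulates an AR(1) process with
    the fitted (phi, sigma), length-matched, mean added back.
    """
    x = _as_values(series)
    n = x.size
    rng = np.random.default_rng(spec.seed)
    m = spec.n_surrogates

    if spec.method == "phase_randomization":
        xf = rfft(x)
        nf = xf.size
        # rotate each bin by a random unit phasor: amplitudes untouched
        rot = np.exp(1j * rng.uniform(0, 2 * np.pi, size=(m, nf)))
        rot[:, 0] = 1.0  # DC untouched: mean preserved exactly
        if n % 2 == 0:
            # Nyquist bin must stay real; random sign preserves |FFT|
            rot[:, -1] = np.where(rng.random(m) < 0.5, 1.0, -1.0)
        return irfft(xf[None, :] * rot, n=n, axis=1)

    fit = ar1_fit(x)
    mu = x.mean()
    burn = int(np.ceil(10.0 / (1.0 - abs(fit.phi)))) if abs(fit.phi) < 1 else 10
    innov = rng.normal(0.0, fit.sigma, size=(m, n + burn))
    out = np.empty((m, n + burn))
    out[:, 0] = innov[:, 0] / np.sqrt(1 - fit.phi**2)
    for i in range(1, n + burn):
        out[:, i] = fit.phi * out[:, i - 1] + innov[:, i]
    return out[:, burn:] + mu


def wavelet_significance(
    result: WaveletResult,
    series,
    spec: SurrogateSpec,
    alpha: float = 0.05,
) -> np.ndarray:
    """Pointwise surrogate test of wavelet power.

    For each (period, year) cell, ``p = (1 + #{surrogate power >= observed})
    / n_surrogates`` (clipped to 1), and the significance mask is
    ``p < alpha``. Requires at least 100 surrogates. The mask and p-values
    are stored on ``result`` and the mask returned.
    """
    if spec.n_surrogates < 100:
        raise ValueError("need >= 100 surrogates for p < 0.05 claims")
    x = _as_values(series)
    n = x.size
    surr = surrogate_ensemble(x, spec)
    surr = surr - surr.mean(axis=1, keepdims=True)

    ff = _fourier_factor(result.omega0)
    scales = result.periods / ff
    npad = next_fast_len(2 * n)
    X = fft(np.pad(surr, ((0, 0), (0, npad - n))), axis=1)

    counts = np.zeros_like(result.power, dtype=int)
    omega = 2.0 * np.pi * np.fft.fftfreq(npad, d=1.0)
    posit = omega > 0
    for j, s in enumerate(scales):
        psi = np.zeros(npad)
        psi[posit] = (
            np.pi**-0.25
            * np.sqrt(2.0 * np.pi * s)
            * np.exp(-0.5 * (s * omega[posit] - result.omega0) ** 2)
        )
        sp = np.abs(ifft(X * psi, axis=1))[:, :n] ** 2
        counts[j] = (sp >= result.power[j][None, :]).sum(axis=0)

    p = np.minimum(1.0, (counts + 1) / spec.n_surrogates)
    mask = p < alpha
    result.pvalues = p
    result.signif_mask = mask
    return mask


# ---------------------------------------------------------------------------
# Ebisuzaki Monte Carlo correlation test
# ---------------------------------------------------------------------------


def _align(x, y) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        common = x.dropna().index.intersection(y.dropna().index)
        return x.loc[common].to_numpy(float), y.loc[common].to_numpy(float)
    xv, yv = np.asarray(x, float), np.asarray(y, float)
    if xv.size != yv.size:
        raise ValueError("plain arrays must have equal length")
    m = np.isfinite(xv) & np.isfinite(yv)
    return xv[m], yv[m]


def _rowwise_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    num = (a * b).sum(axis=1)
    den = np.sqrt((a**2).sum(axis=1) * (b**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def emc_correlation_test(
    x,
    y,
    spec: SurrogateSpec = SurrogateSpec(),
    surrogate_both: bool = True,
) -> tuple[float, float]:
    """Correlation with autocorrelation-aware significance (Ebisuzaki).

    ``r`` is the Pearson correlation on the overlap; ``p`` is the fraction
    of surrogate pairs whose ``|r|`` meets or exceeds the observed
    (``(count+1)/n_surrogates``, clipped to 1). By default both series are
    surrogated (conservative); ``surrogate_both=False`` surrogates only
    ``x``.
    """
    xv, yv = _align(x, y)
    n = xv.size
    if n < 20:
        raise ValueError(f"overlap {n} < 20 yr")
    if xv.std() == 0 or yv.std() == 0:
        raise ValueError("zero-variance input")
    r = float(np.corrcoef(xv, yv)[0, 1])

    sx = surrogate_ensemble(xv, SurrogateSpec(spec.method, spec.n_surrogates, spec.seed))
    if surrogate_both:
        sy = surrogate_ensemble(
            yv, SurrogateSpec(spec.method, spec.n_surrogates, spec.seed + 1)
        )
    else:
        sy = np.broadcast_to(yv, (spec.n_surrogates, n))
    r_surr = _rowwise_corr(sx, sy)
    count = int(np.sum(np.abs(r_surr) >= abs(r)))
    p = min(1.0, (count + 1) / spec.n_surrogates)
    return r, p
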