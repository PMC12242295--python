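# Methods

## The statistical model

The pipeline treats an individual shell's annual increment widths as a
multiplicative composition

    w_i(t) = g(a_i(t)) · s(t) · ε_i(t),

where `g(a)` is the population ontogenetic growth curve at biological age
`a` (age = position in the measured series + pith offset, 1-based), `s(t)`
is an environmental signal common to all shells alive in calendar year `t`,
and `ε_i(t)` is individual multiplicative noise. The multiplicative form is
the error model under which detrending **by division** is exactly unbiased:
dividing widths by an estimate of `g` leaves `s(t)·ε_i(t)`, and averaging
across shells estimates `s(t)`. The real error model of shell growth is
unknown; the lognormal choice for `ε` is a stand-in whose main virtues are
positivity and scale-invariance.

## Synthetic populations

`synthetic_data.SimulationConfig` defaults describe the study conditions the
pipeline is designed for: a 1410–2021 span; lifespans drawn from a normal
(120, 36²) truncated to [52, 245] yr; pith offsets uniform on {0..10}
increments (deleted from the series and recorded); an ontogenetic curve
`g(a) = 250·e^(−0.04a) + 40` (arbitrary width units — all downstream
statistics are unit-invariant); and a common signal built from a ~200-yr and
a ~16-yr sinusoid plus an AR(1) process (φ = 0.5, Gaussian innovations,
burn-in 10/(1−φ) steps), standardized to mean 1 and sd 0.15.

The noise level is the one free parameter that sets how hard every
downstream task is. The default `noise_sd = 0.18` was calibrated once so
that leave-one-out series–chronology correlations land near 0.5 — a
30-shell draw gives r = 0.52 ± 0.08, overlaps ≈ 110 yr and t ≈ 6.5, the
regime reported for real *Arctica islandica* populations. A lower setting,
`noise_sd = 0.115`, realizes the stronger regime in which pairwise
spline-detrended correlations average ≈ 0.5; crossdating recovery
experiments use that setting. Fractions of shells can be emitted undated
("floating", as dead-collected shells are) with their true placement
retained in the truth table.

What the generator does *not* emulate: mechanistic (e.g. von Bertalanffy)
growth, temperature-dependent growth responses, heteroscedastic measurement
error, missing or false rings, within-population cohort differences, and
spatial structure between stations. Passing recovery tests therefore shows
the statistical machinery is correct under the stated model, not that real
shells satisfy that model.

## Crossdating

Series are detrended with cubic smoothing splines parameterized by the
period at which the smoother's frequency response equals 0.5 (the classical
"n-yr spline"). The smoother minimizes `Σ(y−f)² + λΣ(Δ²f)²` on the annual
grid; since the second-difference penalty has transfer function
`(2−2cos ω)²`, choosing `λ = (2−2cos(2π/p))⁻²` puts the half-amplitude
point exactly at period `p`. This is verified behaviourally (a sinusoid at
the cutoff retains 0.50 ± 0.05 of its relative amplitude after division
detrending) rather than by matching any particular implementation's
coefficients.

Lead–lag correlation evaluates Pearson r on the detrended overlap for every
lag in ±max_lag (default 50) and every wavelength in 7–32 yr, with
`t = r√((n−2)/(1−r²))` and a two-sided p from the t distribution. The
Bonferroni multiplicity is the number of *defined* cells actually evaluated
(zero-variance or under-overlap cells are not tests performed). A positive
best lag means the series' nominal placement is that many years too late.

Acceptance requires three conditions: Bonferroni-adjusted p < α (0.05), the
best lag's t exceeding the runner-up lag's by a margin (default 2.0 — the
operationalization of "notably greater", since no standard threshold
exists), and no 21-yr running-correlation window below a floor (default
0.0). The margin rule matters in practice: a strongly periodic common
signal (the 16-yr component) produces alias matches at lags that are
multiples of the period, which pass the p-value screen but fail the margin.
Minimum overlap (30 yr) and the lag grid are conventional defaults, all
configurable. `date_floating` scans every feasible placement of an undated
series along a reference chronology rather than a ±max_lag window.

Leave-one-out validation rebuilds the full RCS + chronology pipeline
without each shell and correlates the held-out, RCS-detrended series with
that chronology at lag 0. When the held-out shell outlives (or starts
younger than) every remaining shell, the regional curve is extended flat at
the ends for detrending it.

## Regional curve standardization

The arithmetic mean width per ontogenetic age (the "regional curve") is fit
with a generalized curve — by default a 50-yr smoothing spline; 10/25/100-yr
splines and a non-negative least-squares negative exponential are
selectable; on synthetic populations the choice changes the resulting
chronology by well under 5% RMS. Ages in the old-age tail whose sample
depth falls below 3 are excluded from the fit (individual trends dominate
there) and the curve is held flat across them; shell growth is
near-asymptotic at those ages, which makes the flat hold mild.

Pith-offset uncertainty is quantified by Monte Carlo: each of 1000
replicates adds an independent uniform {0..10} extra offset to every
shell's alignment, recomputes the mean curve and refits the generalized
curve. The reported envelope is the per-age min/median/max across
replicates (the zero-extra-offset curve is included in the min/max so the
envelope always contains it). The envelope is widest at the youngest ages,
where misalignment moves the steep part of the curve. The chronology itself
is detrended with the zero-offset fitted curve; the ensemble is reported as
uncertainty. Stations are pooled into one curve, treating the population as
sharing a common growth signal.

## Chronology and quality statistics

Per calendar year the chronology is Tukey's biweight robust location of the
available indices (tuning constant c = 9, median start, iterated to 1e-8;
median returned when the MAD is zero). The biweight resists single
anomalous shells: in the corruption tests one gross outlier shell degrades
the arithmetic-mean chronology measurably more than the biweight one. No
variance stabilization for changing sample depth is applied by default.

Rbar is the mean of all pairwise Pearson correlations among series with at
least 20 joint years inside the window (shorter overlaps make unstable
correlations); windows are 100 yr at 50% overlap. EPS uses the standard
form `n·r̄/(n·r̄ + (1−r̄))` with `n` the *mean* sample depth over the
window's years — depth varies within a window, and mean depth is the
common convention; a minimum-depth variant would be more conservative. The
full-record Rbar/EPS apply the same definitions to the whole span.

The loess low-pass is locally weighted degree-1 regression with tricube
weights (one robustness iteration), which is exact on linear trends.

## Spectral analysis

The multitaper spectrum averages K = 3 eigenspectra from Slepian tapers at
time-bandwidth NW = 2 (the usual low-resolution/high-stability choice;
configurable, with K ≤ 2NW−1 enforced), zero-padded to the next fast FFT
length ≥ 2n, and rescales so the spectrum integrates to the series variance
(Parseval). Significance curves are the theoretical AR(1) spectrum

    S(f) ∝ (1−φ²) / (1 − 2φ cos 2πf + φ²),

scaled to the same variance and multiplied by χ²-quantiles (0.95, 0.99)
with 2K degrees of freedom over 2K. φ is the lag-1 sample autocorrelation.

The Morlet wavelet (ω₀ = 6) follows the standard continuous-transform
construction via FFT; the Fourier period is `4πs/(ω₀+√(2+ω₀²)) ≈ 1.033s`,
periods are log-spaced (quarter octaves) over [2, n/2], and the cone of
influence is the √2·s e-folding distance from each edge. Wavelet
significance is **pointwise**: per (period, year) cell the p-value is the
exceedance rank of the observed power in a surrogate ensemble,
`p = (1 + #{surrogate ≥ observed}) / N` clipped to 1 (so p ∈ [1/N, 1]); no
areawise correction is applied, so isolated significant pixels at the ~5%
rate are expected even under the null.

Two surrogate constructions are provided. AR(1) surrogates simulate the
fitted red-noise process and are the null for *spectral* significance
(a deterministic periodic component then shows up as excess band power).
Phase-randomization surrogates preserve the series' full amplitude spectrum
exactly (random unit phasors per FFT bin; DC untouched so the mean is
preserved; the Nyquist bin gets a random sign) and are the null for
*correlation* testing: they share the original's autocorrelation, so the
surrogate distribution of r widens exactly as serial dependence demands.
Phase-randomized surrogates are useless for testing spectral peaks — they
contain the peak — which is why the wavelet default is AR(1). The
correlation (EMC) test surrogates both series by default (conservative) and
uses the two-sided exceedance of |r|. On independent AR(1)(φ = 0.7) pairs
it holds the 5% level (measured ≈ 4%) where the naive t-test rejects >20% —
the reason the test exists. AR surrogate order is fixed at 1.

## Climate correlation

Monthly gridded fields are reduced to annual per-cell series by averaging
the season's months, with December assigned to the following January's year
for boundary-crossing seasons, and thickness-weighting over the requested
depth range (layer bounds at midpoints between level centres, the first at
0 m); `depth_range=(z, z)` selects the single nearest level. Years missing
any season month are dropped. Per-cell Pearson r is computed over the joint
years within the analysis period (≥ 10 required), with the two-sided
regression p-value; no field-wide multiple-testing correction is applied by
default, matching standard practice of per-cell maps followed by EMC
re-testing of candidate cells. OLS multiple regression reports the adjusted
R² `1 − (1−R²)(n−1)/(n−k−1)` on complete cases and warns with VIFs when the
design is ill-conditioned.

NetCDF I/O uses xarray's scipy backend (NETCDF3 classic), which covers the
EN4-style `time × depth × lat × lon` layout used here.

## Numerical and design notes

- Undefined correlation cells (zero variance, insufficient overlap) are
  excluded from Bonferroni counts and from Rbar averages, not imputed.
- The biweight falls back to the median when MAD = 0; correlations are
  clipped to [−1, 1]; t-statistics cap |r| at 1−1e−12 to avoid overflow.
- All Monte Carlo stages take explicit seeds and are bit-reproducible; the
  pipeline manifest records seeds, parameters and output checksums.
- RWL output rounds widths to integers in file units (0.001 mm convention)
  and uses the −9999 terminator; both 999 and −9999 are accepted on read.
  Measurement units are carried opaquely — every downstream statistic is
  invariant to positive rescaling.
- Increments are labelled with the year their growing season begins; a
  partially formed final increment of a live-collected shell can be dropped
  with `drop_final_partial`.

## Problem sizes

The test suite and the acceptance script run everything at desk scale:
populations of 30–50 shells over a ~600-yr span, 1000-replicate pith-offset
Monte Carlo, 1000 surrogates for wavelet significance and EMC, 1000
independent pairs for false-accept calibration and 500 trials for EMC
type-I measurement. These sizes give Monte-Carlo standard errors well below
the decision margins they feed.

## Known limitations

- Wavelet significance is pointwise; contiguous-region claims are
  qualitative.
- The EPS variant behind any particular published 0.85 figure (mean-depth
  vs per-year depth) varies between softwares; both views are computable
  here, mean-depth is the default.
- The generalized-curve flat extension beyond the fitted age range slightly
  biases indices of the very oldest (or earliest-truncated) ages.
- Floating-shell acceptance at realistic noise is deliberately
  conservative: strongly periodic common signals create alias placements
  that only the t-margin and running-correlation screens reject, at the
  cost of leaving some correctly placed shells unaccepted (they would go to
  visual inspection in practice).
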