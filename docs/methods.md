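# Methods

This note records the statistical model behind `sclerochron`, the defaults
and why they were chosen, the numerical conventions, and the limits of
what the synthetic-data experiments can show.

## Chronology model

Each specimen's increment widths are treated as

    w_i(t) = g_i(age_i(t)) · exp(β·Z_t + ε_it),

a deterministic ontogenetic curve `g_i` modulated multiplicatively by a
common environmental signal `Z_t` (shared across specimens) and individual
lognormal noise ε ~ N(0, σ²). The multiplicative form guarantees positive
widths and makes ratio indices well defined. Standardization estimates and
removes `g_i`; averaging the residual indices across specimens estimates
the common signal up to scale.

### Spline standardization (QC path)

The crossdating-QC path fits a cubic smoothing spline to each series and
divides observed by fitted values. Stiffness is parameterized by the 50%
frequency cutoff: for a unit-spaced series the penalized smoothing spline
acts, at interior points, as a linear filter with amplitude response

    H(ω) = 1 / (1 + λ·g(ω)),   g(ω) = 12·(1 − cos ω)² / (2 + cos ω),

so λ is set to make H(2π/cutoff) = ½. The factor 12 was fixed by direct
measurement: with it, `scipy.interpolate.make_smoothing_spline` attenuates
a period-15 sinusoid to 0.500 under a 15-yr cutoff (the package's tests
verify the response at 0.5×, 1×, 2× and 5× the cutoff to within 0.05).
`spline_frequency_response` evaluates the response as a ratio of penalty
spectra, so the constant cancels there. Edge behavior of the spline is
ill-defined; frequency-response checks therefore trim three cutoff-lengths
from each end and the QC statistics make no claim about the outermost
years.

### Power transform and age-trend removal (chronology path)

The adaptive power transform regresses log local spread |x_{t+1} − x_t| on
log local level (x_t + x_{t+1})/2; slope b gives exponent p = 1 − b,
clamped to [0, 1] (variance-inflating transforms are never applied), with
|p| < 0.05 snapping to the log transform. The age trend
`a·e^(−b·age) + k` (a, b > 0, k ≥ 0) is then fitted by bounded least
squares and removed by subtraction in transformed space — after variance
stabilization, residuals rather than ratios are the natural index, and the
log branch can produce nonpositive values for which ratios are undefined
(ratio mode remains available and falls back to untransformed widths). A
fit that fails to converge, violates its constraints, or declines by less
than 1% of the series' standard deviation falls back to a
nonpositive-slope line, and, if even the linear slope is positive, to the
horizontal mean. Residual indices are shifted to unit mean per series
before averaging so both detrending modes yield a comparable dimensionless
chronology.

### Averaging, EPS, truncation

Yearly values use Tukey's biweight robust mean (c = 9, median/MAD start,
at most 10 reweighting iterations), the convention of classical
chronology software; the arithmetic mean is available. Signal strength
uses EPS = n·r̄/(n·r̄ + (1 − r̄)); a suite test confirms the closed form
against a brute-force Monte-Carlo variance-ratio estimate to within 0.03.
The running EPS slides a 30-yr window in 1-yr steps; within a window, r̄
averages pairwise-complete Pearson correlations among series present for
at least ⅔ of the window (staggered lifespans make full-window pairs
rare), and n is the mean yearly sample depth. A year's EPS status comes
from the most recent fully defined window covering it, and the truncation
year is the earliest year from which every later year satisfies both
sample depth ≥ 10 and window EPS ≥ 0.85. Earlier years are retained but
flagged provisional. An `eps_threshold` of 0 disables the EPS half of the
rule explicitly.

### Crossdating QC

Interseries correlation follows the leave-one-out convention: each
detrended series against the arithmetic mean of all others over their
common years (≥ 10 yr required, otherwise the series is excluded with a
warning). Segments of 30 yr lagged by 15 are tested one-tailed (r > 0,
t-approximation, n − 2 df) at α = 0.01 — dating errors manifest as loss of
positive correlation, so a one-tailed test is the sharper instrument.
Trailing segments shorter than 15 yr are skipped. Flagged segments carry
the lag in [−5, 5] that best re-aligns them with the master (ties resolved
toward 0, then toward negative lags). When localizing a suspected
insertion/omission, the lag search is applied to the 30 years preceding
the suspect year — the same span as a QC segment — because the earliest
years of long series are covered by few other specimens and their
leave-one-out master is too noisy for reliable lag attribution. The
package flags and localizes; it never auto-corrects a dating error — that
judgement stays with the analyst.

## Climate-growth inference

Deseasonalization removes a least-squares fit of mean plus sin/cos pairs
at 12- and 6-month periods; gaps are excluded from the fit and preserved.
Growth-year alignment maps the increment labeled *y* to October(y−1)
through September(y), preceded by prior-year April–September, giving 18
month columns; rows with any missing month are dropped with a warning.
Spearman correlations use mid-ranks and a two-tailed t-approximation with
n − 2 df, switching to an exact permutation null (all n! orderings) below
n = 10. Two-tailed p-values are used throughout as the conservative
reading of 90/95% significance tiers. No multiple-testing correction is
applied across the variable × month grid — instead every correlation
table carries the expected number of false positives at α = 0.05 so the
reader can calibrate.

Stepwise regression is forward-only OLS: at each step the candidate with
the smallest partial-F p-value enters if below `p_enter` (default 0.05);
there is no removal step. Collinear candidates are skipped with a warning.
Because a signed correlation is the natural summary of a single-driver
model, the result reports the multiple r, a signed r (slope sign × multiple
r when exactly one predictor is selected) and the partial r of every
selected predictor — the last two can differ in multi-predictor models and
both are emitted. Prewhitening estimates φ as the biased lag-1 sample
autocorrelation and returns x_t − φ·x_{t−1} with the mean restored
(length n − 1); only first-order structure is removed, which suffices for
growth chronologies whose persistence is predominantly AR(1). The
prewhitened regression is a deliberately conservative re-test: it removes
genuine decadal covariance along with the nuisance autocorrelation.

## Synthetic-data generator

The generator emulates: a monthly driver (mean 16, annual/semi-annual
harmonic amplitudes 4 and 1 — an SST-like seasonal cycle — plus a
stationary AR(1) anomaly with φ = 0.5 and innovation SD 0.6); 30 shells
aged uniformly 35–72 yr, collected over two adjacent campaigns, with the
margin increment dated to the growth year preceding collection and the
first two increments unmeasured (juvenile bands lack clear boundaries);
growth parameters a = 2 mm, b = 0.08 /yr, k = 0.3 mm giving mature
increments of a few tenths of a millimetre; log-growth sensitivity
β = 0.5 per unit of growth-year anomaly and individual noise σ = 0.2.
With φ = 0.5 and innovation SD 0.6 the October–September mean anomaly has
SD ≈ 0.33, so the implied pairwise index correlation is ≈ 0.4 and the
leave-one-out interseries correlation lands in the low 0.6s — the range
reported for well-replicated bivalve chronologies — which is how the two
free environmental parameters were fixed. Randomness is counter-based
(per-shell substreams keyed by shell index), so enlarging a population
never changes existing shells and identical configurations are
bit-identical.

What the generator does **not** emulate: growth-rate heterogeneity between
individuals (all shells share one age curve), age-dependent noise,
missing or locally absent increments other than the systematic juvenile
gap, non-AR(1) climate persistence, and measurement error. Passing tests
therefore demonstrate that the pipeline recovers a known signal under its
own model assumptions — they do not certify performance on real shells,
where detrending model error and dating uncertainty interact.

## Problem sizes and numerical conventions

Monte-Carlo experiments in the test suite use 200 fixed-seed replicates of
the 30-shell, ~60-growth-year scenario (signal recovery, dating-error
detection, stepwise behavior) and 400-replicate ensembles for the EPS
variance-ratio check; the acceptance script defaults to 100 replicates
for the pipeline experiments. The truncation fixture is deterministic by
construction: twelve series (four from 1954, eight from 1973) share a
unit-variance signal from 1979 onward while pre-1979 years hold large
anticorrelated-group values, so any 30-yr window touching them has
r̄ ≈ −0.07 and undefined EPS, and the truncation year is 1979 for every
seed. Degenerate inputs are handled explicitly: constant series default
the power exponent to 1 with a warning, zero-MAD years fall back to the
median, zero rank variance makes Spearman undefined rather than raising,
and an AR(1) estimate outside (−1, 1) is clipped to ±0.99 with a warning.

## Known limitations

* The spline's closed-form response describes interior points of long
  unit-spaced series; short series (< ~3 cutoffs) are dominated by edge
  effects.
* EPS assumes exchangeable series with a common signal fraction; strongly
  heterogeneous populations violate it.
* The stepwise procedure inherits the usual selection-inference caveats:
  entry p-values are not valid post-selection inference.
* The ADT index consumes pre-averaged box series; no gridded fields are
  read.
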