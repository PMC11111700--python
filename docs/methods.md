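# Methods

## The model

The framework treats a daily vegetation-index record as a smooth seasonal
trajectory observed through a destructive channel: days are missing at
random (orbit, swath, processing), depressed multiplicatively (clouds and
aerosol lower NDVI), occasionally spiked upward, and sometimes absent for
whole months (instrument hand-overs). Reconstruction therefore has two
jobs that are usually done separately: deciding *which* observations to
trust, and filling everything else.

### Valid-data identification

Screening is anchored on monthly maxima, on the premise that the maximum
of a month is the least cloud-affected observation in it (the same
premise as maximum-value compositing).

**Day level.** For a target month, the reference set `V_max` holds the
monthly maxima of the previous, target and next months plus the two
pairwise means (previous,target) and (target,next) — five numbers when
the window is complete, fewer at record edges or next to empty months.
A day is valid when its absolute percent bias against **at least one**
reference is within `T1`. The "at least one" reading is deliberate: early
days of a month sit near the previous month's level, late days near the
next month's, and requiring closeness to *all* references would reject
nearly everything in any fast transition. A configuration switch
(`require_all_refs`) exposes the strict reading for comparison.

**Month level.** A month is invalidated wholesale when it has no data, or
when the percent bias between its maximum and the mean maximum of the
same calendar month in the adjacent four years (two before, two after,
truncated at record edges; test skipped when no neighbor exists) exceeds
`T2`. All non-missing days of an invalidated month become invalid.
Whether this test should use raw monthly maxima or only the day-level
survivors turns out to be a non-question: the month's maximum day always
survives the day screen, because its percent bias against the
target-month-max reference — itself — is zero. Both readings give
identical masks; the implementation uses the raw maxima.

**Thresholds.** `T1 = 20%` and `T2 = 39%` by default. The calibration
procedure that motivates them is implemented in `calibrate_thresholds`:
over a multi-year monthly-maximum reference, `T1` is estimated as the
mean absolute percent bias between adjacent months' maxima, and `T2` as
the mean over pixels of each pixel's *maximum* adjacent-month percent
bias. On the long real-world monthly record these statistics come out
near 20% and 39%; on other references they measure how fast the
vegetation signal moves month-to-month, which is what the screen must
tolerate.

### Segmented quartic reconstruction

Greenness curves rise and fall asymmetrically, so each pixel-year is
fitted in two pieces split at the **peak day** — the date of the year's
maximum valid value (ties broken to the earliest date). The growth
segment pools valid data from October 1 of the previous year through the
peak; the withering segment from the day after the peak through March 31
of the following year. Each segment gets an ordinary least-squares
degree-4 polynomial. The fitted curves are evaluated on every calendar
day (growth up to and including the peak, withering after), clamped to
the physical range [−1, 1], and **replace** originally valid
observations; keeping the observations is available as an off-by-default
option (`keep_observations`). No continuity is enforced where the two
polynomials meet; the jump magnitude is reported per run (typically below
0.1 NDVI on the synthetic scenes).

A segment with fewer than `min_points = 10` valid observations (or fewer
than five distinct dates) is not fitted — a quartic needs five points to
be identifiable and ten guards against wild extrapolation. Its days, and
whole years with no valid data at all, are filled afterwards with the
mean reconstructed value of the same calendar day in the adjacent four
years (February 29 borrows February 28 from non-leap neighbors). The fill
reads only the pre-fill state, so it is order-independent; a gap with no
neighbor-year value anywhere is a hard error naming the offending
pixel-dates, not a silent hole.

### Evaluation

Per-pixel Pearson *r*, *R*² (one minus the residual sum of squares over
the total sum of squares about the *observation* mean — asymmetric, as is
conventional), MAE, RMSE and percent bias, with pixels under two samples
flagged rather than reported. Self-validation compares the reconstruction
with the original record only on days labeled valid; cross-dataset
comparison uses all co-observed days. Quality rules are pure predicates
on the per-pixel metrics; area proportions are pixel counts on the
regular grid (no cosine-latitude weighting) and latitude bands are grid
rows. Monthly MVC compositing and nearest-neighbour regridding (nearest
cell center per axis, ties to the smaller index) support comparison with
monthly and differently gridded products.

## Tunable parameters

| parameter | default | units | role |
|---|---|---|---|
| `T1` | 20 | % | day-level percent-bias threshold; larger admits more noise, smaller discards fast transitions |
| `T2` | 39 | % | month-level interannual threshold; guards against months whose maximum is itself noise |
| `min_points` | 10 | observations | minimum support for a quartic segment (≥ 5 required) |
| `clamp_range` | [−1, 1] | NDVI | physical range applied to fitted values |
| `neighbor_years` | 4 | years | y±1, y±2 pool for the month screen and the residual fill |
| `keep_observations` | off | — | pass valid observations through instead of fitted values |

Synthetic-scene defaults: winter base 0.15, seasonal amplitude 0.55,
green-up/senescence inflections at days 120/280 with logistic rates
0.10/0.08 d⁻¹ (a temperate mid-latitude seasonal cycle), 3% fractional
interannual jitter on amplitude and inflection dates (≈3.6 d green-up,
≈8.4 d senescence, 1σ); contamination 50% dropout, 20% cloud rate with
depression factors 0.3–0.7, 1% spikes of +0.05–0.30 (clamped at 1), and
one 30-day transition gap.

## What the generator emulates — and what it does not

The generator reproduces the *statistical* structure the method assumes:
smooth unimodal seasonality, negatively biased contamination, missing
runs. It does not simulate spatial cloud correlation, bidirectional
reflectance or orbital-drift artifacts, multi-modal phenology (double
cropping), snow, or sensor calibration drift. Passing recovery tests
therefore demonstrates that the algorithmic chain is correct and
well-conditioned under its own assumptions, not that the method handles
every real-world regime; real-data quality claims require real-data
validation.

## Numerical choices

- Segment time axes are affinely rescaled to [−1, 1] before fitting;
  coefficients are stored with the origin and scale so evaluation at any
  calendar date is exact. The fit itself is `numpy` least squares; the
  test suite checks it against an explicit normal-equations solve.
- Zero-valued references make percent bias undefined and are skipped; a
  day whose references are all zero is classified invalid with a logged
  warning. Zero-reference pairs are likewise excluded (and counted) in
  the PB metric.
- Peak ties break to the earliest date; regridding ties to the smaller
  index; both make the pipeline bit-for-bit deterministic, which the
  tests assert.
- Latitude is held south→north ascending internally; descending files
  are flipped on read. Packed storage is int16 with scale 0.001 and
  sentinel −32768; round trips preserve missingness exactly and values
  to half a quantization step (5×10⁻⁴).
- The quartic-truth generator used for exactness tests produces, per
  pixel, a single downward-opening quartic in *absolute* time, peaked
  mid-record. Truth that is quartic in day-of-year but repeated yearly is
  *not* representable by the method's segment windows (the growth window
  crosses the year boundary, where such truth has a derivative break), so
  absolute-time quartics are the construction under which exact recovery
  is a well-posed claim; the measured recovery error is at machine
  precision (~10⁻¹⁵).

## Known limitations

- **Precision ceiling of max-referenced screening.** A spiked day that
  becomes its month's maximum is invisible to the day screen (its bias
  against the month-max reference is zero by construction). The month
  screen catches such months instead — and by design invalidates every
  clean day in them. On the standard contaminated scene this quarantine,
  plus days falling between reference levels during the steepest
  transitions, holds day-level precision of contamination detection near
  0.68 even though recall is ≈0.88 and the final reconstruction reaches
  median R² ≈ 0.96 against truth. The reconstruction is robust to the
  lost clean days (the fits pool across months), but per-day precision
  should not be read as the screen's quality ceiling on smoother records.
- The two segment polynomials are independent, so the reconstruction can
  jump at the peak day; the jump is reported, not removed.
- No uncertainty quantification; the output is a point estimate.
- The adjacent-year fill assumes interannual stationarity at the
  calendar-day scale; in rapidly changing landscapes it biases filled
  values toward the neighboring years' state.

## Problem sizes

The test suite and the acceptance script run on synthetic scenes of 20×20
pixels × 3 years (the standard contaminated scene), 4×4 × 3 years
(exactness checks), and batches of 100 random cubes of up to 3 pixels ×
18 months for oracle agreement; the full suite completes in well under a
minute on one CPU. All randomness is seeded; scenes regenerate bitwise
identically.
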