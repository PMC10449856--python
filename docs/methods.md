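# Methods

`phenoflux` extracts vegetation phenological transition dates (PTDs) from
daily eddy-covariance gross primary productivity (GPP) and analyses their
long-term trends. This note documents the models, the numerical choices, and
what the built-in synthetic generator does and does not emulate.

## Input model

The unit of analysis is a per-site daily series: calendar date, GPP from
night-time partitioning (gC m⁻² d⁻¹), and the fraction of good-quality NEE
half-hours for the day (`NEE_VUT_REF_QC` in the FLUXNET FULLSET daily
dialect, −9999 as missing sentinel). Because GPP is modelled from NEE, GPP
quality is inferred from the NEE quality flag. A day is *good* when its
quality fraction reaches the per-day cutoff (default 0.8 — the archive does
not prescribe one, so it is exposed as a parameter); a year is *usable* when
strictly more than 70% of its days are good (366-day denominator in leap
years); a site enters trend analysis with strictly more than 10 usable
years.

## Integral smoothing

Daily GPP is noisy; phenology extraction needs a smooth annual curve. Direct
smoothing fits the raw values of one padded calendar year with either a
least-squares cubic regression spline (`knots` interior knots at equally
spaced quantiles of the day axis) or LOWESS. *Integral smoothing* instead:

1. pads the focal year with the last 30 days of the preceding and the first
   30 days of the following calendar year (first/last year of record: the
   same year's own last/first 30 days stand in);
2. accumulates daily GPP into its running sum (missing days contribute a
   zero increment, keeping the cumulative monotone — a flat step marks the
   gap);
3. fits a regression spline to the cumulative curve;
4. differentiates the fitted spline analytically and evaluates it on the
   focal year's daily grid, discarding the pad.

The cumulative sum has a far higher signal-to-noise ratio than the daily
series, which makes the fit robust to the one tunable parameter, the knot
count (default 10; counts below 6 are refused without an explicit override
because they over-smooth).

Two numerical choices matter:

* **The cumulative curve is fit with a quintic (k=5) spline; direct
  smoothing stays cubic.** Differentiation drops one polynomial order: with
  a cubic fit the derived GPP curve is a C¹ piecewise quadratic whose
  knot-to-knot ringing is larger than the direct cubic fit's own error —
  measurably *more* knot-sensitive, defeating the method's purpose. With a
  quintic fit the derived curve is a C³ quartic spline; on noise-free
  synthetic years the maximum smoothing error drops from ≈5% to ≈1% of the
  seasonal amplitude, and the across-knot variability of integral smoothing
  falls below that of direct smoothing (see knot sensitivity below).
* **The derivative is taken from the spline coefficients**, never by finite
  differences of fitted values, so no discretization noise is reintroduced.

Knot sensitivity is quantified by re-smoothing a year at every knot count in
5–18, taking the per-day standard deviation across counts (ddof 1), and
averaging over days and years: `sigma_dir` for the direct family,
`sigma_int` for the integral family. On noisy synthetic grassland-like years
the median of `sigma_dir − sigma_int` is positive — integral smoothing is
the steadier method — though sites with very sharp, narrow seasonal towers
(crop-like shapes whose transitions are faster than the knot resolution) can
invert the ordering; this is a documented limitation, not a target of the
test suite.

**Validity domain.** A spline with `K` interior knots over a 425-day padded
window resolves features no narrower than roughly `425/(K+1)` ≈ 39 days at
the default `K=10`. Green-up or senescence transitions faster than that are
systematically broadened, which biases low-threshold crossings outward and,
when the season geometry drifts over years, leaks into trend estimates. The
synthetic defaults (below) are chosen inside this domain.

## Phenological transition dates

**Threshold method.** The smoothed focal year is min-max normalized to
[0, 1] (focal year only, never the pad). For a threshold *f*, the start of
season (SOS) is the upward crossing of *f* nearest to and before the
seasonal peak; the end of season (EOS) is the downward crossing nearest to
and after it; growing-season length GSL = EOS − SOS. The default grid is
0.10–0.70 in steps of 0.05 (13 thresholds). Crossings are located at
fractional days by linear interpolation between the bracketing days —
integer-day quantization would corrupt decadal trends of a few days per
decade — with an integer-day mode available.

**Multi-season years.** Growing seasons are maximal runs of normalized GPP
above a floor (default 0.2); the run with the largest integral of smoothed
GPP governs, ties going to the earliest run, so every year yields exactly
one SOS and one EOS assigned to the most productive season.

**Cross-year seasons.** When the curve is already above the threshold at the
year boundary (southern-hemisphere sites whose season straddles New Year),
the search continues into the neighbouring year's own normalized curve and
reports a signed day coordinate relative to Jan 1 of the focal year: SOS ≤ 0
lies in the previous year, EOS > days-in-year in the next. Search depth is
one neighbour; beyond that the (year, threshold) cell records a no-season
error. Min-max normalization is per calendar year, so the neighbour's curve
is normalized within its own year — adequate when year-to-year amplitude
changes are modest.

**Derivative method.** SOS/EOS are the days of the maximum/minimum of the
first derivative of the smoothed curve (analytic, from the spline), searched
on the governing season's rise and fall. For logistic-like cycles these
extrema sit at the inflection days, close to the 0.5-and-higher threshold
dates. Curves with near-constant derivative on a flank make the extrema
ill-defined; such results are boundary artefacts.

## Trends

Per site, metric (SOS, EOS, GSL) and threshold (plus the derivative tag),
the trend over years is the Theil-Sen estimator: the median of all pairwise
slopes (y_j − y_i)/(t_j − t_i), with t the calendar year, so series with
missing years remain valid. Even pair counts take the midpoint of the two
central slopes. Confidence intervals use Sen's rank-based procedure (order
statistics of the enumerated pairwise slopes at ranks set by the normal
approximation of the Mann-Kendall variance with tie correction, via
`scipy.stats.theilslopes`); p-values are two-sided Mann-Kendall with tie and
continuity corrections (implemented in-package; cross-checked against
`scipy.stats.kendalltau`). Slopes are reported per year and ×10 per decade.

**GSL trends are the trend of the per-year difference EOS − SOS computed
over common years** — not the difference of the two trends. The median of
pairwise slopes is not additive, and the two definitions genuinely diverge
on nonlinear series; the test suite carries a discriminating fixture.

**Threshold-uncertainty classification.** A site's metric is flagged
*uncertain* when the sample standard deviation (ddof 1) of its per-threshold
slopes, in days/decade, strictly exceeds a cutoff: 0.5 for SOS and EOS, 1.0
for GSL. The derivative-method trend is reported alongside but excluded from
the spread, which is defined across thresholds. A bootstrap that resamples
whole years with replacement (preserving the within-year threshold
structure; B = 1000, seeded) yields a percentile confidence interval for the
spread. The point estimate gates the flag; the interval is reported.

## Weekly GPP trends and coupling

Weeks are redefined from the first day of the year — week *w* covers DOY
7(w−1)+1…7w — so the same days of year are pooled every year. DOY 365 and
the leap day are excluded (52 weeks of exactly 7 days; equal support). For
each week, all (year, daily GPP) observations of its member days are pooled
(≈7× the number of years) and regressed on year by OLS; significance is the
two-sided t-test at α = 0.05. Weeks observed in fewer than 3 years are
reported with a reason instead of a slope.

Coupling analyses run across sites, per threshold and for the derivative
method:

* **SOS/EOS coupling** — x: the site's PTD trend (days/decade); y: the
  *mean* of its weekly GPP slopes over weeks intersecting ±2 weeks around
  the site's across-year mean PTD at that threshold. OLS of y on x gives the
  sensitivity (slope) and its strength (R²). The window aggregate is the
  mean rather than the sum so y does not scale with how many weeks the
  window happens to intersect; a `sum` mode is available.
* **GSL coupling** — y is the *sum* of weekly slopes over the weeks between
  mean SOS and mean EOS (partially covered weeks included), i.e. the trend
  of seasonal productivity; x is the GSL trend.

## Synthetic generator

The generator is the test bed: multi-year daily GPP with known phenology.

* **Seasonal shape**: difference of two rising logistics,
  `bump(t) = L(k_sos (t − t_sos)) − L(k_eos (t − t_eos))`, rescaled each year
  so the daily-grid maximum equals baseline + amplitude exactly. Inflections
  and half-heights are analytic, so `true_ptd` inverts one branch in closed
  form and serves as an exact oracle (at half height the crossing *is* the
  inflection day).
* **Defaults** (chosen once, for a generic broad temperate site): amplitude
  8 gC m⁻² d⁻¹ over a 0.5 baseline, inflections DOY 120/280, logistic slopes
  0.06 d⁻¹ (10–90% green-up in ≈73 days). The slope default keeps the
  transitions wider than the default 10-knot smoothing resolution, inside
  the method's validity domain; tests that need tight closed-form/scan
  agreement use steeper branches (0.12–0.15 d⁻¹), where the branch-inversion
  oracle and the full curve agree to <0.01 day.
* **Trends**: inflection days and amplitude shift linearly per year;
  individual calendar weeks can carry additive GPP trends
  (week-index → gC m⁻² d⁻¹ yr⁻¹) to emulate localized productivity change.
* **Noise**: Gaussian, heteroscedastic — sd = max(frac · signal,
  0.05 · amplitude). The floor keeps the dormant season noisy, as
  partitioned GPP is in real archives; `frac = 0` means strictly noise-free.
  A `gap_frac` of days is flagged poor-quality (quality 0, GPP missing).
* **Southern hemisphere**: a circular phase shift of the DOY axis (period
  365), with the bump evaluated at its ±1-period images so a season centred
  on the year boundary contributes tails to both calendar edges. Seasons
  whose support exceeds 366 days are rejected when phase-shifted (they would
  overlap their own wrap image).
* **Bimodal years**: an optional second season with a strictly smaller
  integral, so the most productive season is unambiguous.

**What the generator does not emulate**: weather-driven autocorrelated
variability, disturbance events (cuts, harvests, drought collapse),
partitioning artefacts with heavy tails, instrument outages in multi-day
blocks, and any NEE/radiation physics. Passing recovery tests therefore
demonstrates correctness of the algorithms under idealized noise, not
performance on every real-world pathology; the robustness claims that
matter for real data (outlier resistance of Theil-Sen, gap handling in the
cumulative) are tested separately with adversarial fixtures.

## Degenerate inputs and tie-breaks

* Flat smoothed years (max = min) and years with no season above the floor
  raise explicit degenerate-year errors; whole-series extraction records
  them per year in an `issues` column and continues.
* Thresholds never crossed in the focal or neighbouring year raise a
  no-season error for that cell only.
* Equal-integral seasons: earliest run governs. Even pairwise-slope counts:
  midpoint. Uncertainty flag with fewer than two valid per-threshold trends:
  undefined, with a reason.
* Years present but fully missing quality default to 0 good days.

## Problem sizes in the shipped checks

The bundled verification runs use 100 replicates for ensemble statements
(trend recovery, knot sensitivity), 20-year series where decadal trends are
estimated, 500 random series for the estimator-vs-enumeration check, and
3-year series where a single smoothed year suffices. These sizes give
stable medians and percentages while keeping the full run in the
single-digit minutes on one CPU.

## Known limitations

* The knot-sensitivity ordering (integral steadier than direct) holds for
  broad-to-moderate seasonal shapes; very sharp narrow towers can invert it.
* Normalizing each year independently makes cross-year coordinates slightly
  inconsistent when amplitude trends are strong.
* The derivative method inherits smoothing bias directly; it is reported
  alongside threshold results, not used for the uncertainty spread.
* LOWESS has no analytic derivative; its derivative-method PTDs use a
  numerical gradient.
* The weekly significance test treats pooled daily observations as
  independent; within-week autocorrelation in real data would make it
  anticonservative.
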