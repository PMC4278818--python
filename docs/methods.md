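# Methods

This note records the models, conventions and numerical choices behind
`modisbatch`, and what its synthetic tests do and do not demonstrate about
real MODIS data.

## Grid model and tile arithmetic

The MODIS land grid is a sinusoidal projection of a sphere of radius
R = 6371007.181 m: x = R·λ·cos(φ), y = R·φ (radians). The inverse is exact
away from the poles; round trips recover coordinates to better than 1e−9°.
Cell sizes are the exact grid constants per resolution class —
231.656358 m (250 m class), 463.312717 m (500 m), 926.625433 m (1 km) —
so 4800 cells of the 250 m class tile one 10° grid tile exactly.

Tile sizes are requested as whole kilometres north/south and east/west of
the focal pixel and converted to pixel counts with **nominal** resolution
and integer division: pixels per dimension = 2·(1000·km div res) + 1.
This reproduces the service's published arithmetic — size (1,1) at 250 m
is a 9×9 = 81-pixel tile, size (3,3) a 25×25 tile with a 6.25 km nominal
edge — even though the actual ground extent of 9 cells is ≈2.08 km. Both
dimensions are always odd, keeping the focal pixel centred. Sizes above
(100,100) are rejected, matching the service's maximum area of interest.

The focal pixel is snapped to the global pixel grid anchored at the
south-west corner of the sinusoidal plane, (−πR, −πR/2). This choice is a
convention: the original service's snapping rule is not documented, so the
package asserts only sub-pixel agreement (within one cell) with published
corner coordinates. Empirically, this anchoring reproduces the documented
worked-example tile corner to under a metre.

## ASCII subset dialect

Subset files are comma-separated and header-less; each row carries ten
header fields (tile rows, tile columns, lower-left x and y in sinusoidal
metres, pixel size, granule identifier, product code, A[YYYYDDD] date
code, a `Lat…Lon…Samp…Line…` location tag, and the processing stamp)
followed by Samp·Line row-major pixel values, north-west pixel first.
Stored values are integers in product units. Date codes use the proleptic
Gregorian calendar (day-of-year 1–366, validated against leap years); no
time zones — dates only.

Numeric formatting is a documented convention chosen for byte-stable round
trips: cell size at 4 decimals, corner coordinates in fixed notation with
up to 6 decimals (integers written without a decimal point), coordinates
in the location tag with up to 10 decimals, trailing zeros trimmed,
never scientific notation. `parse ∘ write` is the identity on records and
`write ∘ parse` is the identity on canonical files.

One file holds one site/product pair (`<site>__<product>.asc`, all bands
interleaved, sorted by band then date). Site tables must carry `lat`,
`long`, `end.date` and optionally `start.date`/`ID`; year-only end dates
resolve to December 31, year-only start dates to January 1, and an absent
start date opens the window on January 1 of (end year −
time_series_length). Generated IDs are `Site<k>__<lat>_<long>` with
coordinates at six decimals, collision-checked.

## Acquisition

Transport is an injectable `SubsetSource` contract; the shipped
implementation reads local fixture archives (the historical SOAP service
is not revived; a skeletal HTTP adapter marks the extension point).
Each unique (site, product, bands, size, window) request is fetched
sequentially — duplicates are collapsed with a log notice — and retried on
transient failures within a per-subset window of 15 minutes, pausing 30 s
between attempts (the pause is a convention; only the window is a
documented service behaviour). Subsets the first pass could not fetch get
a second pass under the same policy before being marked `Failed`. The log
holds exactly one row per unique request with status
`Success`/`Retried-Success`/`Failed`/`Cached` and the attempt count;
`Cached` marks subsets skipped because a complete, parseable file already
covered the request, which makes re-running a completed download a no-op
that leaves files byte-identical. Clocks are injectable, so the retry
protocol is tested in simulated time.

## Quality screening

A stored value survives screening iff it is not the band's no-data fill,
lies inside the band's valid range (checked in stored units, bounds
inclusive), and — when the reliability screen is on — a reliability record
exists for that date with rank ≤ the threshold (default 0; ranks strictly
above the threshold are omitted). A date with no reliability record is
masked: the conservative reading of screening out "poor-quality and
missing" data. Survivors are scaled by the band's scale factor; masked
entries are NaN and are never scaled. Screening is monotone in the
threshold: lowering it never un-masks a value. Only the integer
pixel-reliability band is interpreted; bit-field QA words are out of
scope.

## Interpolation and summaries

Gaps are filled by piecewise-linear interpolation in calendar days;
leading/trailing gaps take the nearest valid value (constant extension
rather than extrapolation, keeping the interpolant inside the observed
range so max/min over observations are preserved). At least two valid
observations are required; otherwise summaries are missing-marked (a
single observation still defines max = min).

* `max`, `min`: extremes over valid observations (interpolation cannot
  change them).
* `mean`: the trapezoid-weighted temporal mean of the interpolated series,
  AUC/(tₙ−t₁). The time-average is used rather than the arithmetic sample
  mean so that (a) `variability = mean − min` holds exactly and (b) a
  seasonal cycle sampled over whole periods is estimated without the
  endpoint double-count an arithmetic mean incurs. Without interpolation
  the mean falls back to the arithmetic mean of valid observations.
* `variability` ("yield"): V = [AUC(v) − min(v)·(tₙ−t₁)]/(tₙ−t₁), the
  time-averaged area between the series and its minimum, normalised by the
  spanned time so it is shift-invariant, scales linearly with amplitude,
  and is expressed in band units. Normalising by spanned time (rather
  than by the composite count) is the literal reading of a time-averaged
  area; it makes V = A exact for whole-period sinusoids.

Site-level values aggregate per-pixel statistics as their unweighted mean
across the tile (the alternative — summarising the pixel-mean series — is
a documented option, `aggregate_sites(how=…)` being the seam). Merging
preserves the user table's row count and order, appends one
`<band>__<stat>` column per statistic, and missing-marks sites without
data; statistics for a site absent from the table are an error.

## Synthetic scenes and what the tests show

The generator emulates 16-day composite series: a seasonal sinusoid
v(t) = offset − amplitude·cos(2π(t − phase)/period) in physical units,
quantized to stored integers (error ≤ scale/2 = 5e−5 NDVI), plus Gaussian
observation noise, random fill values, and random bad-reliability
composites shared between the NDVI and EVI bands of a date. Defaults are
the package's reference conditions: 3 years of composites (n = 69),
period 368 days (23 composites), offset 0.55 and amplitude 0.25 (typical
temperate broadleaf NDVI), noise 0.015 (mid-range for good-quality 16-day
VI composites), and ≈19% data loss (5% fill + 15% bad reliability). The
date grid is uniform at the composite interval (the real product resets
day-of-year each year, giving one short interval; this is immaterial to
the statistics and not simulated). The phase aligns a composite with the
seasonal trough, so the sampled minimum is exact while the crest can be
missed by up to half an interval — visible in the sampled `true_max`.
There is no spatial autocorrelation and no radiometric realism: passing
tests demonstrate the pipeline's arithmetic and contracts, not geophysical
fidelity.

Recovery behaviour, established by simulation and asserted in the tests:

* Noise-free, whole-period scenes: recovered variability equals the
  amplitude to within quantization (≤1e−4).
* With noise σ = 0.015 and 20% masking at 69 composites: the temporal-mean
  estimator is unbiased (average error across 100 seeds well inside
  3σ/√n ≈ 0.0054) and ~95% of individual seeds fall inside that bound.
  Individual seeds can exceed it: when a masked run touches the series
  boundary, constant extension gives a single noisy observation a large
  trapezoid weight, fattening the error tail — an estimator property, not
  a bug, so the per-seed check allows a 10% tail.
* Recovered variability carries a positive bias of ≈1σ from the noisy
  sampled minimum (min of ~10 near-trough samples under noise); at
  σ = 0.015 the across-seed average sits ≈6% above the noise-free value,
  inside the 10% band the tests assert. Larger noise-to-amplitude ratios
  would widen this bias proportionally.

## Numerical and degenerate-input choices

* Variability and temporal means use `numpy.trapezoid` on actual date
  offsets; an independent midpoint-Riemann oracle at Δt = 0.01 day agrees
  to 1e−6 on composite-spaced series.
* Coordinate parsing accepts DMS and degrees-decimal-minutes, hemisphere
  letters or signs; both present and conflicting is an error, not a
  preference. Minutes/seconds must lie in [0, 60).
* Empty record lists write empty files; empty collations return empty
  frames; all-masked series produce missing-marked summaries with
  `n_valid = 0` rather than errors.
* ESRI grids write the six header keywords in canonical order, integers
  without decimal points, and a `.prj` sidecar with the sinusoidal
  sphere's well-known text; integer grids round-trip losslessly. Grids
  default to stored units with the band fill as NODATA (what GIS users
  expect of MODIS dumps); scaled export is a flag.
* Problem sizes in the test suite and acceptance script (tiles up to 9×9,
  up to 100 seeds × 69 composites, 4-site batches) are chosen to exercise
  every contract at desk scale while the statistical assertions above
  remain well-powered.

## Known limitations

* Only the fixture transport is wired; reviving a live subset service
  means implementing one `fetch` method against the documented contract.
* Catalogue entries beyond MOD13Q1 (and an illustrative MOD11A2) are
  optional extras; constants for other products must be added to the YAML
  catalogue before use.
* No HDF tile reading, no reprojection or mosaicking, no bit-field QA
  parsing, no Fourier/PCA/bioclim summaries — the summary set is the
  max/mean/min/variability family described above.
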