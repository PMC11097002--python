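# Methods

This note documents the models and procedures `weedclim` implements,
the defaults it ships, the design choices that were genuinely open, and
what the synthetic validation world does and does not establish.

## Data model

Occurrence records carry species, decimal coordinates, observation year
and month, and (after enrichment) elevation. Environmental variables
live on regular lon/lat grids with a contiguous monthly time axis:
land-surface temperature (LST, °C), root-zone soil moisture expressed
as a wetness percentile (RZSM, 0–100, the drought-indicator convention
of gravimetric soil-moisture products), static elevation (m), and
static per-crop harvested-area layers for two census epochs.

Point extraction is nearest-cell with ties broken toward the lower
index, and never extrapolates: points outside a grid's bounding box or
time coverage yield missing values. No interpolation is performed —
values are read off coarse rasters as-is, because interpolating between
cells of a 0.05°-class product would manufacture precision the data do
not have. Scaled Kelvin inputs decode as `(dn·scale + offset) − 273.15`.

### Cleaning

Each raw row receives exactly one fate, in fixed precedence: missing
species → defective coordinates (missing, out of range, or exactly
(0,0), the canonical junk coordinate in biodiversity databases; no
uncertainty-radius heuristic is applied, and the rule is echoed in the
report) → unusable date (lag arithmetic needs a month) → duplicate of
an earlier row on (species, lon, lat, year, month), first kept. The
report therefore always reconciles: retained + Σdrops = input. Records
missing only elevation are kept; elevation is enriched from the grid.

### Lags, climatology and completeness

Lag k of an observation in month (y, m) is the calendar month k months
earlier, correct across year boundaries. Lagged LST values are also
ranked against their cell's climatology using the ≤ convention
(100·#{ref ≤ x}/#ref), which makes "≥ 70th percentile" thresholds
inclusive and ranks a value equal to the reference maximum at 100. The
default climatology pools **all** months of the cell's record, matching
the percentile convention of the moisture product the temperature is
coupled to; a same-calendar-month variant is available via
`enrich(..., climatology="calendar")`.

Completeness is tracked per analysis: a record missing a moisture lag
leaves the moisture and coupling analyses but stays in the temperature
analysis. Each downstream stage excludes exactly its own incomplete
records.

## Heat-moisture coupling

A coupling event at one location-month is `LST ≥ 25 °C AND RZSM ≥ 70`,
inclusive at both boundaries — 25 °C is the lower edge of the optimal
witchweed preconditioning band, and the 70th moisture percentile marks
the upper, "wet soil" tercile. An occurrence is coupled when any
configured lag (default {0, 1, 2}) has an event, with both variables
from the *same* month. Missing-value semantics are conservative: a true
lag decides the record regardless of other lags; otherwise any missing
lag makes the record undecidable, and undecidable records are excluded
from (not counted against) the per-species association percentages.
Thresholds and the lag set are configuration, echoed in every output.

For per-location *monthly* series the indicator is the plain month-by-
month conjunction (defined only where both constituents are present);
the lag window belongs to the occurrence-linked analysis alone.

## Statistical machinery

**Mann-Kendall.** S = Σ_{i<j} sign(x_j − x_i); tie-corrected variance
[n(n−1)(2n+5) − Σ_t t(t−1)(2t+5)]/18 over tie groups; tie-corrected
τ = S/√(D(D−T)) with a tie-free time axis; ±1 continuity correction;
two-sided normal p. The normal approximation is used at all n (the
monthly series this test targets run ≥ 100 points); an all-equal series
degenerates to τ = 0, p = 1. No seasonal variant and no
multiple-testing correction across locations or species are applied.

**Logistic trends.** Two-parameter maximum likelihood via
Newton/IRLS on *centred* time (tolerance 1e-8, cap 25 iterations);
centring only changes the intercept, and the reported slope is per
original time unit (invariance is tested to 1e-6). Wald z = β̂/SE with
a two-sided normal p. Complete or quasi-complete separation — a
response pattern perfectly ordered by time, under which the MLE
diverges — is detected as a degenerate (constant) response or a capped
fit with |slope| > 15 or SE > 100, and is *flagged while the last
iterate is reported*, mirroring how standard GLM software prints a huge
estimate and SE rather than failing; flagged fits propagate their flag
into odds summaries and are classified "none" in trend classification.
Odds summaries: total odds ratio e^{β(t₁−t₀)} and the fitted
probability change over the span.

**ANOVA, Tukey HSD, compact letters.** One-way F on the group means;
all-pairs comparisons via the studentized-range distribution
(`scipy.stats.studentized_range`, which reproduces the published
q(k=3, df=27, α=.05) = 3.506 to table precision) with the Tukey-Kramer
half-sample SE for unequal n. Letters come from the insert-and-absorb
algorithm, ordered by descending group mean for stable output: two
groups share a letter iff their HSD comparison is non-significant. All
groups identical and variance-free yields F = 0 and a single shared
letter.

**PCA.** Columns standardized (ddof = 1), SVD decomposition, per-
component sign fixed so the largest-|loading| entry is positive; biplot
arrows are loading·√eigenvalue. Zero-variance columns fail by name;
rows with missing values are dropped (minimum 3 complete rows).

## Trend analyses and thresholds

The montane benchmark is 1000 m. Deliberately, two readings coexist,
as per-analysis explicit defaults rather than a silent unification: the
occurrence-trend analysis uses the *strict* reading (> 1000 m), the
host-crop analysis the *inclusive* one (≥ 1000 m). Both appear in
output metadata. The significance gate for classifying a location's
coupling-frequency trend as increase/decrease is α = 0.05, matching the
convention used everywhere else in the pipeline. Location series are
compiled at the deduplicated grid cells of a species' observations and
require ≥ 24 months of (decidable) data. Windowed PCA restricts the
enriched records of one species to an inclusive year range and runs the
standardized PCA on (elevation, lag-1 LST, lag-1 RZSM).

Host presence is a conservative binary: any host crop with harvested
area strictly > 0 at the nearest cell; no area threshold or density
comparison, because the two crop-census products are not quantitatively
comparable. Millet is one layer. Both epochs are evaluated on the same
occurrence set.

## Synthetic world

The generator emulates the statistical structure of the study system,
not its physics: no sensor effects, cloud masking, coastlines or
reprojection. Defaults (all overridable in `ScenarioConfig`):

* 20×20 cells over 10°×10° in the southern tropics, monthly 2006–2022
  (204 months). One global seed drives three named substreams
  (environment / occurrences / crops), so products regenerate
  independently; identical seeds give bit-identical output.
* Elevation: a smooth surface (80–1750 m) whose montane massif
  (> 1000 m, a few dozen cells) sits at mid-longitude so the static
  west-east wetness gradient contributes no baseline
  elevation-moisture correlation.
* LST: 32 °C sea-level baseline, 6.5 °C/km lapse rate, ±4 °C annual
  sinusoid (phase flipped south of the equator), Gaussian noise
  (SD 1.2 °C), and a planted +0.15 °C/yr warming at the designated
  (montane) cells. RZSM is generated directly on the percentile scale:
  base 55 ± 10 across longitude, noise SD 12, clipped to [0, 100], with
  a planted +1.5 pct/yr wetting at designated cells. Jointly these
  raise the monthly coupling probability at designated cells from
  roughly 0.08 to 0.4 over the span while leaving other cells
  stationary (~0.1) — a detectable but not overwhelming planted signal.
* Species are placed by importance sampling (weighted choice over the
  finite (cell, month) candidate set, bounding runtime) on the product
  of Gaussian niche densities in lag-1 LST, lag-1 RZSM and elevation.
  The elevation weight, with a time-varying centre
  (elev_pref + trend·years), is what realizes the planted altitudinal
  drift — an addition over a pure temperature×moisture niche, since
  without it no elevation trend could be expressed. Niche means span
  30 °C/75 pct (hot-wet witchweed-like) to 21 °C/35 pct (cool-dry
  broomrape-like); these contrasts are sized to produce ≥ 20-point
  coupling-association margins. A niche whose density underflows at
  every candidate fails by species name. 2 % duplicate rows and 2 %
  missing-coordinate rows exercise cleaning; coordinates are jittered
  within the generating cell so nearest-cell extraction maps back.
* Crops: seven layers, 60 % cell coverage with uniform areas, one
  shared baseline copied to both epochs (2000, 2015); withdrawal
  entries zero a named crop above an elevation cutoff in one epoch
  only. The default scenario withdraws beans/peas/lentils above 1000 m
  in 2015, so the legume-host species' montane host presence collapses
  between epochs while its overall presence barely moves.

**What passing on this world shows — and does not.** The tests
demonstrate that the pipeline recovers planted trends, contrasts and
withdrawal patterns under Gaussian noise, iid errors and a regular
grid. Real occurrence data add spatial sampling bias, autocorrelated
environments, observer effects and dataset-shift between crop
censuses; none of these is modelled, so green tests certify the
machinery, not the ecology.

## Numerical and engineering choices

* Grid I/O is NetCDF3 via xarray's scipy engine; occurrence tables,
  summary tables and reports are CSV/JSON with a fixed float format, so
  a rerun with the same seed is byte-identical (tested).
* The run manifest records the config (hashed, excluding the output
  location), package versions and per-stage row counts; counts
  reconcile at every stage (input = survivors + exclusions).
* CLI exit codes: 0 success, 2 configuration error, 3 data error.
* Problem sizes in the default scenario (≈2 300 records, 400 cells,
  204 months) keep a full run and the complete validation suite in the
  tens of seconds on one CPU while leaving every planted effect
  comfortably detectable.

## Known limitations

Plain lon/lat grids only (no reprojection or datum handling); no
spatial autocorrelation modelling, changepoint detection or seasonal
trend adjustment; no GBIF/web retrieval — all inputs are file
contracts; exact small-n Mann-Kendall tables are out of scope; the
compact-letter display is the standard insert-absorb construction and
can, like all CLDs, admit multiple valid letterings (ours is made
deterministic by mean-ordering).
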