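# Methods

## Model

The package prices land-use change in carbon terms. Every ordered transfer
route t → i moves area S_t·a(t,i) (km²) between classes whose *effective*
carbon densities differ by e_i − e_t (g/m²), where e = ρ(1+β) anticipates the
density's own drift over the projection horizon. Because km²·g/m² = 10⁶ g =
1 t, the transfer-in ledger ZR_i, transfer-out ledger ZC_i and their grand
total GTYX are in tons without conversion factors. Total sequestration GTZG
adds GTYX (rescaled to 10⁴ t) to the standing stock Σ S_i·ρ_i/10⁴.

Written as above, each pairwise flow enters ZR of the destination and ZC of
the source with the same sign and magnitude, so Σ ZR = Σ ZC identically and
GTYX = 2·Σ ZR. The reference tables packaged with this code print ZR- and
ZC-row sums that differ, so whatever their authors computed deviates from the
printed equations in an unstated way; this implementation follows the
equations as written and treats the printed per-class values as opaque inputs
(see "Fixture mode" below). The model is attributional, not spatial: flows
are priced at class-mean densities, and no per-cell carbon bookkeeping is
attempted.

### Assumptions

* Transition probabilities estimated over 2000–2020 remain valid for the
  projection years (a stationary Markov assumption at the area level).
* Class-mean carbon densities apply uniformly to all area entering or leaving
  a class.
* Density drift is linear in time over the horizon (β from an OLS slope).
* Classes with no tabulated carbon accounts (construction, ice and snow,
  wasteland) carry ρ = 0 and β = 0 unless overridden — the only defensible
  default when the accounts table records no carbon for them, and
  configurable via `ScenarioConfig`/`CarbonImpactModel` parameters.

## Parameter estimation

**Transition probabilities.** Aligned raster pairs are cross-tabulated over
cells valid in *both* epochs (nodata in either epoch removes the cell: only
co-observed cells carry change information). Probabilities are counts·k/S_i
with S_i taken from the counts themselves, which makes occupied rows sum to 1
to ~1e-15; externally supplied epoch areas are cross-checked against counted
areas (warning beyond 5% relative). The multi-year matrix is the entrywise
mean of the consecutive-pair matrices, with the pair interval configurable
(`TransitionEstimator(interval_years=...)`). Rows for classes absent at the
source epoch are kept as zero rows and flagged (`empty_rows`) rather than
dropped, so matrix algebra downstream keeps a stable shape. Pairs are counted
directly instead of through the 100·from+to encoding sometimes used in
cross-tabulation scripts; the semantics are identical for class codes < 100
and direct counting has no code-range restriction.

**Forecasting (S and ρ at the target year).** Two point forecasters are
averaged:

* *GM(1,1)*, implemented from scratch as the textbook variant: AGO cumulative
  sum x¹, background z¹(k) = ½(x¹(k)+x¹(k−1)) (coefficient fixed at 0.5),
  (a, b) by least squares on x⁰(k) = −a·z¹(k)+b for k = 2..n, initial
  condition x̂¹(1) = x⁰(1), exponential response restored by first
  differencing, with the b-linear limit used for |a| < 1e-12 so constant
  series are an exact fixed point. Requires ≥ 4 strictly positive
  observations.
* *ARIMA*, behind statsmodels. When no order is given, all (p, d, q) ≤
  (2, 2, 2) are fitted and ranked by AICc with a deterministic tie-break
  (smallest p+d+q, then lexicographic); orders that fail to fit are skipped
  in the search but are a hard error when requested explicitly. The
  deterministic trend term is a constant for d = 0, a drift term for d = 1
  (so integrated fits continue a linear trend instead of flattening) and
  nothing for d ≥ 2.

The ensemble value is their arithmetic mean. Series that fluctuate around a
stable level rather than trending — lake, ice-and-snow and wasteland areas,
wetland and lake densities in the packaged study — are projected as their
historical mean instead (`apply_stationary_overrides`); overridden entries
are identical across target years by construction. An override naming a
series absent from the history is an error at the operation level;
`run_scenario` first filters the default override list to the classes the
supplied history actually covers, because a history without a series also
produces no forecast entry to replace.

The packaged projection tables cannot be re-derived exactly from the packaged
accounts: the source states neither its grey-model variant nor its ARIMA
orders, and its two projection tables even disagree on the *direction* of the
wetland trend. The ensemble and override rules, which are stated, are
asserted against the printed tables; re-deriving the component forecasts is a
diagnostic, not a contract.

**β coefficients.** The source multiplies ρ by (1+β) but reports only
absolute annual density increments, so the conversion to a dimensionless β
must be pinned down somewhere: here β = slope × horizon / ρ(reference year),
with the OLS slope over the full history, the horizon the distance from the
last observed year to the target year, and the reference density the observed
value at the reference year (the last observed year by default; the fitted
line value if the reference year is outside the sample). β may instead be
supplied per class (`beta_source="explicit"`), which reproduces alternative
readings. β = 0 when the reference density is 0.

## Fixture mode

The study's per-class ZR/ZC tables were produced with β values that were
never published, so they cannot be recomputed end-to-end.
`ImpactBreakdown.from_components` therefore accepts per-class ZR, ZC and
(optionally) printed subtotals directly and only aggregates. Printed
subtotals occasionally differ from ZR+ZC by 1 t (independent rounding of
unprinted underlying values); when supplied they take precedence in the
aggregation, and a deviation beyond 1 t is rejected as inconsistent input.

## Units and data quality

One convention package-wide: areas km², densities g/m², ZR/ZC/GTYX tons,
stocks and GTZG 10⁴ t. All conversions live in `accounting` (10⁴ t = 10¹⁰ g;
1 km² = 10⁶ m²). Report columns carry unit suffixes (`_km2`, `_gm2`, `_t`,
`_1e4t`).

Fixtures store printed values verbatim; the manifest flags every known
internal inconsistency instead of correcting it:

* the totals table's lake and wetland columns are transposed (the printed
  "wetland" stock equals lake area × lake density);
* the 2021 no-impact components sum to 12233.554, not the printed 12133.5540
  (only the 2022 row is internally consistent);
* five transition-matrix rows print with a deficit (shrub sums to 0.9864,
  wetland to 0.9767, lake/ice/wasteland slightly under 1);
* the ninth column of both impact tables is headed "Wasteland" a second time
  but is wetland;
* ±1 t subtotal rounding as above.

Account tables are validated on read: duplicate (year, class) records and
negative areas are errors; a stored density inconsistent with sequestration ÷
area is a warning with both values, using a rounding-aware tolerance of
0.5 + 0.5·10⁴/area g/m² because integer-rounded sequestration cannot pin the
density of small-area classes tighter than that.

## Raster I/O

Two single-band integer formats: ESRI ASCII grid (plain text, carries cell
size; the text format used for fixtures and round-trip tests) and TIFF via
tifffile, with the cell area taken from resolution tags when present and
required explicitly otherwise. Epoch pairs must share shape and cell size
exactly — no resampling is performed, because silent resampling corrupts
transition counts. Reprojection, mosaicking and classification from imagery
are out of scope.

## Synthetic generators

`generate_markov_rasters` evolves every cell independently by a known
row-stochastic matrix from a seeded initial composition; estimator tests
check recovery within 3 binomial standard errors per entry and error
shrinkage with cell count. `generate_account_series` draws per-class areas
and densities from linear trends plus Gaussian noise and derives
sequestration through the unit identity, so generated tables satisfy the
account invariants by construction; negative draws are clipped to zero with
a warning. Both generators are driven by a single explicit seed and are
bit-reproducible; no global random state is touched. The defaults in
`study_trend_spec` mirror the magnitudes of the packaged accounts (slopes
from their OLS fits, noise of the order of the year-to-year scatter).

What the synthetic data deliberately lacks: spatial autocorrelation (real
land-cover change is clustered; per-cell i.i.d. transitions make the
transition-count sampling error *smaller* than a real map of equal size
would), classification error, and any area/density covariance. Passing
recovery tests therefore validates the estimators' arithmetic and
consistency, not their behaviour under spatially structured noise.

## Numerical choices

* Row-stochasticity tolerance for raster-derived matrices: 1e-9 (they are
  exact to floating-point roundoff by construction).
* GM(1,1) singular normal equations (degenerate series) are a hard error;
  the a → 0 limit switches at |a| < 1e-12.
* Matrix CSVs are written with `%.17g` and read with round-trip float
  parsing, so CLI output equals in-process results bit-for-bit.
* Route classification breaks ties exactly: a route is neutral only when the
  effective densities are equal.
* `total_with_impact` warns (heuristically, never errors) when the impact
  term is smaller than 10⁻³ of the stock, the signature of a value already
  divided by 10⁴.

## Problem sizes

Test rasters are 30×30 to 300×300 cells (9·10² to 9·10⁴ cells), enough to
hold the 3-standard-error recovery bounds with wide margin; the slope-bias
check uses 200 Monte-Carlo replicates of 21-year series. The full scenario
pipeline on the packaged nine-class history (12 series × 27 candidate ARIMA
orders) runs in well under a minute; tests that exercise the pipeline pin
ARIMA orders to keep the suite fast.

## Known limitations

* Flows are priced at class-mean densities; heterogeneous within-class
  density (e.g. altitude gradients) is invisible to the model.
* The literal transfer equations force Σ ZR = Σ ZC; the reference tables'
  asymmetric row sums cannot be reproduced and are not reverse-engineered.
* Point forecasts only — no prediction intervals, seasonal terms, exogenous
  regressors or GM(1,N).
* The β convention (relative growth anchored at the last observed density)
  is one defensible reading of an under-specified quantity; explicit β
  injection exists precisely so other readings can be tested.
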