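# Methods

## Model overview

`nutrigrid` implements a bottom-up nutrient-discharge inventory in three
stages.

**Accounting.** Annual provincial discharge of TN and TP is computed per
sector from activity data times per-unit coefficients. The model's core
assumption is linearity: discharge scales with population, headcount,
sown area or wastewater volume, attenuated multiplicatively by the
treatment, reuse and retention pathways. Canonical units are tonnes per
year for mass, litres per person per day for water use (with a fixed
365-day year), mg/L for concentrations and kg per capita (or per head,
per hectare) per year for generation coefficients; the L·mg → t
conversion factor is 10⁻⁹. One declared unit system with explicit
converters guards against silent thousand-fold errors, since source
statistics mix all of these.

**Spatial allocation.** Each provincial sector total is distributed over
the cells of that province in proportion to non-negative surrogate
weights (dasymetric downscaling). Residential and industrial discharge
follow calibrated population on the sector's eligible land-use classes
(urban land for urban and industrial sources, rural residential land for
rural sources, other construction land additionally for industry);
agricultural discharge follows the product of slope-grade and
clay-grade nutrient-loss coefficients on cultivated land. Weights are
renormalized to sum to one within every province, which makes mass
conservation a structural property rather than a numerical aspiration:
the only error left is floating-point rounding, and the validation
tolerance of 10⁻⁹ relative sits about seven orders of magnitude above
observed round-off.

**Temporal allocation.** Annual grids are split into twelve months by
per-cell profiles: the temperature-modulated residential water-use
curve, rainfall × crop-calendar weights for crop farming, plain rainfall
shares for livestock (the flushing effect of precipitation), and a
uniform 1/12 for industry, which shows no meaningful seasonality.

## Parameters that matter

| parameter | units | default | notes |
|---|---|---|---|
| amplitude R | – | 0.2 | relative difference in residential water use between the warmest and coldest months; the adopted national-assessment value |
| slope loss grades | – | 0.10 / 0.20 / 0.35 / 0.50 | slope classes [0,8), [8,15), [15,25), ≥25 % |
| clay loss grades | – | 0.75 / 0.50 / 0.25 / 0.10 | clay classes [0,18), [18,35), [35,60), ≥60 % |
| conservation tolerance | relative | 10⁻⁹ | applied to every spatial and temporal mass-balance check |
| share-sum tolerance | absolute | 10⁻⁶ | for fractions from rounded statistical tables (e.g. dry + flush toilet shares = 1) |
| days per year | d | 365 | fixed; leap days are far below the precision of the inputs |

The coefficient-grade bins are lower-inclusive / upper-exclusive; the
published class ranges touch at their endpoints, so a deterministic
convention is required, and a boundary cell lands in the higher-loss
class. The convention is recorded in the run configuration.

## Design choices where the design was open

* **Industrial gap-filling.** Missing years of the industrial discharge
  series are predicted from a per-province, per-pollutant ordinary
  least-squares fit of log(discharge) on log(GDP) — the standard
  emission–activity elasticity form. With exactly two positive
  observations the fit is the exact power law through them; with one,
  the fill is constant. Observed years always pass through unchanged,
  and predictions are clipped at zero and flagged `imputed`.
* **Combining the agricultural surrogates.** Slope and clay grades are
  combined multiplicatively, treating the two grades as independent
  relative propensities; provincial renormalization restores exact
  conservation under any combination rule, so the choice affects only
  the within-province pattern, never the totals.
* **Industrial weighting.** Within its two eligible land-use classes,
  industrial discharge is population-weighted (not uniform), on the
  grounds that industrial activity co-locates with population at the
  regional scale.
* **Livestock surrogate.** Livestock discharge uses the same cultivated
  land mask and terrain grades as crop farming; no separate livestock
  surrogate layer is defined.
* **Profile normalization.** The rainfall-driven monthly coefficients
  P_i/P_avg sum to 12 over the year, which would multiply annual mass
  by 12 if applied literally; profiles are therefore normalized to sum
  to one (equivalently P_i/ΣP), the only reading consistent with
  annual–monthly mass balance. The crop profile's calendar term
  Σ_n A_n,i·F_n,i is likewise treated as a relative weight only. The
  normalization decision is recorded in output metadata.
* **Per-cell profiles.** Residential, crop and livestock profiles are
  computed per grid cell from the monthly climate stack, matching the
  use of kilometre-scale monthly climate data; the profile functions
  also accept plain 12-vectors for province-mean use.
* **1:1 validation statistic.** Cross-scale R² is computed against the
  1:1 line, `1 − Σ(pred−obs)²/Σ(obs−mean)²`, not from a refitted slope:
  the question is whether the grid reproduces the statistics, not
  whether they correlate.

## Numerical choices and degenerate inputs

* Values are float64 in memory and float32 on disk; conservation is
  checked in memory before the cast.
* Monthly reductions (annual temperature mean, annual rainfall sum) use
  strict sequential month-by-month accumulation, fixing the
  floating-point evaluation order so the vectorized grid path is
  bit-for-bit reproducible by a per-cell scalar loop.
* Zero-division guards: constant temperature → uniform residential
  profile; rain-free year → uniform livestock profile and calendar-only
  crop profile; amplitudes R > 1 can push extreme months negative, in
  which case coefficients are clipped at zero and renormalized (logged).
* Provinces whose surrogate carries no mass in a sector fall back to a
  uniform split over eligible cells, then over all province cells; each
  fallback is logged and recorded in the weights' provenance. National
  inventories never hit these branches; toy grids do.
* Slope is derived from the DEM with Horn's 3×3 operator,
  edge-clamped at the boundary; it is exact on an inclined plane and
  invariant under a constant height offset.
* All layers of a run must share one grid (shape, affine transform, CRS
  label) exactly; mismatches are errors, never implicit resampling.
  Each cell belongs to exactly one province via a pre-rasterized
  province-ID grid, which precludes double counting at boundaries.

## The synthetic generator

`nutrigrid.synthetic` builds complete toy input sets: a Voronoi
tessellation of provinces over one grid, a categorical land-use field
guaranteed to contain every class each sector needs in every province, a
clustered log-normal population surface boosted on urban and rural
settlement cells, smooth Gaussian-filtered terrain and soil-clay fields,
a sinusoidal annual temperature cycle with noise, summer-peaked
precipitation, a two-region crop calendar, and per-province parameter
tables drawn from ranges plausible for a mid-sized province. The default
scale is 3 provinces on a 60 × 60 grid over 12 months for both
pollutants — large enough to exercise the fallback and boundary code
paths, small enough to run in a couple of seconds. The acceptance
battery and some tests use the same generator at 40 × 40 or smaller,
which exercises identical code paths at lower cost. All draws come from
a single seeded generator; a scenario is byte-for-byte reproducible from
its seed, and the shipped ground truth is by construction exactly what
the accounting operations produce on the shipped tables.

What the generator does **not** emulate: real provincial magnitudes and
their correlations (fixtures target structure, not realism), spatial
autocorrelation between land use and terrain, multi-year parameter
trends, nodata margins, and reporting artifacts of real yearbooks
(unit changes, series breaks, definitional revisions). Passing tests
therefore demonstrate that the machinery is conservative, deterministic
and correct on well-formed inputs — not that any particular real-world
inventory is accurate, which depends entirely on the quality of the
statistical inputs and coefficients supplied.

## Known limitations

* Aquaculture is excluded from the livestock sector.
* No uncertainty propagation: outputs are point estimates.
* No reprojection or resampling: all inputs must be pre-aligned on one
  grid, and province polygons must be rasterized externally.
* The industrial discharge–GDP relationship is a gap-filling device, not
  a structural model; imputed years inherit its elasticity assumption.
* Sub-monthly (e.g. diurnal livestock) variation is not modelled.
* Monthly NetCDF output uses the classic NetCDF-3 format.
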