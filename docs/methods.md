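# Methods

## Model and assumptions

The package treats rubble accumulation as a purely geomorphometric
property of the reef surface: a 10-m point on a down-slope transect can
retain a problematic rubble layer when the surrounding terrain is locally
flat or forms a depression deep enough to hold the layer, and cannot when
it sits on or near a steep drop (rubble rolls to the reef base as talus)
or on a local high. Hydrodynamic forcing, rubble formation rates and
stabilisation are deliberately out of scope — the output is *relative
susceptibility*, not a rubble budget.

Conventions used throughout:

* **Depth is positive-down metres.** File formats that store elevation
  (ESRI ASCII grids, where below-sea-level values are negative) are
  negated at the I/O boundary. This removes double-negative reasoning in
  the decision tree.
* Profiles are sampled at exactly 10-m spacing, matching the native cell
  size of current satellite-derived bathymetry products; all window
  lengths are expressed in metres and converted to samples by rounding to
  the nearest sample.

## The decision tree and its parameters

| parameter | default | unit | meaning |
|---|---|---|---|
| `moving_window_m` | 50 | m | half-width of the along-track window (5 samples each side) over which local relief is assessed |
| `rubble_height_m` | 0.5 | m | minimum rubble-layer thickness considered problematic; a depression must sit this far below both flanks to trap it |
| `roll_depth_range_m` | 5 | m | window depth range at or above which the point is on/near a steep slope and rubble rolls off |
| `flat_depth_change_m` | 0.5 | m | maximum window depth range still considered flat |

Rule order at each focal point: roll exclusion, local-high exclusion,
then depression-or-flat. Boundary conventions: the roll exclusion is
strict-at-the-boundary (a range of exactly 5 m rolls), the flat rule is
inclusive (exactly 0.5 m is flat), and the depression rule uses ≥ for the
rubble-height clearance. The 0.5-m defaults reflect the vertical
resolution limit of satellite-derived bathymetry — smaller relief cannot
be resolved reliably at 10-m grid scale.

Edge handling is explicit because windows truncate at profile ends: a
side with no points can satisfy neither the depression rule nor the
local-high exclusion (both require two sides), while the flat rule still
applies. A point can satisfy the depression rule while the window range
lies between the flat and roll thresholds; the branch order permits this
intentionally (a 1-m-deep pocket on an otherwise gentle slope traps
rubble even though the window is not "flat").

The depression test compares the focal depth against the *shallowest
point on each whole window side*, not just immediate neighbours: at 10-m
sampling a one-sample depression is rarely resolvable, and the whole-side
reading is the conservative interpretation of "both flanks stand above
the focal point".

## Transect sampling

Profiles are extracted by bilinear interpolation at 10-m steps along
500-m transect lines (scipy's regular-grid interpolator over cell
centres; nodata propagates as NaN). Both ends are truncated where depth
≤ 2 m so reef crests and flats are excluded; interior points are never
removed. Transects attach to the nearest reef polygon within 1000 m
(distance to boundary or interior, 0 if inside). Cell aspect uses Horn's
3×3 estimator on elevation — the method behind the standard GIS Aspect
tool — and a transect's mean aspect is the circular (vector) mean of the
aspects of all cells whose centres lie within 10 m of the line. Aspect
classes are 90°-wide, half-open and centred on the cardinal directions
(N = [315°, 360°) ∪ [0°, 45°), and so on); the centring is a design
choice, as is resolving the "nearest reef" distance to the polygon
boundary rather than the centroid. Transect *generation* (centreline
derivation from geomorphic zone polygons) is not re-implemented: lines
are inputs, or are produced synthetically as normals to an axis polyline
at 500-m spacing.

## Aggregation and sensitivity

Exceedance is strict (cover > t); the top decile in rankings is
⌈0.1·n⌉ reefs with ties broken by reef id so sensitivity-of-ranking
numbers are reproducible. The OAT analysis reruns the full pipeline at
0.8× and 1.2× each parameter (others at base; 40 m and 60 m windows map
to 4 and 6 samples). Count sensitivity is the mean over perturbations and
thresholds of 100·|n − n_base|/n_base; thresholds with a zero base count
are excluded from the mean by default (they would otherwise contribute an
undefined ratio), with an `include` mode that counts them as 0% change.
Ranking sensitivity is the mean absolute rank change of the base-case
top-decile reefs under each scenario's re-ranking, averaged per threshold
and then across thresholds, with a standard error over per-threshold
means; a reef absent from a scenario's ranking is assigned rank
(list length + 1). Percentage changes are reported as magnitudes;
direction is retained in the detailed tables.

## Beta-regression mixture

Cover proportions per transect × depth-section are compressed with
`y* = (y(n−1)+0.5)/n` (n = observations in the analysed table) and
modelled as a two-component mixture of beta regressions in the
mean–precision parameterisation (shape1 = μφ, shape2 = (1−μ)φ), each
component with logit-linked mean over (intercept, deep, E, S, W; references
shallow and N) and its own covariate-free precision. Fitting is EM:
E-step responsibilities, M-step weighted ML beta regressions (L-BFGS with
analytic gradients, warm-started). The observed-data log-likelihood is
asserted non-decreasing at every iteration; convergence is a 1e-8
relative change, max 1000 iterations, with 10 restarts (the first a
deterministic quantile split on logit(y*), the rest random seeded
splits — single-component data in particular has local optima that the
restarts escape). Components are reported sorted by intercept to fix the
label-swap ambiguity. Wald z = β̂/SE uses the observed information of the
*full mixture* likelihood (numerical Hessian over coefficients, log
precisions and the logit mixing weight). The depth×aspect interaction
test hard-assigns observations by posterior, then compares per-component
beta regressions with and without the three interaction terms by a
3-df likelihood-ratio test.

## Synthetic data

The generators exist so that every stage is testable without external
bathymetry products. `make_profile` composes flats, linear ramps/drop-offs
and V-shaped depressions/highs whose relief is realised exactly on the
10-m lattice before optional Gaussian noise (truncated so depths stay
positive; zero by default so algorithm tests are exact).
`make_reef_grid` builds annular-platform and ribbon reefs with a shallow
crest and a linearly deepening slope, radially monotone pre-noise. The
packaged demo set uses 12 annular reefs with slope widths drawn from
60–300 m and noise up to 0.35 m, giving a realistic spread of transect
covers from near 0 to 100%. `simulate_mixture` draws proportions from the
two-component beta-regression mixture with a balanced random
depth/aspect design; its default coefficients ((−2,0,0,0,0) and
(1,0.3,−0.2,−0.3,0.1), φ = 20/30, π = 0.3) produce the strongly bimodal,
mostly-low-cover pattern characteristic of real transect data.

What the synthetic surfaces do *not* emulate: spur-and-groove structure
(below 10-m resolution anyway), nodata gaps of realistic shape,
georeferencing quirks of mosaicked products, and any correlation between
aspect and slope steepness induced by wave exposure. Passing tests
therefore demonstrate algorithmic correctness and statistical recovery
under the stated model, not fidelity of any particular field prediction.

## Problem sizes and numerical choices

The test suite and the acceptance script run on deliberately compact
problems chosen to exercise every code path: 1,000 random profiles
(~24,000 focal points) for the oracle-equivalence check, 200 profiles for
the monotonicity ladders, a 12-reef demo set (~60 transects) for
pipeline and OAT summaries, 5,000 observations for mixture recovery, and
40 null replicates (80 component-level tests) for the interaction-test
type-I calibration. Degenerate inputs are rejected early with named
errors: empty profiles, profiles with interior NaNs (cleaning is a
separate, explicit step with a counted report), parameter sets violating
`flat_depth_change_m < roll_depth_range_m`, and designs with fewer
observations than coefficients.

## Known limitations

* Susceptibility is relative; no rubble volume, stability or transport is
  estimated.
* The 2-m truncation and 10-m shallow/deep split are fixed conventions of
  the analysis, configurable but not validated against ground truth here.
* Grid I/O is limited to the plain-text ESRI ASCII format; vector inputs
  are GeoJSON. No coordinate-system handling is performed — grids and
  geometries must share a projected metre-based CRS.
* The precision φ of each mixture component is covariate-free; strongly
  heteroscedastic covers would need a precision submodel.
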