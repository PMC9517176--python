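# Methods

This note documents the models implemented in `urban3d`, the design of the
synthetic city that drives them, the numerical choices, and what the test
suite does and does not establish about real data.

## Function-zone identification

Candidate polygons are classified from the area shares of land-use classes
inside them (polygon intersection against the parcel mosaic): residential,
commercial and educational zones require a strict majority (> 50%),
industrial zones > 40%. Thresholds are strict because the rule is "more
than". When several rules fire the largest share wins; an exact tie — which
cannot occur for two majority classes and is only conceivable in degenerate
compositions — yields no label, since the zone's function is then not
distinct. Candidates are an input: zone delineation is a planning judgement,
not an algorithm, so the package classifies rather than segments.

## 3D landscape indices

Buildings are rectangular prisms: volume = footprint area × height, height =
floors × 2.8 m (5.0 m for industrial plants). Heights fall into eight
categories (bungalow 2.8–5.0 m … super high-rise > 100 m). The printed
category bounds enumerate attainable heights rather than partitioning the
line, so gaps exist (e.g. 15.0–19.6 m); a height in a gap is assigned to the
category with the nearest interval endpoint, ties to the lower category —
this makes classification total over every floor count.

Per sample area (zone): mean height H̄; volume density Σ Vᵢ/(H_max·S);
spatial dispersion as the population coefficient of variation of heights
(the 1/n variance, following the printed normalisation); fluctuation
H_max − H_min; Shannon diversity of footprint-area shares across the height
categories (area shares, not building counts — the definition speaks of
"area occupied"); and uniformity as that entropy over ln m, with m the
number of categories *present* (a `smax_global` switch uses ln 8 instead).
A single-category zone has uniformity 0 by convention. Building-free zones
are an error, not a zero.

## LUR

Buffer predictors at radii 500–5000 m (all seven listed radii; the
enumerated list is taken over the stated count of six): area shares of
ecological(+water), industrial, water, arable and residential land, and
main/secondary/total road length per buffer area, computed on dissolved
class geometry so the parcel tessellation is irrelevant. Meteorology enters
unbuffered, standardized as `met_scale · (x − mean)/sd` with population
statistics from the panel and `met_scale` = 0.1. The coefficient magnitudes
of the generating equation are only physically plausible on a standardized
scale; the 0.1 factor makes its seasonal terms produce monthly swings of
roughly ±10–15 µg/m³ around a ~41 µg/m³ mean, i.e. realistic monthly
concentrations, and since the transform is shared between the generator and
the fitter (and stored on the fitted model for prediction), coefficient
recovery is exact at zero noise. The scale is exposed as configuration.

Screening keeps, per variable family, the member most Pearson-correlated
with PM2.5, ranks the keepers by |r|, and drops any keeper correlated above
0.6 with an already accepted one (dropping the lower-ranked member of a
pair; the alternative of discarding the whole family is not implemented as
default behaviour). The stepwise is removal-only: each pass removes every
variable with two-sided p > 0.10 plus any buffered variable whose sign
contradicts its assumed direction, and stops when a pass removes nothing —
convergence in at most as many passes as variables. Sign enforcement
applies to buffered variables only: the procedure's plausibility argument
concerns land-use directions, and meteorological signs (precipitation in
particular) are legitimately data-determined. A numerically perfect fit
yields meaningless t-ratios; variables with negligible standardized
contributions are then removed directly.

Validation: random 75/25 split by seed; mean absolute error rate
mean(|ŷ−y|/y) (zero observations skipped with a warning) and RMSE. Surface
prediction evaluates the fitted equation at cell centres (default 100 m in
the API; the pipeline default is 500 m, a problem size that resolves the
synthetic city's ~1 km zones while keeping a full run in seconds);
meteorological terms default to their panel mean (zero on the standardized
scale), so the surface is an annual-mean field. The raster is a plain-text
ASCII grid with no-data −9999.

## GWR

Local weighted least squares at every observation with Gaussian weights
exp(−(d/b)²). Fixed (not adaptive) bandwidth selected by golden-section
search on AICc, computed from the trace of the hat matrix; the search is
deterministic, endpoints are always evaluated, and a non-unimodal profile
falls back to the grid minimum with a warning. In the exact-fit limit the
error variance is floored at a machine-precision share of the response
variance so that model comparison degenerates gracefully to preferring the
flattest model. Singular local designs fall back to a tiny ridge with a
warning. Standardized residuals are internally studentized with the GWR
leverage. Predictor selection per zone type: the index with the largest
|r| against zonal PM2.5 plus the best-ranked remaining index correlated
with it below 0.6; if none qualifies a single-predictor model is fit with a
warning.

Moran's I on the standardized residuals uses inverse-distance,
row-standardized weights; expected value −1/(n−1); two-sided p from 999
seeded permutations. A model is flagged credible when p > 0.05 (residuals
spatially random). Zone locations are polygon centroids.

## The synthetic city

The generator's defaults are the study conditions. Region ≈ 24 × 23.4 km
(≈ 562.6 km², ~35 km² per monitoring site); 16 industrial + 14 educational
+ 18 residential + 13 commercial zone rectangles with per-type area ranges,
and a Beta-shaped draw whose mean matches the per-type mean areas; mixed
candidates that satisfy no dominance rule; a background mosaic of
ecological / water / arable / residential / other patches with a west→east
ecological gradient, district-scale (4.5 km) variation, and a river band.
Buildings sit on jittered grids inside zones (disjoint by construction)
with zone-type floor distributions: industrial 1–3 plant floors (low,
simple), educational 2–8, residential 6–33, commercial 2–40 — so zone-type
mean heights differ strongly (the ANOVA power check in the tests).

The monitoring panel sets PM2.5 = reference-equation linear combination of
VEG5000, INDU500 (raw shares) and standardized PRE_1h, PRS_Sea, plus
Gaussian noise, by default at 1% of the signal SD. Meteorology is monthly
and city-wide with subtropical-monsoon phenology: pressure peaks in winter,
temperature in late summer, precipitation in the April rainy season —
placing precipitation and sea-level pressure in near phase-quadrature, the
structure a panel must have for both to survive |r| > 0.6 screening.

Two design devices deserve emphasis, because they encode the
cross-correlation structure that the reference screening outcome implies
the real panel had:

* decoy meteorology is constructed either to be strongly collinear with a
  *stronger-ranked* driver (humidity tracks the rainy season and the damp
  winter; station pressure carries a secondary local harmonic absent from
  the sea-level series) or to have its net correlation with PM2.5 cancelled
  by phase mixing (wind combines winter-monsoon and spring components), so
  that decoys are screened out against the drivers rather than occasionally
  displacing them — mirroring a panel in which exactly the four reference
  variables emerged;
* site layouts are rejection-sampled (deterministically, by sub-seed) until
  the reference buffer predictors are the within-family correlation
  maximizers of the implied site-level signal, with a small margin and a
  collinearity cap between them. This emulates, by construction, the fact
  that in the real geography VEG5000 and INDU500 won their families. If no
  layout qualifies within 100 attempts the best-scoring one is used with a
  warning.

A subset of sites is placed adjacent to (west of) industrial zones so
industrial 500 m shares vary across sites, as they must for the industrial
term to be estimable.

What the generator does **not** emulate: within-month temporal dynamics,
street-canyon effects, terrain, measurement error in covariates, spatially
correlated model error, and real street-network topology. Passing tests
therefore demonstrate correctness of the computational chain and its
statistical calibration under the stated design — not that the reference
effect sizes would be recovered from other cities' data.

The GWR testbed is separate: n = 200 points, standard-normal covariates,
true coefficient surfaces linear in the coordinates with a monotone
west→east gradient on the first slope and a south→north gradient on the
second, noise at 5% of the signal SD.

## Numerical choices and degenerate inputs

* Buffers are 128-gon circle approximations (`quad_segs=32`).
* Constant predictor columns are excluded from screening with a warning;
  an all-removed stepwise returns an explicit intercept-only model.
* Zones smaller than a raster cell have no cell centre; zonal means then
  error by default, and the pipeline falls back to the centroid cell.
* One-way ANOVA uses the plain between/within decomposition (for a one-way
  layout Type III coincides with it, also under the unbalanced 16/14/18/13
  group sizes); LSD applies no multiplicity adjustment, by definition.
* All stochastic stages draw from `numpy` Generators seeded by fixed
  offsets from one master seed, so each stage is independently
  reproducible and whole runs are byte-identical.

## Known limitations

* The stepwise keeps a spurious variable with probability near its 10%
  removal level per surviving decoy — a property of the procedure, not a
  defect; exact four-variable recovery is therefore the modal, not
  universal, outcome (~90% of seeds at the default conditions).
* Fixed-bandwidth Gaussian GWR only; no adaptive, mixed or multiscale
  variants.
* The credibility rule for GWR residuals (Moran p > 0.05) is applied as
  stated even though local-model residual diagnostics on n ≈ 15 zones have
  little power.
* Road-density covariates in the synthetic city vary little across sites
  (a grid network), so traffic terms are usually screened or removed —
  consistent with the motivating analysis, but meaning the traffic path is
  exercised mainly by unit tests.
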