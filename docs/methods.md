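# Methods

## The model

The quantity of interest is relative risk of a successful marine bioinvasion
between an ordered pair of coastal regions, decomposed into the probability
of *introduction* (surviving the voyage) and the probability of
*establishment* (surviving the destination). Three measurable proxies stand
in for these:

1. **Shortest over-water distance** (meters) between region centroids —
   longer voyages mean longer exposure to transport stress. The conservative
   assumption is that vessels take the geographically shortest feasible sea
   route; interim stops, weather routing and exclusion zones are ignored.
2. **Cross-latitudinal extent** of that route (degrees) — a proxy for the
   temperature range experienced en route. Within one hemisphere it is
   max − min latitude over the route's cell centers. For a route that
   strictly crosses the equator the meridional temperature gradient reverses
   sign, so the effective span is the absolute latitude farthest from the
   equator; a route that merely touches latitude 0 uses the plain difference
   (both formulas agree there).
3. **Environmental distance** (unitless) between regional annual-mean
   sea-surface temperature (°C) and salinity (PSU) — smaller distance means
   an easier establishment. Values are comparative only.

### Routing graph

The ocean is rasterized on a regular lon/lat grid (WGS84): a cell is water
iff its center lies inside an ocean polygon (cell-center rule — simple,
deterministic, and faithful to a water=1/no-data raster). Water cells become
nodes of an undirected graph; edges join all 8-neighboring water pairs
(orthogonal + diagonal). Diagonal edges are allowed whenever both endpoint
cells are water, even when the two shared orthogonal neighbors are land —
plain 8-connectivity with no corner-cutting prohibition, which on coarse toy
grids can let a route slip across a single-cell land corner; production
masks should be fine enough that this does not matter.

Each edge weight is the great-circle distance in meters between the two cell
centers (haversine on a sphere of radius 6 371 000 m, configurable; other
radii shift absolute distances by <0.5% and no relative comparison changes).
This realizes geometric correction of a unit-conductance transition matrix:
cost per hop = inter-center distance, so E–W hops shrink toward the poles
while N–S hops are latitude-independent. Shortest paths use Dijkstra's
algorithm on the sparse weight matrix (scipy); the distance matrix is
symmetrized exactly (elementwise minimum with its transpose) to remove
last-ulp sweep-order asymmetry.

`wrap_longitude` (default on) makes the first and last columns of each row
adjacent — a global ocean is physically periodic. It is configurable off to
mimic a non-wrapping raster; whether the original global analysis wrapped
across the antimeridian is not documented, so trans-Pacific distances under
either choice are both available.

Canals are ordered lon/lat vertex chains; carving turns every cell under a
vertex plus the 8-connected Bresenham cell line between consecutive vertices
into water. Carving is idempotent and never removes water, hence never
increases any pairwise distance.

### Centroids and path statistics

A region's routing endpoint is its polygon's area centroid, unless an
explicit `centroid_override` is set (reproducing hand-placed endpoints such
as an Arctic centroid moved toward the busiest shipping waters). If the
containing raster cell is land, the endpoint snaps to the nearest water-cell
center, automating manual repositioning to the nearest coast. Nearness is
great-circle distance quantized to the micrometer so that geometrically
equal candidates tie exactly; ties resolve to the lowest (row, col).

Route geometry is reconstructed by backtracking from the destination along
cells whose distance labels are consistent (relative tolerance 1e-9),
breaking ties toward the lowest node id. Node ids number water cells in
row-major order, so tie-breaking is reproducible. Tie routes of equal length
can differ in latitude extent; the deterministic rule pins one choice, and
this sensitivity is inherent to the statistic, not to the implementation.
Latitude extents are taken over all traversed cell centers.

### Environmental summaries and distance

Regional means are computed over field cells whose centers fall inside the
region polygon, weighted by cos(latitude) to correct the poleward shrinkage
of lon/lat cell areas (an unweighted mean is available). The default
distance is Euclidean after standardizing each variable to zero mean and
unit variance across regions (population σ), putting °C and PSU on a common
scale; raw Euclidean and per-variable weights are configurable, and extra
variables (oxygen, nutrients) are accepted as additional columns. The
original study took its environmental distances from an externally released
dataset built with a generalized-linear-model formulation whose exact
transformation is not recoverable; its published 0–73.02 range is therefore
not a target here, and the standardized-Euclidean default is this package's
own choice. A variable with zero cross-region variance makes standardization
undefined; this errors with advice rather than silently dividing by zero.

### Risk standardization and combination

For each distance matrix, `M = floor(max finite entry) + 1` in the matrix's
native units (meters, degrees, unitless). `risk = 1 − d/M` for d > 0;
`risk = 0` where d = 0, including the diagonal — a region is not a risk to
itself. Taking the *next highest* integer (rather than the ceiling, which is
a no-op at integer maxima) guarantees the farthest pair keeps strictly
positive risk; e.g. a maximum span of 84.92° gives M = 85 and a minimum risk
of 1 − 84.92/85 ≈ 0.00094, printing as 0.001 at the three-decimal precision
used in report tables. For meter-valued matrices the integer round-up is
numerically negligible (≤1 part in 10⁶). Risks reconstruct their distances
via d = M·(1 − risk) to ≤1e-12 relative error. Combined risk is the weighted
elementwise sum (defaults: unit weights, range 0–3); NA in any component
propagates. Unreachable (+inf) pairs indicate disconnected basins — usually
a missing canal — and are surfaced in a reachability report; standardization
converts them to NA with a warning rather than polluting M.

Excluded regions (e.g. provinces whose any reasonable centroid would sit on
a landmass) carry NA rows/columns through every matrix.

### Empirical validation

Recorded counts of vessel-mediated NIS introductions are indexed by an
external classification (Large Marine Ecosystems); risks are indexed by the
internal region set. The judgment-based crosswalk is an input table, not
code: `sum_counts` entries pool counts from several external areas onto one
region; `combine_and_average` entries additionally average each risk type
across ≥2 adjacent regions; `omit` entries are excluded with a logged
reason. Counts are conserved: matched + omitted = input. Matches with
exactly one recorded NIS are noisy one-off records and can be filtered
before regression; both the all-data and singleton-filtered OLS fits
(slope, intercept, R² = 1 − SS_res/SS_tot) are reported. The published
12-match table for the Northern European Seas destination ships as a
packaged CSV fixture. A constant response returns slope 0 and R² 0 by
definition rather than a 0/0.

## Synthetic worlds

The toy-world generator produces the study conditions at desk scale: a
40°×60° basin at 1° cells (2 164 water cells; small enough that exhaustive
oracles run in milliseconds) split by a meridional continent at lon 18–22°,
a canal at lat 0.5°, and six coastal regions in three latitude bands on each
shore. SST at cell latitude φ is `28 − 0.4·|φ|` °C plus Gaussian cell noise
(σ = 0.25 °C, seeded; 0.4 °C/deg approximates the real meridional SST
gradient and 28 °C a tropical surface mean). Salinity is 35 PSU plus
per-region offsets within ±1 PSU, the scale of real inter-basin surface
contrasts. Everything is a pure function of (spec, seed).

What it deliberately does not emulate: real coastline complexity, real WOA
climatology (zonal SST structure, seasonal cycles), ocean currents, and the
62-province global geometry. Passing tests therefore demonstrate the
*mechanics* — routing, statistics, standardization, aggregation — under
known ground truth, not the published global distance extremes, which
require the real polygon and climatology datasets and a 0.05° global run.

## Numerical choices

- Great-circle distances: haversine (stable at small angles), clipped into
  the arcsin domain.
- Shortest-path ties: lowest-node-id predecessor; distance-label matching at
  rtol 1e-9 with strict-progress guard.
- Nearest-water ties: micrometer quantization then row-major first-minimum.
- Degenerate inputs error early and specifically: empty grid extent,
  all-land grids, channel vertices outside the extent (named in the
  message), all-NA fields, zero-variance variables, constant regressors,
  label mismatches (offending labels listed).
- CSV matrices: region ids as first row/column, literal `NA` for missing,
  shortest-round-trip float formatting, parsed back with round-trip
  precision so write→read→write is byte-stable. Pipeline reruns on
  identical inputs are byte-identical for all data files.

## Problem sizes

Tests and the acceptance checks run on the toy world (≤60×40 cells), on
randomized 10×14 worlds (100 replicates for metric properties, 40 for
carving monotonicity), and on ≤6×6 grids for the exhaustive path-enumeration
oracle — sizes chosen so the independent oracles (pruned DFS over simple
paths, Bellman-Ford label correction, networkx on independently built
graphs) stay exact and fast.

## Known limitations

- Distance is a proxy for duration: uniform vessel speed, no seasonal ice,
  no traffic weighting (propagule pressure is explicitly out of scope).
- The environmental-distance default is not the external GLM formulation the
  original risk tables used; rankings may differ even with identical inputs.
- Latitude extents are computed from traversed cell centers; analyses that
  derived extents from segment bounding boxes agree up to half a cell.
- 8-connectivity quantizes route headings to 45°, inflating distances by up
  to ~8% versus true geodesics; all risks are relative, so the bias largely
  cancels.
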