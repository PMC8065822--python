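# Methods

This note documents the models and procedures implemented in `endemap`,
the assumptions behind them, the parameters that matter, and the choices
made where the design was genuinely open.

## Spatial frame

All surfaces live on a regular square grid in projected kilometres. The
projection is the Lambert cylindrical equal-area map on a sphere of radius
6371 km (x = R·λ, y = R·sin φ), chosen because it is exactly area-preserving:
a density of *d* points/km² on the grid is a true spherical density, and
patch/cell areas need no correction. The projection is a closed form, so the
round trip is exact to floating point; distortion of *shape* grows away from
the equator, which affects nothing here because no statistic depends on
local angles. Distances between localities (species range radii, GIE class
assignment, kernel distances in GIE) are great-circle kilometres via the
haversine formula on the same sphere — "km between places" should not depend
on a map choice. Grids use half-open cells `[edge, edge + cell_size)` with
row 0 at minimum y; a grid always covers its requested extent, rounding the
cell count up. NaN marks nodata and is excluded from every statistic.

## Record cleaning

Occurrence hygiene mirrors standard museum/GBIF practice: rows missing
mandatory fields are dropped and counted; numeric but out-of-range
coordinates are carried through parsing (as unvalidated `RawPoint`s) so the
cleaner can count them as invalid-coordinate drops rather than the loader
discarding them silently; records whose stated coordinate uncertainty
exceeds `max_uncertainty_m` (default 10 000 m — a one-minute-of-arc-scale
threshold typical for historical museum material; records with *unknown*
precision are retained) are dropped; exact (species, lon, lat) duplicates
collapse to their first record. Exact duplication at full float precision is
deliberate — it makes the rule deterministic; an optional rounding knob
(default off) coarsens it. Judgement-based exclusion of doubtful records is
not automatable; an exclusion list of species names is honoured instead.
Cleaning never raises: it returns a report whose counts reconcile exactly
with the table lengths, and it is idempotent.

## Density and richness surfaces

`point_density` is a moving-circle count: cell value = points within
`radius_km` of the cell centre, divided by π·r². `kernel_density` uses the
quartic (biweight) kernel K(d) = 3/(πh²)(1 − d²/h²)², the compact-support
kernel used by mainstream GIS density tools, normalised to unit mass per
unit weight. Mass conservation (surface sum × cell area = total weight,
within 1 %) holds for points at least one bandwidth from the grid edge; no
edge correction is applied, matching planar GIS practice. The default
bandwidth is 50 km in the library API and 100 km in the pipeline defaults
(set alongside the 100-km tessellation so the smoothed richness surface and
the density surfaces are comparable); bandwidth is always an explicit,
logged parameter because no universal default is defensible.

Species richness uses a square tessellation anchored at the projected
origin (default resolution 100 km): a cell's richness is its count of
distinct species, not of points. Cells are converted to centre points
weighted by richness and smoothed with the same quartic KDE, giving a
continuous richness surface whose mass approximates total summed richness.
Squares (not hexagons) keep cell membership a half-open floor operation —
exactly testable.

## Habitat Specificity

From the cleaned occurrences and a disjoint patch mosaic, the binary
incidence matrix assigns species *i* to patch *j* iff it has ≥ 1 occurrence
inside *j* (point-in-polygon with `covers`, so boundary points count;
a point on a shared edge goes to the lexicographically smallest patch id —
an arbitrary but deterministic tie-break). Patches whose interiors overlap
are rejected. Species with every occurrence outside all patches are dropped
from the matrix and reported.

The corrected index is S_j = Σ over species present in j of 1/nᵢ, computed
as an exact rational sum (`fractions.Fraction`) before conversion to float,
so the conservation law Σⱼ Sⱼ = species count holds to machine precision by
construction, not approximately. The index is incidence-based: locality
counts within a patch are irrelevant, only presence. Per-patch occurrence
percentages (share of all localities falling in each patch) are reported
alongside, with out-of-patch localities kept in the denominator.

## Climate profiles, clustering, overlap

Bioclim profiles are the means of the 19 BIO variables over a taxon's
occurrences, sampled by nearest-cell lookup on a shared grid; occurrences on
nodata are excluded per variable and counted. The package ships one small
reference table of published per-taxon means for the five Afrotropical taxa
(three flea-beetle genera, two host-plant genera) as `data/`, used by the
worked examples and tests.

Euclidean distance between profiles defaults to **unstandardized** raw
values. This matches the convention under which the shipped profiles were
produced, but it means large-scale variables (temperature seasonality,
annual precipitation — hundreds of units) dominate the metric; a
`standardize=True` flag z-scores variables across profiles for analyses
where that is unwanted.

WPGMA (McQuitty) clustering merges the closest pair at height equal to
their current distance; the merged cluster's distance to any third cluster
is the plain average (d₁+d₂)/2 regardless of sizes. Heights are recorded as
raw inter-cluster distances (not halved), so the cophenetic distance of two
leaves is read directly off their lowest common merge; the Newick export
halves heights to place leaves at equal ultrametric depth. Ties on the
minimum distance break lexicographically on cluster labels. WPGMA is
reducible, so heights never decrease — asserted as an invariant. The
implementation is cross-checked in the tests against both a structurally
independent reference implementation and `scipy`'s `weighted` linkage.

Niche-overlap detection fits, on pooled-z-scored attributes (BIO1, BIO7,
BIO14, BIO18 by default), a near-hard-margin linear SVM (C = 10³); perfect
training classification means divergent niches with a linear boundary.
Otherwise a polynomial-kernel SVM (degree 3, coef0 = 1 so lower-order terms
are included; same C) is tried; perfect separation there still counts as
divergence. Residual misclassification means the clouds interpenetrate:
`overlap=True` with the polynomial stage's error count and percentage.
Misclassification is counted by the sign of the decision function on the
training points. The SVM solver is capped at 10⁵ iterations: with large C
on deeply interpenetrating clouds libsvm otherwise grinds toward an
infeasible hard margin; separable inputs converge far below the cap, so
divergence verdicts are unaffected and only the exact error count on heavily
overlapping data could differ marginally from an uncapped fit. Two identical
point clouds give exactly 50 % misclassification (each duplicated point
contributes one wrong label whatever the prediction).

## Geographical Interpolation of Endemism

A species' range is summarised by the centroid of its occurrences (mean in
projected equal-area coordinates, mapped back to lon/lat) and its
area-of-influence radius — the maximum great-circle distance from the
centroid to an occurrence. Classes are **disjoint** radius intervals,
(0, 100] km (class 1) and (100, 300] km (class 2) by default; a `nested`
flag assigns a species to every class whose bound covers it, since either
convention is defensible. Species beyond the last bound are non-endemic at
these scales and are left out.

The per-class surface sums peak-normalised quartic kernels
K(d) = (1 − d²/h²)², d < h, centred at each species centroid, with h
defaulting to the class bound (100/300 km). Peak normalisation — rather
than the unit-mass normalisation used for density estimation — makes the
surface read directly in species-equivalents, so "k species overlap here"
has a literal meaning.

Areas of endemism are connected components (8-neighbour) of cells where at
least `min_synendemic` (default 2) species' kernels are **positive** —
i.e. cells lying inside that many areas of influence. Thresholding the
kernel *sum* at the same count was rejected as knife-edged: the discretised
sum of k coincident species peaks at k·(1 − d²/h²)² for the nearest cell
centre, which is strictly below k for any cell not centred exactly on the
centroid, so the canonical two-coincident-species case would produce no area
on almost every grid. The count rule is robust, monotone in the threshold
(lowering `min_synendemic` never removes an area), and matches the
definition of synendemy as a species count. Components are polygonized from
their cell rectangles and annotated with every contributing species; the
consensus map keeps per-class areas as distinct labelled layers, preserving
overlap and containment between classes. `min_synendemic` is a parameter
because single-species areas are sometimes of interest.

## Synthetic data: what it emulates, and what it does not

The generator provides the study conditions for all recovery experiments.
Defaults: a 2400 × 1200 km equal-area frame near the equator; 20 Voronoi
patches (an ecoregion-like mosaic: space-filling, irregular, disjoint);
19 climate layers, each a planar gradient plus low-frequency sinusoidal
field plus white noise with plausible bioclim units, with BIO6 derived as
BIO5 − BIO7 (BIO7 floored positive) so maximum monthly temperature dominates
the minimum everywhere; 400 plant localities from a Thomas-like
parent–offspring cluster process (20 parents, 40-km offspring scatter) and
120 insect localities, each tethered to a random plant point with
probability ρ = 0.9 and 30-km isotropic scatter, otherwise uniform; and two
endemic assemblages of 4 species × 10 points drawn uniformly in 20-km discs
whose centres are 2000 km apart. Species labels are assigned round-robin
(8 plant, 5 insect species). Tethering-with-probability makes ρ directly
interpretable: it is the fraction of insect localities that track the plant
pattern, and it is what the density-correlation experiment recovers.
Everything is deterministic per seed, with independent substreams for
landscape, climate, points, and endemics.

What the generator does **not** emulate: real ecoregion shapes or African
geography; spatially autocorrelated sampling bias and collection-effort
gradients typical of museum data; niche-driven (climate-dependent) point
placement — climate layers and point patterns are independent by
construction; coordinate error. Tests passing on this generator therefore
demonstrate that the *methods* recover planted structure under clean
conditions, not that any particular empirical dataset would yield particular
values.

## Numerical and scale choices

Exercised problem sizes — 25-km analysis cells over the default frame
(96 × 48 cells), 520 generated localities, 20-seed recovery experiments —
were chosen so the full pipeline runs in seconds while leaving every planted
effect far from marginal (the tethered-vs-null correlation gap is ~0.8 at
these sizes). ASCII rasters print values with `%.17g`, which round-trips
IEEE doubles exactly, so write-then-read is bit-exact despite the text
format. The WPGMA tie tolerance is 1e-15 (ties essentially only occur for
exactly equal inputs). Degenerate inputs are handled explicitly: empty point
sets give zero rasters, an empty endemism class gives a zero surface,
cleaning never fails, and constant-feature SVM inputs are guarded in the
z-scoring.

## Known limitations

* Only GeoJSON patch layers and ESRI ASCII rasters are supported; no
  shapefile or GeoTIFF I/O, and no CRS database — the single supported
  projection is the built-in cylindrical equal-area on the sphere.
* Kernel densities have no edge correction; mass statements hold for
  interior points only.
* The overlap detector reports training-set separability, as overlap
  detection requires; it is not a cross-validated classifier and its error
  percentages should not be read as generalisation error.
* Patch occupancy requires disjoint patches; genuinely overlapping habitat
  layers must be resolved upstream.
* GIE class-2 surfaces use a 300-km bandwidth, which on coarse grids can
  make two moderately separated assemblages merge into one area; bandwidth
  per species (its own radius, floored at one cell) is available as an
  option where that matters.
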