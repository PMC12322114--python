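# Methods

## The estimation problem

The package estimates annual 1-km crop-specific *area actually irrigated*
(AAI, hectares) from four kinds of inputs: an annual regional total-AAI
series (NUTS2, for some countries NUTS1); a single reference-year census
of crop-specific AAI per NUTS2 region; two rasters of *area equipped for
irrigation* (AEI) at mismatched resolution and epoch (fine/2005 and
coarse/2010); and yearly 1-km agricultural weight and crop-growing-share
layers.  The estimator is dasymetric: regional statistics are spread over
cells in proportion to ancillary layers, under hard conservation
constraints (regional cell sums equal the regional targets) and a hard
capacity constraint (a 1-km cell holds at most 100 ha).

Two constancy assumptions make the under-determined problem solvable:
the NUTS2-within-NUTS1 proportions of total AAI and the within-region
crop composition of AAI are both frozen at their reference-year values.
A third assumption — the *uniform irrigation percentage* — states that
within a region, crop and year, every cell irrigates the same fraction
of its crop-specific equipped area.  That fraction is exactly the
calibration coefficient, so the allocation step has no further freedom.

## Equipped-area harmonization

The fine 2005 AEI raster is block-summed to the coarse lattice (an exact
integer nesting in this package; the real 0.6′/5′ grids do not nest, see
Limitations).  The per-coarse-cell change ratio between epochs is then
resampled bilinearly to 1 km, as is the fine 2005 map, and the two are
multiplied.

**Ratio orientation.** The source formulas define the ratio as
100·AEI2005/AEI2010 yet multiply the 2005 map by it to obtain a 2010
map; taken literally the product has 2005²/2010 semantics.  Both
orientations are implemented behind `ratio_orientation`.  The default is
`inverted` (multiply the 2005 map by the 2010/2005 ratio) because only
that orientation reproduces the coarse 2010 totals when the ratio field
is spatially flat — a property asserted in the tests.  `as_printed` is
retained for literal reproduction.  Note that a *spatially constant*
ratio cancels entirely in the later calibration step, so the two
orientations produce identical final AAI in that regime; they separate
only for spatially varying ratio fields.

**Numerical choices.** Bilinear resampling maps each target cell centre
into the source's fractional index space and combines the four
surrounding source centres; outside the outer centre lattice coordinates
clamp to the boundary centres (edge replication — the source names the
method but not the boundary rule; clamping avoids nodata fringes).  Any
nodata neighbour makes the output cell nodata.  Zero-denominator ratio
cells yield ratio 0 and are flagged: a location with no 2010 coarse
equipped area carries no harmonized infrastructure.  Block sums treat
nodata members as 0 and report their count.

## Allocation and post-processing

Cell weights above 100 % are capped so they read as an area fraction;
crop growing area is capped-weight × cell area × share.  Crop equipped
area is share × harmonized AEI.  Calibration coefficients
(100 × regional target / regional equipped area) are **not clipped at
100 %**: the source states the expectation AAI ≤ AEI but no clip, and
clipping would silently break regional conservation; coefficients above
100 % therefore pass through and the violation is observable in the
calibration table.  Where a region has zero equipped area but a positive
target, the coefficient is 0, the row is flagged and the target mass is
reported as unallocated — inventing a spatial pattern for it would be
invisible corruption.  The same flag-and-report choice covers regions
whose reference crop table is all zero (their annual totals cannot be
split across crops) and the even-split fallback extends the stated
missing-data rule to the zero-sum case so hierarchy conservation always
holds.

Post-processing order is cap first, clamp second, mirroring the method's
narration: cells whose crop sum exceeds `cap_ha` (default: the cell
area, 100 ha) are scaled by cap/sum, preserving crop ratios; then AAI is
clamped to the growing area per crop and rainfed = growing − AAI, so the
product identity AAI + RF = GA holds exactly.  Clipped and clamped mass
is surfaced in diagnostics per region/crop/year and never redistributed
to other cells, so any conservation loss is measurable rather than
hidden.  Cells outside every region are nodata in all outputs.  The
written UAA layer is the crop-covered agricultural area (the crop sum of
growing areas), which keeps UAA = Total_IR + Total_RF exact even when
per-cell crop shares sum below 1.

## The synthetic world

The generator inverts the model: it draws the inputs, computes a
per-cell truth through the same harmonization formulas the pipeline
applies, and then *derives the regional statistics from the truth* by
aggregation, so the pipeline's targets are self-consistent and the full
build must recover the truth cell-for-cell (the round-trip test passes
at machine precision; the tolerance asserted is 1e-6 relative).

Choices, made once:

* **Geometry.** Regions are rectangular tiles (NUTS1 row bands split
  into NUTS2 column strips), carried as a membership raster — the form
  the pipeline actually consumes.  The fine grid doubles as the 1-km
  target grid (identity resampling); `target_offset_cells` shifts the
  target half a cell to exercise true bilinear weights.  Coarse cells
  nest 8 × 8 fine cells so block-sum oracles are exact.
* **Magnitudes.** Cell weights are uniform on 60–110 % (a few cells
  exceed 100 % to exercise the capping rule); fine 2005 AEI is uniform
  on 0–50 % of the cell's agricultural area; the 2005→2010 change ratio
  defaults to a flat 0.9 (equipped area mildly declining), with a
  `smooth` mode drawing a spatially correlated field around that value.
  Crop shares are a symmetric Dirichlet (α = 0.8) with one slack
  component, so per-cell crop sums stay below 1.
* **Irrigation fractions.** The within-region fraction factors as
  p[region, crop, year] = q[region, crop] · m[NUTS1, year] with
  q ~ U(0.05, 0.95) and m ~ U(0.5, 1).  The factorization (and crop
  shares held constant across years) is exactly what makes the
  reference-year proportions time-valid, i.e. the regime in which the
  method's assumptions are true and recovery can be exact.  Worlds
  violating these assumptions would measure assumption error, not
  implementation error, and are deliberately not generated.
* **Determinism.** One seed feeds independent child streams per
  component; survey sampling takes its own seed, so the world is
  invariant to the number of points drawn.
* **Cap trigger.** On request the centre cell's equipped area is
  rescaled so its unconstrained crop-summed allocation reaches 1.5 × the
  capacity in the reference year, and everything downstream of that cell
  is rebuilt deterministically — used by the capacity-cap checks.

Survey points emulate a field survey: one point at the centre of each
sampled agricultural cell, crop drawn from the cell's share
distribution, irrigated (water-management code 1 vs 5) as a Bernoulli
draw of the cell's irrigated fraction of that crop's growing area, land
use U111.  What the synthetic world does **not** emulate: realistic
geography or crop frequencies, survey stratification weights, non-binary
water-management labels (codes 2, 3, 8 never occur in generated points,
though the classifier handles them), reporting biases, and NUTS boundary
changes.  Passing tests therefore demonstrate correctness of the
machinery under the method's assumptions, not the accuracy of the method
on real European data.

## Validation statistics

Point and raster sides are aggregated to square blocks (half-open
intervals, a point on a shared edge belongs to the block to its
lower-left in index space; partial edge blocks use the cell area they
actually cover).  The paired 0.3 % filter is **inclusive** (the source
states both "below … excluded" and "greater than … retained"; ≥ is
chosen and the threshold is configurable).  Water-management code 2
("potential irrigation") is excluded from the irrigated set by default
and available behind `include_potential`, reflecting an internal
inconsistency in the source's description.  Years are pooled after
per-year block aggregation (pre-pooling would mix survey epochs inside a
block).  Agreement per crop is the Pearson correlation and the OLS slope
of the raster side on the point side, with a two-sided p-value from the
correlation's t statistic on n − 2 degrees of freedom and the usual
significance stars; groups with fewer than 3 blocks or zero variance are
flagged rather than reported.

## Problem sizes and defaults

The reference recovery scenario used by the acceptance tests is a
64 × 64 km world with 16 crops, 3 NUTS1 × 2 NUTS2 regions and 3 years —
small enough to run in seconds while exercising every stage, and chosen
as the package's standard demonstration size.  The acceptance script
uses a 32 × 32 cap-trigger world with 8 crops for the capacity check.
The bilinear oracle runs 100 random grid/offset pairs at 1e-12; the
estimator self-consistency check samples every cell of an
equipped-dominated 64 × 64 world so that Bernoulli noise, the only
disturbance, stays below the regional signal.

## Known limitations

* Planar grids only; no geographic (arc-minute) grids, no geodetic
  reprojection, and no area-weighted (conservative) resampling — the
  bilinear scheme does not conserve mass under spatially varying ratio
  fields except at coarse scale in the flat-ratio case.
* Capped regions cannot meet their regional targets; the shortfall is
  quantified in diagnostics but not corrected.
* Whether the real production chain clipped calibration coefficients
  above 100 % is unknown; this implementation tolerates them.
* The uniform-irrigation-percentage assumption is structural: within a
  region the spatial pattern of AAI is exactly proportional to equipped
  area times crop share, which real irrigation need not follow.
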