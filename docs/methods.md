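# Methods

## The classification model

The map assigns every 10 m pixel one of six codes: non-WUI (0), intermix WUI
dominated by forest/shrubland/wetland (1) or by grassland (2), interface WUI
with the same split (3, 4), and masked water (255).  The decision sequence
is: mask water → candidate test (aggregated building share > 0.5 %) → urban
character test (> 15 %, blocks intermix only) → intermix test (wildland
share ≥ 50 %, grassland included) → interface test (within 2,400 m of a
large vegetation patch).  Codes are mutually exclusive by construction; the
rule table is purely per-pixel once the focal shares and proximity masks are
computed, which is what makes brute-force per-pixel oracles possible.

Two conventions in the rule table were genuinely open and are fixed as
follows:

- *Urban-character pixels remain eligible for interface WUI.*  The urban
  exclusion is stated only for intermix; conceptually the interface class
  describes settled land abutting wildland regardless of density.
- *The 50 % intermix split always uses the grassland-included vegetation
  share.*  The grassland-excluded reclassification exists to build the
  second set of interface patches; intermix subclassing instead compares the
  kernel shares of the two cover groups directly, with ties going to
  forest/shrubland/wetland (deterministic, and conservative for fire
  relevance).  When both patch variants are within reach, interface is
  subclassed F/S/W.
- *Dominant cover is evaluated over the 500 m kernel.*  At 10 m a pixel has
  exactly one cover class, so "dominant cover within a pixel" is read as
  dominant cover within its aggregation window.

## Thresholds and defaults

| parameter | default | unit | meaning |
|---|---|---|---|
| `kernel_radius_m` | 500 | m | focal aggregation radius |
| `candidate_min_building_share` | 0.005 | fraction | WUI candidacy (strict >) |
| `urban_character_share` | 0.15 | fraction | intermix exclusion (strict >) |
| `intermix_min_veg_share` | 0.5 | fraction | intermix vegetation floor (≥) |
| `patch_share_threshold` | 0.75 | fraction | patch binarisation (strict >) |
| `patch_min_area_km2` | 5 | km² | large-patch minimum (≥, configurable) |
| `interface_distance_m` | 2400 | m | ember-transport distance (≤) |
| `slope_max_deg` | 25 | ° | building-share zeroing (strict >) |
| `water_max_pct` | 20 | % of year | building-share zeroing (strict >) |
| `building_min_pct` | 20 | % | per-pixel reliability floor (zeroed unless >) |
| `connectivity` | 8 | — | patch labeling adjacency |

Strictness follows the wording of each rule ("more than", "greater than or
equal"); boundary cases are pinned by unit tests.  The large-patch
comparator is ≥ (the two circulating phrasings, "at least" and "more than",
disagree; ≥ is the default and a strict variant is available).

The patch rule needs an aggregation convention on a 10 m binary mask: the
75 % share is evaluated on the same 500 m focal share used everywhere else,
then binarised and labeled with 8-connectivity.  This reuses the workflow's
only stated aggregation scale rather than inventing a second one.

## Numerical choices

- **Focal means** use an exact column-run decomposition of the circular
  kernel (one vertical moving sum per distinct run height, then shifted
  adds): O(N·kernel width), no FFT round-off.  Window sums of binary masks
  and integer-percent rasters are therefore exactly representable, which
  makes threshold comparisons reproducible to the bit across
  implementations.  Percent rasters are averaged in percent and divided by
  100 afterwards for the same reason.
- **Edges and nodata**: the mean's denominator shrinks to the in-bounds,
  non-nodata cells, so shares near scene edges remain unbiased means of
  observed pixels.  Kernel membership is by pixel-center distance.
- **Proximity** uses an exact Euclidean distance transform (center-to-center
  distances); squared distances are integers in units of the squared pixel
  size, so the ≤ 2,400 m comparison has no representational ambiguity.
- **Areas** are pixel counts times nominal pixel area unless an
  area-correction factor raster is supplied, in which case per-pixel
  corrected areas are accumulated.  A factor of 1 reproduces nominal
  statistics exactly.
- **Tiling**: wildland masks, focal means and the rule table are tiled with
  a margin of max(kernel radius, interface distance), which provably equals
  the untiled run; patch labeling and the distance transform always run on
  the full scene because connected components are nonlocal — no fixed
  overlap bounds a patch's extent.  A tiled-vs-untiled equality test pins
  this contract.
- **Eq-style sample size** applies a ceiling after subtracting 1e-9, so
  designs whose analytic value is an integer (uniform U = 0.75, S = 0.01 →
  1875) are not bumped up by floating-point noise.

## Exposure and summary conventions

Fire detections are filtered to vegetation fires whose enclosing 1 km cell
is majority (> 50 %) wildland — the cell stands in for the sensor footprint,
whose true scan-angle-dependent geometry is out of scope.  Presence is
binary per 1 km cell ("at least one fire"), cells follow the half-open
`[x0, x0 + 1000)` convention, and everyone living in a fire cell counts as
affected.  Wildfire area in the WUI is attributed by pixel-area share within
fire cells; affected people are attributed to WUI classes by their 100 m
population cell's majority WUI class, and biomass by the 300 m cell's
majority class (ties to the lower code).  Biomass carbon converts to
dry-matter mass at a factor of two, 1 Mg = 1000 kg, pixel areas in ha.
Zone membership is pixel-center-in-polygon; hotspot border distances default
to minimum boundary-to-boundary polygon distance when no matrix is given.

The published total of 1,504 validation sites per world region is not
derivable from the design formula with a uniform target user's accuracy of
0.75 (which yields 1875 for any W); class-specific targets were presumably
used.  The design object therefore accepts either the formula's n or an
explicit override, and 1,504 over five classes allocates as 301/301/301/301/300.

## The synthetic landscapes

The random scenario emulates the structure of the real input stack: land
cover as a quantile-mapped autocorrelated field (realized class fractions
match the configured mixture almost exactly — the default is a temperate
mosaic with 34 % tree cover, 16 % grassland, 18 % cropland, 5 % water),
building share decaying around settlement seeds (peak 85 %, e-folding
≈ 400 m, quantised to whole percent like the source product, zero on water),
population disaggregated proportionally to built-up surface at 100 m
(≈ 4,000 people per built-up km²), biomass as a smooth 0–120 MgC ha⁻¹ field
damped outside wildland at 300 m, and vegetation-fire points from a Poisson
process (0.5 events km⁻², emulating an 18-year record) over
majority-wildland 1 km cells, plus a few static-source detections as
negative cases for the filter.  Default scene: 6 km × 6 km at 10 m, chosen
so every coarser grid (100 m, 300 m, 1 km) tiles it exactly.

What the generator does **not** emulate: class confusion and omission errors
of real land-cover/building products, sensor artifacts, projection-induced
area distortion (an area-factor raster can be supplied but is synthetic),
real settlement morphology, or fire spread.  Passing tests therefore
demonstrate the correctness of the *procedure* — operators, rule table,
bookkeeping — not the accuracy of any real-world WUI map, which is governed
by input-data quality.

The analytic-strip scenario exists because its correct classification can
be computed by an independent oracle: all layers vary only along x, so each
focal mean collapses to per-row 1-D convolutions with integer weights, patch
qualification is area arithmetic on the thresholded share, and proximity
comes from KD-tree nearest-neighbour distances.  The production pipeline is
required to reproduce this truth pixel-for-pixel, including the null
variants (forest block under 5 km² → no interface; building share at or
below the 20 % reliability floor → no WUI at all).

## Problem sizes

Tests run scenes up to 1000 × 1000 pixels (10 km × 10 km at 10 m) for the
known-truth pipeline check and 200 × 200 for brute-force oracle comparisons;
the acceptance script uses the 10 km strip and a 6 km random scene.  These
sizes exercise every code path (multiple patches, scene edges, all six
classes, coarse-grid resampling) while keeping a full run in seconds; the
operators are linear in pixel count times kernel width and scale to larger
scenes without modification.

## Known limitations

- Only integer-ratio, shared-origin grid pairs can be resampled; arbitrary
  reprojection is out of scope by design.
- Cross-scene (multi-tile) patch stitching is not implemented; patches are
  global within a scene but scenes are independent.
- Fire footprints are points in cells; no swath-geometry or small-fire
  omission modelling.
- Hexagonal display binning and degree-of-urbanisation / income-class
  cross-tabulations are not implemented (any categorical raster can be
  summarised as a generic zone layer instead).
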