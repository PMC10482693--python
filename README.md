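# wuimap

Raster tools for mapping the **wildland–urban interface (WUI)** — the zone
where buildings and wildland vegetation meet or intermingle — and for the
summary and validation statistics that go with such a map: population,
biomass and wildfire exposure inside the WUI, and area-adjusted accuracy
assessment of the final product.

The package is aimed at landscape- and fire-ecology researchers who want to
run a globally consistent, raster-based WUI workflow on their own land-cover
and built-up-surface grids (10 m-class products such as ESA WorldCover and
GHS-BUILT-S), or to study the behaviour of the mapping rules themselves on
controlled synthetic landscapes.

## The mapping rules

All aggregation uses a circular moving window of radius *r* = 500 m.
Writing *b* for the built-up surface share aggregated over the window,
*v* for the wildland vegetation share (tree cover, shrubland, herbaceous
wetland, mangroves, moss/lichen, and optionally grassland), a pixel is

- a **candidate** WUI pixel if *b* > 0.5 %;
- of **urban character** if *b* > 15 % (dense suburbs: managed vegetation
  and fire control, so never *intermix*, though still eligible for
  *interface*);
- **intermix WUI** if it is a candidate, not urban, and *v* ≥ 50 %;
- **interface WUI** if it is a candidate, not intermix, and lies within
  2,400 m (the ember-transport distance) of a *large vegetation patch*:
  a connected region with focal vegetation share > 75 % covering at least
  5 km² (the minimum size excludes urban parks);
- **non-WUI** otherwise; open water is masked.

Before aggregation the built-up share is set to zero where slope > 25°,
where intra-annual surface-water occurrence > 20 %, or where the pixel's own
share is ≤ 20 % — all common sources of false building detections.  Intermix
and interface are each split into *forest/shrubland/wetland-dominated* vs
*grassland-dominated* subclasses (grassland ranges from wild steppe to
near-agricultural pasture, so the two patch variants — grassland included or
excluded — are mapped separately).  The classical US threshold of
6.17 buildings km⁻² is **not** a rule here: with area-share building data it
is replaced by the 0.5 % aggregated-share candidate threshold.

Validation follows the standard stratified design: the number of sites

    n = ( Σᵢ Wᵢ √(Uᵢ(1−Uᵢ)) / S )²

for mapped area proportions *Wᵢ*, target user's accuracies *Uᵢ* and target
standard error *S*, with equal allocation across classes, and Olofsson-style
area-adjusted overall/user's/producer's accuracies (cell proportions
p̂ᵢⱼ = Wᵢ nᵢⱼ / nᵢ·).

## Worked example

The analytic-strip scenario — a 5 km-wide forest block abutting uniformly
settled cropland (30 % built-up share) on a 10 km × 10 km scene — has a
classification that is computable independently of the raster operators, so
the pipeline can be checked pixel-for-pixel:

```python
import numpy as np
from wuimap import LandscapeConfig, generate_analytic_strip, map_wui
from wuimap.classify import WUI_CLASS_NAMES

cfg = LandscapeConfig(n_rows=1000, n_cols=1000, scenario="analytic_strip")
stack = generate_analytic_strip(cfg, forest_width_m=5000, building_pct=30)
wui = map_wui(stack.landcover, stack.building_share,
              stack.slope_deg, stack.water_occurrence_pct)

for code, count in zip(*np.unique(wui.values, return_counts=True)):
    print(f"{WUI_CLASS_NAMES[int(code)]:>20s}: {count * 1e-4:7.2f} km2")
print(f"truth agreement: {(wui.values == stack.truth['class_map']).mean():.1%}")
print(f"large patch area: {stack.truth['patch_area_km2']:.2f} km2")
```

prints

```
             non_wui:   73.50 km2
        intermix_fsw:    4.51 km2
       interface_fsw:   21.99 km2
truth agreement: 100.0%
large patch area: 47.99 km2
```

The forest qualifies as a large patch (47.99 km² of > 75 % focal vegetation
share — less than the nominal 50 km² because the share rolls off near the
boundary).  Cropland within 2,400 m of it becomes interface WUI
(10 km × 2.4 km minus edge effects ≈ 22 km²), a narrow band straddling the
boundary where the window mixes ≥ 50 % forest with > 0.5 % buildings becomes
intermix, and the far cropland — more than 2,400 m out — stays non-WUI.

The same functions run from the shell: `wui simulate`, `wui preprocess`,
`wui map`, `wui fire`, `wui summarize`, `wui validate design|accuracy` and
`wui run --config pipeline.yaml` (see `wui --help`).

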