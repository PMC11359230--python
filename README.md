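# burnmap

Automatic burned-area and fire-severity mapping from pre/post-fire
SuperDove-class multispectral imagery.

CubeSat constellations image fire-affected landscapes almost daily at 3 m
resolution, but their sensors lack the short-wave infrared (SWIR) band that
the standard Normalized Burn Ratio (NBR) workflow relies on. `burnmap`
implements an SWIR-free alternative aimed at emergency-mapping analysts and
fire-ecology researchers, particularly for small fires: vegetation-index
differencing between a pre-fire and a post-fire scene, followed by
unsupervised clustering, so no fixed index threshold is ever chosen.

## Method

For co-registered pre- and post-fire surface-reflectance scenes the tool:

1. computes vegetation indices (NDVI, YNDVI, GNDVI1/2, WDRVI, SAVI, EVI,
   GEMI, SR, MSR) and their pre−post differences, e.g.
   dNDVI = NDVI_pre − NDVI_post with NDVI = (NIR − RED)/(NIR + RED);
   vegetation loss makes the difference positive;
2. screens indices by their mean difference inside a delimitation mask and
   uses a selected pair — by default (dNDVI, dYNDVI), where YNDVI
   substitutes the yellow band for red — as a 2-D feature vector per pixel;
3. separates burned from unburned pixels with **bisecting K-means**
   (K = 2): starting from one cluster, the cluster with the highest sum of
   squared errors (SSE) is repeatedly split by two-cluster K-means; the
   cluster with the larger combined index loss is the burned area;
4. stratifies the burned pixels into four ordered severity classes
   (negligible-to-slight, moderate, high, destroyed) with plain K-means
   (K = 4), classes ordered by centroid index loss;
5. converts pixel counts to hectares with per-pixel slope weights
   1/cos(slope) derived from a DEM (Horn 3×3 slope, bilinear resampling to
   the scene grid), and reports the discrepancy against a reference
   delimitation (e.g. a Copernicus EMS product) as
   100 · (reference − estimated) / reference.

A synthetic-scene generator produces paired scenes with a contiguous burned
region of graded severity, known noise, and DEMs of analytic slope, so the
whole pipeline is testable without licensed imagery.

## Worked example

```python
from burnmap import (ScenarioConfig, generate_scene_pair, generate_dem,
                     compute_index, index_difference, map_burned_area,
                     map_severity, slope_weights, weighted_area,
                     severity_percentages, AreaReport)

cfg = ScenarioConfig(n_rows=200, n_cols=200, burned_fraction=0.2,
                     noise_sigma=0.02, seed=42, dem_mode=("tilted", 30.0))
pre, post, truth = generate_scene_pair(cfg)
d1 = index_difference(compute_index(pre, "NDVI"), compute_index(post, "NDVI"))
d2 = index_difference(compute_index(pre, "YNDVI"), compute_index(post, "YNDVI"))
mask, _ = map_burned_area(d1, d2, seed=1)
sev, _ = map_severity(d1, d2, mask, seed=1)
dem, dem_grid, _ = generate_dem(cfg)
w = slope_weights(dem, dem_grid, cfg.grid)
report = AreaReport.build(weighted_area(mask, weights=w),
                          truth.true_burned_area_ha,
                          severity_percentages(sev, w))
print(report.to_text())
```

prints

```
Burned-area report
==================
Estimated burned area : 8.31 ha
Reference delimitation: 8.31 ha
Difference            : 0.00 ha (0.04%)
Severity shares of burned surface:
  negligible to slight damage  22%
  moderately damaged           27%
  highly damaged               28%
  destroyed                    23%
```

The estimated burned surface (slope-corrected, on uniformly 30°-tilted
terrain) matches the generator's analytic truth of 8.31 ha to 0.04%, and
the four severity shares are the surface fractions of each damage class
within the burn scar. On this scenario the burned/unburned pixel accuracy
against the ground-truth mask is 0.9999.

The same run from a shell, via GeoTIFF files:

```sh
burnmap simulate --out-dir fx --rows 200 --cols 200 --seed 42 --dem-mode tilted:30
burnmap run --pre fx/pre.tif --post fx/post.tif --dem fx/dem.tif --out-dir out
```

which writes `burn_mask.tif`, `severity.tif`, `slope.tif`, `screening.csv`,
`report.json` and `run_log.json`. See `examples/` for narrative scripts
covering index screening, mapping and slope-corrected areas.

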