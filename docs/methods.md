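# Methods

## Problem setting and model

`burnmap` maps the extent and severity of a wildfire burn scar from two
co-registered surface-reflectance scenes, one acquired before and one after
the fire, on sensors without a SWIR band (SuperDove-class, 8 visible/NIR
bands at 3 m). The working assumption is that fire expresses itself as a
drop in vegetation-index values — chiefly through NIR collapse and red/
yellow brightening of char and exposed soil — so the pre−post difference of
a vegetation index is near zero on unaffected land cover and positive
inside the burn, growing with damage severity.

Rather than thresholding a difference image, both classification steps are
unsupervised:

* **Burned extent.** Each valid pixel contributes a 2-D feature vector of
  two index differences, by default (dNDVI, dYNDVI). Bisecting K-means
  with K = 2 splits the feature cloud; the cluster whose centroid has the
  larger coordinate sum (greater combined index loss) is labeled burned.
  Using two indices rather than one adds a consistency requirement — a
  pixel must lose both red-referenced and yellow-referenced greenness —
  which suppresses single-band radiometric artifacts.
* **Severity.** Plain K-means with K = 4 runs on the burned pixels only.
  Clusters are ranked by centroid coordinate sum and mapped to the four
  ordered damage classes (negligible-to-slight, moderate, high,
  destroyed). The class boundaries therefore adapt to each fire instead of
  being fixed index thresholds.

Surface areas account for terrain: a pixel on slope θ represents a true
ground surface of pixel_area / cos θ. Slope comes from a DEM via Horn's
3×3 eight-neighbor gradient, resampled bilinearly to scene pixel centers;
burned area is the sum of per-pixel weighted areas in hectares. The
discrepancy against a reference delimitation (an emergency-service product)
is reported as reference − estimated and as a percentage of the reference.

## Algorithms and numerical choices

* **K-means** is Lloyd's algorithm with k-means++-style seeding.
  Seeding draws are made over a lexicographically sorted copy of the data,
  so the partition is invariant to row order for a fixed seed. Convergence
  when the largest centroid movement falls below `tol` (default 1e-6 in
  feature units) or after `max_iter` (default 300) iterations. Empty
  clusters are repaired by donating the point farthest from its centroid
  from a cluster with at least two members; this guarantees the non-empty
  invariant the severity stage needs, including on degenerate all-identical
  inputs. The per-iteration SSE sequence is recorded
  (`ClusterResult.sse_history`) and is non-increasing.
* **Bisecting K-means** starts from one cluster and repeatedly bisects the
  cluster with the highest SSE (ties → lowest cluster id) using the best of
  `n_trial_bisections` (default 5) two-cluster K-means runs with derived
  seeds. Size-1 clusters are skipped in favor of the next splittable one.
  The nearest-centroid property holds within each split; it is not imposed
  globally across the final hierarchy, which is standard for the divisive
  algorithm.
* **Distances** are squared Euclidean on unscaled features: the default
  pair dNDVI/dYNDVI share units and range, so no standardization is
  applied.
* **Degenerate inputs.** Coincident K = 2 centroids (a constant difference
  field) yield a no-burn result flagged `degenerate`. A centroid
  separation below twice the pooled within-cluster spread — the expected
  outcome when clustering pure noise — flags the mask `low_separation`.
  Zero denominators in any index formula produce nodata pixels, never
  clamped values.
* **Index definitions.** MSR is the linear form (NIR/RED − 1)/(NIR/RED + 1)
  (algebraically NDVI); the square-root variant found elsewhere in the
  literature is deliberately not provided as an option — one behavior,
  documented. GEMI uses the canonical two-equation form. GNDVI1/GNDVI2 use
  the two green bands (513–549 nm and 547–583 nm) of the 8-band layout.
  WDRVI's weight `a` defaults to 0.1, configurable in [0.1, 0.2].
* **Slope.** Horn's kernel with edge replication at borders; slope in
  degrees, weights 1/cos(slope). Bilinear resampling is exact on linear
  fields, so tilted-plane DEMs reproduce their analytic slope and area
  factor to 1e-6, which the tests exploit. The DEM must be in a metric CRS
  on the scene's coordinate system; reprojection of geographic DEMs is the
  caller's responsibility (standard GIS tooling), not re-implemented here.
  A missing DEM degrades to planimetric areas with an explicit report flag,
  and partial DEM coverage defaults uncovered pixels to flat with a flag.
* **Grids.** Pixel (0,0) is upper-left, map coordinates refer to pixel
  centers, rows increase southward. Pre/post scenes must share shape,
  pixel size and origin within 1e-6 pixel; the tool aborts rather than
  resampling, so registration errors surface instead of being interpolated
  away. Vector masks rasterize by center containment.
* **Reflectance scaling** defaults to 1e-4 per stored digital number,
  matching integer-stored surface-reflectance products; it is a config
  item because providers differ.

## Synthetic scenes

The generator emulates the data regime the method targets: paired 8-band
3 m scenes with one contiguous burn scar of graded severity.

* The scar is the top `burned_fraction` (default 0.2) of a
  Gaussian-smoothed random field, taken as exactly the top-k pixels so the
  ground-truth count is exact and area assertions are sharp.
* Severity rings are concentric equal-count bands of distance-to-edge
  rank: damage grows toward the core.
* Reflectance is a per-class mean signature plus i.i.d. Gaussian noise
  (default σ = 0.02 reflectance units, drawn independently for the two
  scenes), emulating sensor and radiometric noise.
* DEM modes: `flat`, `tilted(θ)` (exact area factor 1/cos θ) and
  `sinusoidal(A, λ)` (factor by fine midpoint quadrature). The DEM grid is
  30 m with a two-pixel margin beyond the scene so resampled slopes are
  free of border artifacts.

**Signature design.** Healthy vegetation has NDVI ≈ 0.75 (NIR 0.56, RED
0.08); the four severity classes have post-fire NDVI {0.30, 0.20, 0.10,
0.00} at constant NIR + RED, i.e. dNDVI ≈ {0.45, 0.55, 0.65, 0.75}. The
gap between background (dNDVI ≈ 0) and the lightest class is deliberately
kept wider than the spacing between classes. This is not cosmetic: with
equal-area rings, a 2-means split minimizes total SSE, and if the
background-to-lightest gap is comparable to the within-burn spread the SSE
optimum absorbs the lightest ring into the background cluster (e.g. with
post-fire NDVI levels {0.55, 0.40, 0.25, 0.10} the optimal 2-partition
underestimates burned area by ≈ 25% even without noise). The chosen levels
make the true burned/unburned partition the SSE optimum with a comfortable
margin, so recovery failures in tests indicate real defects rather than an
unidentifiable scenario. Post-fire NDVI near zero for the destroyed class
is consistent with charred surfaces.

What the generator does **not** emulate: spatially correlated or
inter-sensor radiometric bias between the two acquisitions, mixed pixels at
the burn edge, clouds/smoke, soil-type variability, and topographic
illumination effects on reflectance. Passing recovery tests therefore
demonstrates the correctness of the machinery under the stated noise model,
not field-accuracy on real imagery, where radiometric inconsistencies are
the dominant error source.

## Default study conditions and problem sizes

End-to-end evaluations use a 300×300 scene (90,000 pixels, 81 ha) with 20%
burned fraction and noise σ = 0.02; under these conditions the pipeline
recovers burned area within 2% of the analytic truth, pixel accuracy
≥ 0.99, and the severity ring ordering exactly (modal recovered class per
ring equals the ring index). Unit and property tests use 40–120 pixel
grids, and the exhaustive clustering oracle enumerates partitions up to
n = 12, K = 3.

## Reporting conventions

Percent discrepancy is relative to the reference area. Severity
percentages are surface-weighted shares of the burned surface (pixel shares
on flat terrain); they are rounded only for display, with unrounded values
retained in the JSON report. The report carries explicit flags
(`no_dem_planimetric_areas`, `partial_dem_coverage`, `low_separation`,
`degenerate`, `severity_skipped`, `degenerate_severity`) so downstream
consumers can distinguish a clean run from a degraded one.

## Known limitations

* No radiometric harmonization between the two scenes is performed; the
  method relies on the chosen index pair being relatively robust to
  radiometric drift.
* No spatial post-processing (morphological cleaning, minimum mapping
  unit) is applied to the burned mask, so estimates differ systematically
  from delimitation products that filter objects by size.
* Severity classes are relative to each fire (clustering), not anchored to
  field-calibrated damage thresholds; cross-fire comparability of class
  boundaries is not guaranteed.
* Imagery reprojection, mosaicking, cloud masking and DEM void filling are
  out of scope; inputs are expected as single co-registered rasters.
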