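# Methods

This note documents the models, conventions and design choices behind the
package, in the spirit of a model-description chapter: what is computed,
under which assumptions, with which defaults, and what the synthetic test
bed does and does not demonstrate.

## Analysis model

The pipeline treats human–wildlife conflict as a land-use conflict: land
that is simultaneously highly suitable (hence "preferred") for wildlife and
for a human use is a potential conflict zone. Three goal-level suitability
surfaces are built on a common set of decision units and overlaid.

**Decision units.** Square units on two nested resolutions, 250 m and
1000 m by default. A 1000 m unit is emitted only where the full coarse
square lies inside protected polygons *and* no part of it is within
`developed_buffer_m` of a developed feature; every other coarse square
decomposes into 250 m units. The tessellation partitions the extent
exactly, so area accounting is conservative by construction. The buffer
defining "near development" is a free parameter (default 2000 m): the
two-resolution scheme is fixed but the proximity rule that switches between
them is a modeling choice, not an observable.

**Cell membership convention.** Cells are half-open, origin at the grid's
upper-left corner, row-major; a raster cell (and any point) belongs to the
unit containing its center. One stated convention everywhere avoids
double-counting at unit borders. Because units are aligned with the fine
grid, zonal aggregation reduces to exact block statistics.

**Criterion transforms.** Five transforms cover every sub-objective:

| transform | input | per-unit value |
|---|---|---|
| `distance` | vector layer | zonal mean of the planar Euclidean distance surface (m), then 1–9 rescale (inverted for accessibility/proximity criteria) |
| `slope` | DEM raster | zonal mean of finite-difference slope (degrees), rescaled (inverted: flatter is better) |
| `identity` | continuous raster | zonal mean, rescaled |
| `reclass_table` | categorical raster | zonal majority class mapped through an explicit class → score table (every class present must be mapped) |
| `buffer_exclusion` | vector layer | 1 if the unit centroid is within `buffer_m` of a feature, else 9 |

Distances are planar in the projected CRS (the data model assumes a metric
UTM projection); there is no geodesic option. Development constraints are a
`buffer_exclusion` criterion on protected polygons with a 1 m buffer —
centroid-in-polygon membership expressed through the same transform — so
that "remove the constraints layer" in sensitivity analysis is an ordinary
weight-tree edit rather than a special masking path.

**Standardization.** Criterion and goal scores are affinely rescaled so the
observed minimum maps to 1 and the maximum to 9 (reversed when inverted).
Scores stay *continuous* in [1, 9]; rounding to integers before preference
binning would only discard information the Jenks classifier uses. A
constant input rescales to the midpoint 5 with a logged warning instead of
erroring, so a degenerate layer cannot abort a run. Only the goal-level
composite is re-standardized after aggregation; objective-level composites
keep the scale their children share (re-standardizing at every tier would
make sibling weights scale-dependent).

**Aggregation.** Weighted linear combination with weights summing to 1
within 0.01 — the tolerance accommodates weight tables printed at two
decimals (0.33/0.34/0.33). Nodata in any child propagates to the parent.
Weights can also be derived from a reciprocal pairwise matrix by the
Analytic Hierarchy Process: principal eigenvector via power iteration
(tolerance 1e-10, ≤ 10^4 iterations), λ_max from the mean Rayleigh ratio,
CI = (λ_max − n)/(n − 1), CR = CI/RI with the standard random-index table
(0, 0, 0.58, 0.90, 1.12, 1.24, 1.32, 1.41, 1.45 for n = 1..9). CR ≤ 0.1 is
accepted; larger CR returns a result flagged inconsistent rather than
failing, leaving the decision to the analyst.

**Default hierarchies.** The shipped YAML encodes the study's weight
tables: agriculture = 0.7 crop + 0.3 livestock; crop physical 0.60
(existing farms 0.30, soil condition 0.20, terrain 0.20, constraints 0.30)
and economic 0.40 (four criteria at 0.25); livestock physical 0.40,
economic 0.30 (transport 0.33, water 0.34, 300 m cattle-post buffer 0.33)
and wildlife condition 0.30 (lion 0.50, leopard 0.20, hyaena 0.20, elephant
0.10, *inverted*: predator habitat depresses livestock suitability);
settlement physical 0.50 (population density 0.40, terrain 0.30,
constraints 0.30) and economic 0.50 (roads 0.50, existing settlements
0.50). Two interpretations were left open by the source material and
resolved here: market accessibility reuses settlement centroids as market
proxies (no market layer exists), and "existing use" criteria are
inverted-distance scores to the existing features (the stated intent —
favor continuity around existing farms/posts/settlements — without a
printed formula). Terrain characteristics and soil condition are small
sub-trees (slope + land-cover; pH + root-zone depth + drainage) with equal
or near-equal internal weights.

**Wildlife goal.** The wildlife surface is an ecological input, not a
weight hierarchy: per-species habitat rasters are combined with a cell
statistic (unweighted mean by default, max optionally), zonal-averaged and
rescaled. Refitting the underlying habitat models is out of scope.

**Preference and conflict.** Each goal's unit scores are classified into
k = 3 preference levels by exact Jenks natural breaks. The conflict rules
are applied literally at matched levels; a triple such as WL=3, AG=2
matches no rule and maps to *none*. This is counterintuitive but
deliberate: the rule set as printed encodes matched-level overlap only, and
no reinterpretation is attempted. Consequences: (i) "low conflict" fires
when *all* preferences are low; (ii) a unit with nodata wildlife preference
can never be in conflict. Area accounting uses true unit-polygon areas
(robust to future non-square cadastral units), reported in km² with shares
at both integer and one-decimal precision.

**Jenks implementation.** Fisher's O(k·n²) dynamic program on sorted data,
ties broken toward the lowest break values. Above 4 000 values the breaks
are fit on a seeded random subsample of 4 000 and applied to all values —
break placement for the smooth, unimodal score distributions produced here
is insensitive to sampling at that size, and the subsample is always a
subset of the data so no class can be empty. The exact program is used
whenever n ≤ 4 000, and the test suite checks it against exhaustive
partition search.

**Map-removal sensitivity.** One factor group at a time is deleted from the
agriculture and settlement trees (the wildlife input carries none of the
five factors); surviving sibling weights are renormalized proportionally —
the least-informative rebalancing, preserving relative importance and
reducing to weight 1.0 for a sole survivor. Nodes left childless are
removed recursively the same way. Jenks breaks are refit within each
scenario: a removal is a full rerun, and refitting is the only way a
removed layer can move class boundaries. Change metrics are reported as
km² differences (whole km² in reports) and percent of the base class area
(one decimal); a zero base area makes the percent change undefined and it
is reported as missing rather than inflated.

## Synthetic landscape generator

The generator emulates the *statistical structure* the analysis assumes,
not any real region:

* **Continuous fields** (soil pH 6.5 ± 0.7, root-zone depth 80 ± 25 cm,
  drainage class 3 ± 1, DEM 1000 ± 15 m, species habitat 0.5 ± 0.2 clipped
  to [0, 1]) are Gaussian-filtered white noise, kernel σ = range/2,
  affinely rescaled to the exact requested mean/sd. Correlation decays like
  exp(−d²/range²·…) and is ≈ 0 beyond 3 range lengths. Default range 5 km
  (habitat 10 km — wildlife suitability varies more smoothly than soils).
* **Roads** are piecewise-linear paths crossing the extent; **settlements**
  sit jittered on road vertices; **farms** are 1 km² blocks of which a
  fraction `farm_wildlife_overlap` (default 0.6) is placed on top-tercile
  cells of the combined habitat surface (choosing, among candidate cells,
  the one nearest a road), the rest along roads; **cattle posts** scatter
  around farms; **boreholes** split between development-adjacent and
  dispersed. **Protected areas** are an edge strip with exactly the
  requested area fraction (default 0.30).
* **Land cover** is a thresholded random field (grassland/shrubland/
  woodland/bare at 35/30/25/10 %) overridden to cropland under farm
  polygons and built-up within 500 m of settlements, guaranteeing
  vector/raster consistency.
* One global seed drives fixed per-layer seed offsets, so layers are
  independently reproducible and adding a layer never perturbs the others.

Default scene scale: 50 × 50 km at 250 m (200 × 200 cells, ~31 000 decision
units) — large enough for stable Jenks classes and spatial structure, small
enough that a full five-scenario sensitivity run completes in seconds.
Replicate-based properties (e.g. the monotone response of high-conflict
area to `farm_wildlife_overlap`) use five seeds per condition.

**What passing tests do not show.** The generator makes no attempt to match
real distributions of any study region (rainfall, terrain ruggedness,
actual road topology), produces rectangular protected areas and square
farms, and ties habitat to nothing but smoothed noise. Pipeline properties
demonstrated on it (area conservation, determinism, directional responses)
are properties of the *method*; magnitudes of conflict shares or
sensitivity changes on synthetic scenes are not predictions for any real
landscape.

## Numerical and degenerate-input policies

* Nodata (−9999 sentinel) propagates through slope stencils, WLC, and
  zonal statistics; it is never interpolated into valid cells when
  resampling (bilinear falls back to the nearest valid sample).
* Categorical rasters refuse bilinear resampling and use majority zonal
  statistics.
* Constant rescale input → midpoint 5 with a warning (see above).
* Jenks requires at least k distinct values; preference binning therefore
  rejects goal surfaces with fewer than 3 distinct scores instead of
  silently producing empty classes.
* Power iteration on a positive reciprocal matrix converges to the Perron
  eigenvector; order ≤ 2 matrices have CR ≡ 0 by definition.
* All file formats are plain text (ASCII grid, GeoJSON, CSV, YAML); float
  formatting is fixed so identical runs produce byte-identical artifacts.

## Known limitations

* No reprojection: all layers must already share a projected metric CRS.
* Mixed-level conflict (e.g. WL=3 with AG=2) registers as none — a faithful
  but debatable reading of the rule set; analysts wanting graded overlap
  should edit the rules, not reinterpret the output.
* The preference binning is relative (Jenks on the realized score
  distribution), so conflict shares are not comparable across scenes with
  different score distributions.
* Sensitivity covers map removal only; weight-perturbation and
  variance-based global sensitivity are out of scope.
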