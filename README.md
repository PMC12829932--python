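# lucis

Spatially explicit identification of human–wildlife conflict (HWC) by
**land-use conflict analysis**: hierarchical multi-criteria suitability
modeling for competing land uses, preference overlay, and map-removal
sensitivity analysis, with a fully seeded synthetic-landscape generator so
the whole pipeline runs end to end without any proprietary GIS layers.

The package is aimed at conservation planners and landscape ecologists who
need a transparent, reproducible alternative to desktop-GIS workflows for
questions like: *where will expanding farms and settlements collide with
wildlife corridors, and which input layers drive that answer?*

## Method

The analysis follows the LUCIS (Land Use Conflict Identification Strategy)
five-step structure — goals, data inventory, suitability, preference,
conflict — for three competing goals: **agriculture** (crop farming 0.7 /
livestock rearing 0.3), **human settlement**, and **wildlife** (an external
habitat-suitability surface, combined across species).

1. **Decision units.** The study extent is tiled with a multi-resolution
   square grid: 250 m cells within a configurable buffer of developed
   features (farms, settlements), 1000 m cells inside protected zones, 250 m
   elsewhere. Units partition the extent exactly.
2. **Criterion scores.** Each sub-objective (distance to roads/water/farms,
   slope, land-cover reclassification, soil attributes, regulatory buffers
   such as the 300 m cattle-post rule, protected-area constraints) is
   evaluated per unit and standardized linearly to the suitability scale
   s ∈ [1, 9] (9 = most suitable; cost-like criteria inverted).
3. **Weighted linear combination.** Scores aggregate bottom-up through a
   three-tier weight hierarchy, S = Σᵢ wᵢ·sᵢ with Σwᵢ = 1 at every node;
   the goal-level composite is re-standardized to [1, 9]. Weights may be
   assigned directly or derived with the Analytic Hierarchy Process
   (principal eigenvector of a reciprocal pairwise matrix; consistency
   ratio CR = CI/RI, flagged when CR > 0.1).
4. **Preference and conflict.** Each goal's suitability is rebinned to
   preference levels 1–3 with Jenks natural breaks (exact Fisher dynamic
   program minimizing within-class SSE). Conflict follows the literal
   matched-level rules — high: WL=3 ∧ (AG=3 ∨ HS=3); moderate: WL=2 ∧
   (AG=2 ∨ HS=2); low: WL=1 ∧ (AG=1 ∨ HS=1); anything else: none.
5. **Sensitivity.** One-at-a-time map removal: each of five factor groups
   (existing land use, terrain characteristics, road accessibility, water
   proximity, development constraints) is deleted from the human-goal
   hierarchies, surviving sibling weights renormalized proportionally, the
   full pipeline rerun, and per-class area changes (km², %) reported.

All I/O is plain text: ESRI ASCII grids for rasters, GeoJSON for vectors,
CSV/YAML for tables and manifests.

## Worked example

```python
import numpy as np
from lucis import (
    LandscapeConfig, generate_scene, build_decision_units, FeatureSet,
    load_hierarchies, build_goal_suitability, bin_preferences,
    overlay_conflict, summarize_areas,
)

cfg = LandscapeConfig(seed=7, extent=(0, 0, 20_000, 20_000), n_farms=15,
                      n_settlements=5, n_boreholes=10, n_cattle_posts=6,
                      n_roads=3, field_range_m=3_000, farm_wildlife_overlap=0.6,
                      protected_fraction=0.25)
scene = generate_scene(cfg)
developed = FeatureSet(scene.vectors["settlements"].geometries
                       + scene.vectors["farms"].geometries)
units = build_decision_units(cfg.extent, developed,
                             scene.vectors["protected_areas"],
                             developed_buffer_m=2_000)
print(f"{units.n_units} decision units "
      f"({(units.df.res_class == 'coarse').sum()} coarse, "
      f"{(units.df.res_class == 'fine').sum()} fine)")

trees = load_hierarchies()
levels = {}
for i, goal in enumerate(("wildlife", "agriculture", "settlement")):
    suit = build_goal_suitability(goal, scene, units, trees.get(goal))
    levels[goal] = bin_preferences(suit, rng=np.random.default_rng(i))

cmap = overlay_conflict(levels["wildlife"], levels["agriculture"],
                        levels["settlement"], units)
print(summarize_areas(cmap, units).to_frame().to_string(index=False))
```

prints

```
5815 decision units (39 coarse, 5776 fine)
   class  area_km2  share_pct
    none     182.9       45.7
     low      68.2       17.0
moderate     123.8       30.9
    high      25.1        6.3
```

i.e. on this 20 × 20 km synthetic landscape, 6.3 % of the area is land that
both wildlife and a human use prefer at the highest level — the candidate
high-conflict zone — while 45.7 % shows no matched-level overlap at all.
Because 60 % of the farms were deliberately sited inside the top tercile of
the wildlife-habitat surface (`farm_wildlife_overlap=0.6`), high-conflict
units concentrate around those farms.

The same analysis is available as a CLI:

```sh
lucis all --config my_run.yaml --seed 42 --outdir out/
lucis sensitivity --config my_run.yaml --outdir out/   # reuses out/scene
```

which persists the scene, per-unit scores, preference levels, conflict map,
area accounting, the sensitivity report and a provenance manifest
(config hash, seed, checksums) under `out/`.

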