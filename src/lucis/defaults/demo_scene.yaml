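# Demo run configuration: a 50 x 50 km synthetic scene at 250 m resolution
# (200 x 200 cells) with farms sited preferentially inside the wildlife
# corridor (farm_wildlife_overlap 0.6), a 30% protected strip and clustered
# development along four road corridors.
scene:
  synthetic:
    extent: [350000.0, 7950000.0, 400000.0, 8000000.0]
    cell_size_m: 250.0
    n_roads: 4
    n_settlements: 8
    n_farms: 40
    n_boreholes: 25
    n_cattle_posts: 15
    protected_fraction: 0.30
    field_range_m: 5000.0
    farm_wildlife_overlap: 0.6
decision_units:
  fine_m: 250.0
  coarse_m: 1000.0
  developed_buffer_m: 2000.0
hierarchies: null      # packaged defaults (the printed weight tables)
factor_groups: null    # packaged defaults (the five named factors)
wildlife_combine: mean
seed: 42
report_precision: 1
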