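# Default goal hierarchies: goals -> objectives -> sub-objectives with the
# study's weight tables.  Agriculture splits 0.7 crop farming / 0.3 livestock.
# Distance-like criteria are inverted (nearer is better); the livestock buffer
# encodes the district's 300 m cattle-post regulation; development constraints
# score 1 inside protected/reserved polygons and 9 outside (buffer_m of 1 m on
# unit centroids, i.e. effectively polygon membership).
agriculture:
  name: agriculture
  children:
    - name: crop_farming
      weight: 0.7
      children:
        - name: physical
          weight: 0.60
          children:
            - name: existing_farms
              weight: 0.30
              criterion: {source_layer: farms, transform: distance, invert: true}
            - name: soil_condition
              weight: 0.20
              children:
                - name: soil_ph
                  weight: 0.34
                  criterion: {source_layer: soil_ph, transform: identity}
                - name: root_zone_depth
                  weight: 0.33
                  criterion: {source_layer: root_zone_depth, transform: identity}
                - name: drainage
                  weight: 0.33
                  criterion: {source_layer: drainage, transform: identity}
            - name: terrain_characteristics
              weight: 0.20
              children:
                - name: slope
                  weight: 0.5
                  criterion: {source_layer: dem, transform: slope, invert: true}
                - name: land_cover
                  weight: 0.5
                  criterion:
                    source_layer: lulc
                    transform: reclass_table
                    transform_params:
                      table: {1: 7, 2: 5, 3: 3, 4: 4, 5: 9, 6: 2}
            - name: development_constraints
              weight: 0.30
              criterion:
                source_layer: protected_areas
                transform: buffer_exclusion
                transform_params: {buffer_m: 1.0}
        - name: economic
          weight: 0.40
          children:
            - name: transport_accessibility
              weight: 0.25
              criterion: {source_layer: roads, transform: distance, invert: true}
            - name: water_proximity
              weight: 0.25
              criterion: {source_layer: boreholes, transform: distance, invert: true}
            - name: market_accessibility
              weight: 0.25
              criterion: {source_layer: settlements, transform: distance, invert: true}
            - name: distance_to_crop_farms
              weight: 0.25
              criterion: {source_layer: farms, transform: distance, invert: true}
    - name: livestock
      weight: 0.3
      children:
        - name: physical
          weight: 0.40
          children:
            - name: existing_livestock_location
              weight: 0.40
              criterion: {source_layer: cattle_posts, transform: distance, invert: true}
            - name: terrain_characteristics
              weight: 0.30
              children:
                - name: slope
                  weight: 0.5
                  criterion: {source_layer: dem, transform: slope, invert: true}
                - name: land_cover
                  weight: 0.5
                  criterion:
                    source_layer: lulc
                    transform: reclass_table
                    transform_params:
                      table: {1: 9, 2: 7, 3: 4, 4: 5, 5: 3, 6: 2}
            - name: development_constraints
              weight: 0.30
              criterion:
                source_layer: protected_areas
                transform: buffer_exclusion
                transform_params: {buffer_m: 1.0}
        - name: economic
          weight: 0.30
          children:
            - name: transport_accessibility
              weight: 0.33
              criterion: {source_layer: roads, transform: distance, invert: true}
            - name: water_accessibility
              weight: 0.34
              criterion: {source_layer: boreholes, transform: distance, invert: true}
            - name: livestock_buffer
              weight: 0.33
              criterion:
                source_layer: cattle_posts
                transform: buffer_exclusion
                transform_params: {buffer_m: 300.0}
        - name: wildlife_condition
          weight: 0.30
          children:
            - name: elephant_habitat
              weight: 0.10
              criterion: {source_layer: habitat_elephant, transform: identity, invert: true}
            - name: lion_habitat
              weight: 0.50
              criterion: {source_layer: habitat_lion, transform: identity, invert: true}
            - name: leopard_habitat
              weight: 0.20
              criterion: {source_layer: habitat_leopard, transform: identity, invert: true}
            - name: spotted_hyaena_habitat
              weight: 0.20
              criterion: {source_layer: habitat_spotted_hyaena, transform: identity, invert: true}
settlement:
  name: settlement
  children:
    - name: physical
      weight: 0.50
      children:
        - name: population_density
          weight: 0.40
          criterion: {source_layer: population_density, transform: identity}
        - name: terrain_characteristics
          weight: 0.30
          children:
            - name: slope
              weight: 0.5
              criterion: {source_layer: dem, transform: slope, invert: true}
            - name: land_cover
              weight: 0.5
              criterion:
                source_layer: lulc
                transform: reclass_table
                transform_params:
                  table: {1: 6, 2: 5, 3: 3, 4: 7, 5: 4, 6: 9}
        - name: development_constraints
          weight: 0.30
          criterion:
            source_layer: protected_areas
            transform: buffer_exclusion
            transform_params: {buffer_m: 1.0}
    - name: economic
      weight: 0.50
      children:
        - name: road_accessibility
          weight: 0.50
          criterion: {source_layer: roads, transform: distance, invert: true}
        - name: distance_to_settlement
          weight: 0.50
          criterion: {source_layer: settlements, transform: distance, invert: true}
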