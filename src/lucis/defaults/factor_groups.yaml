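# Factor groups for one-at-a-time map-removal sensitivity analysis.
# Each member is [goal, node-name]; removal deletes every node with that name
# in that goal's hierarchy and renormalizes surviving sibling weights.
# The wildlife goal is an external habitat surface and carries none of these
# factors, so removal applies to the agriculture and settlement trees only.
existing_land_use:
  - [agriculture, existing_farms]
  - [agriculture, distance_to_crop_farms]
  - [agriculture, existing_livestock_location]
  - [settlement, distance_to_settlement]
terrain_characteristics:
  - [agriculture, terrain_characteristics]
  - [settlement, terrain_characteristics]
road_accessibility:
  - [agriculture, transport_accessibility]
  - [settlement, road_accessibility]
water_proximity:
  - [agriculture, water_proximity]
  - [agriculture, water_accessibility]
development_constraints:
  - [agriculture, development_constraints]
  - [agriculture, livestock_buffer]
  - [settlement, development_constraints]
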