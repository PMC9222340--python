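name: bc45_like
description: 'Reconstruction of a 55.5 mm pre-pilot twin-screw machine (1000 mm screws):
  conveying elements, one left-handed element, melt conveying to paired circular dies.'
screw_diameter_mm: 55.5
total_screw_length_mm: 1000.0
centerline_distance_mm: 46.0
barrel_zone_lengths_mm:
- 200.0
- 200.0
- 200.0
- 200.0
- 200.0
elements:
- kind: conveying_rh
  length_mm: 820.0
  pitch_mm: 55.0
  channel_depth_mm: 9.0
  label: feed conveying
- kind: reverse_lh
  length_mm: 30.0
  pitch_mm: -33.0
  channel_depth_mm: 9.0
  label: reverse
- kind: conveying_rh
  length_mm: 150.0
  pitch_mm: 55.0
  channel_depth_mm: 9.0
  label: die-fed conveying
die:
- kind: circular
  length_mm: 10.0
  radius_mm: 1.5
  group: pair
- kind: circular
  length_mm: 10.0
  radius_mm: 1.5
  group: pair
meta:
  provenance: reconstructed machine fixture; printed facts are D, L, element sequence
    and die size only
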