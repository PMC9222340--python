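name: process11_like
description: 'Reconstruction of an 11 mm laboratory twin-screw machine (269.5 mm screws):
  conveying, 90-degree kneading discs, one left-handed element, conveying to a circular
  die.'
screw_diameter_mm: 11.0
total_screw_length_mm: 269.5
centerline_distance_mm: 9.3
barrel_zone_lengths_mm:
- 67.375
- 67.375
- 67.375
- 67.375
elements:
- kind: conveying_rh
  length_mm: 150.0
  pitch_mm: 11.0
  channel_depth_mm: 2.0
  label: feed conveying
- kind: kneading_block
  length_mm: 22.0
  stagger_angle_deg: 90
  disc_thickness_mm: 2.75
  channel_depth_mm: 2.0
  label: kneading block
- kind: reverse_lh
  length_mm: 11.0
  pitch_mm: -7.3
  channel_depth_mm: 2.0
  label: reverse
- kind: conveying_rh
  length_mm: 86.5
  pitch_mm: 11.0
  channel_depth_mm: 2.0
  label: die-fed conveying
die:
- kind: circular
  length_mm: 5.0
  radius_mm: 1.0
meta:
  provenance: reconstructed machine fixture; printed facts are D, L, element sequence
    and die size only
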