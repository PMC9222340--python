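name: evolum25_like
description: 'Reconstruction of a 25 mm pre-pilot twin-screw machine (400 mm screws):
  conveying, mixing block, one left-handed element, conveying to a circular die.'
screw_diameter_mm: 25.0
total_screw_length_mm: 400.0
centerline_distance_mm: 21.0
barrel_zone_lengths_mm:
- 100.0
- 100.0
- 100.0
- 100.0
elements:
- kind: conveying_rh
  length_mm: 250.0
  pitch_mm: 25.0
  channel_depth_mm: 4.2
  label: feed conveying
- kind: kneading_block
  length_mm: 25.0
  stagger_angle_deg: 45
  disc_thickness_mm: 5.0
  channel_depth_mm: 4.2
  label: mixing block
- kind: reverse_lh
  length_mm: 15.0
  pitch_mm: -15.0
  channel_depth_mm: 4.2
  label: reverse
- kind: conveying_rh
  length_mm: 110.0
  pitch_mm: 25.0
  channel_depth_mm: 4.2
  label: die-fed conveying
die:
- kind: circular
  length_mm: 10.0
  radius_mm: 1.5
meta:
  provenance: reconstructed machine fixture; printed facts are D, L, element sequence
    and die size only
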