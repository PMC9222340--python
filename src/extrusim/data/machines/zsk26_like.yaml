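name: zsk26_like
description: 'Reconstruction of a 25.5 mm co-rotating twin-screw machine (740 mm screws):
  conveying, three 45-degree kneading blocks, three left-handed elements, melt conveying
  to a 3 x 15 mm circular die. Channel geometry uses conventional ratios; all values
  are overridable.'
screw_diameter_mm: 25.5
total_screw_length_mm: 740.0
centerline_distance_mm: 21.1
barrel_zone_lengths_mm:
- 105.715
- 105.714
- 105.714
- 105.714
- 105.714
- 105.714
- 105.715
elements:
- kind: conveying_rh
  length_mm: 363.1
  pitch_mm: 25.5
  channel_depth_mm: 4.6
  label: feed conveying
- kind: kneading_block
  length_mm: 25.5
  stagger_angle_deg: 45
  disc_thickness_mm: 5.1
  channel_depth_mm: 4.6
  label: kneading block 1
- kind: kneading_block
  length_mm: 25.5
  stagger_angle_deg: 45
  disc_thickness_mm: 5.1
  channel_depth_mm: 4.6
  label: kneading block 2
- kind: kneading_block
  length_mm: 25.5
  stagger_angle_deg: 45
  disc_thickness_mm: 5.1
  channel_depth_mm: 4.6
  label: kneading block 3
- kind: conveying_rh
  length_mm: 50.0
  pitch_mm: 25.5
  channel_depth_mm: 4.6
  label: transition conveying
- kind: reverse_lh
  length_mm: 16.8
  pitch_mm: -16.8
  channel_depth_mm: 4.6
  label: reverse 1
- kind: reverse_lh
  length_mm: 16.8
  pitch_mm: -16.8
  channel_depth_mm: 4.6
  label: reverse 2
- kind: reverse_lh
  length_mm: 16.8
  pitch_mm: -16.8
  channel_depth_mm: 4.6
  label: reverse 3
- kind: conveying_rh
  length_mm: 140.0
  pitch_mm: 25.5
  channel_depth_mm: 4.6
  label: melt conveying
- kind: conveying_rh
  length_mm: 60.0
  pitch_mm: 25.5
  channel_depth_mm: 4.6
  label: die-fed conveying
die:
- kind: circular
  length_mm: 15.0
  radius_mm: 1.5
meta:
  provenance: reconstructed machine fixture; printed facts are D, L, element sequence
    and die size only
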