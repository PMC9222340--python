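name: wf_hb
description: Wheat flour with high wheat-bran enrichment (24.4% fiber)
composition:
  starch: 0.555
  protein: 0.15
  fiber: 0.244
  lipid: 0.022
  ash: 0.032
thermal:
  rho_dry_kgm3: 1400.0
  rho_water_kgm3: 1000.0
  cp_dry_JkgK: 1550.0
  cp_water_JkgK: 4186.0
  k_dry_WmK: 0.25
  k_water_WmK: 0.6
  melting_enthalpy_Jkg: 14000.0
melting_curve:
- - 0.1
  - 185
- - 0.15
  - 170
- - 0.18
  - 161
- - 0.22
  - 150
- - 0.3
  - 132
- - 0.4
  - 114
viscosity:
  dialect: absolute
  K0_Pasn: 0.002
  E_over_R_K: 11201.0
  alpha: 34.5
  beta_kgkJ: 0.0075
  n0: 0.129
  a1: 0.0
  a2: 0.0
  a3: 0.0
  a4: 0.0
  a5: 0.0
  a6: 0.0
meta:
  viscosity_provenance: published parameter table
  melting_curve_provenance: reconstructed (anchored to printed T_m where available)
  thermal_provenance: generic molten-starch defaults; user-overridable
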