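name: maize_a
description: High-amylose maize starch (70% amylose)
composition:
  starch: 0.934
  protein: 0.0015
  fiber: 0.01
  lipid: 0.013
  ash: 0.0015
  amylose_of_starch: 0.7
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
  - 205
- - 0.15
  - 190
- - 0.2
  - 177
- - 0.25
  - 166
- - 0.3
  - 157
- - 0.36
  - 147
- - 0.45
  - 135
viscosity:
  dialect: referenced
  K0_Pasn: 12100000.0
  E_over_R_K: 11440.0
  alpha: 14.6
  beta_kgkJ: 0.0
  n0: -1.16
  a1: 0.00793
  a2: 1.31
  a3: 0.0
  a4: 0.0
  a5: 0.0
  a6: 0.0
meta:
  viscosity_provenance: published parameter table
  melting_curve_provenance: reconstructed (anchored to printed T_m where available)
  thermal_provenance: generic molten-starch defaults; user-overridable
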