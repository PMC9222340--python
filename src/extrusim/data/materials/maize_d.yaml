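name: maize_d
description: Waxy maize starch (1% amylose)
composition:
  starch: 0.923
  protein: 0.0025
  fiber: 0.01
  lipid: 0.002
  ash: 0.001
  amylose_of_starch: 0.01
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
  - 175
- - 0.15
  - 160
- - 0.2
  - 147
- - 0.25
  - 136
- - 0.3
  - 127
- - 0.36
  - 117
- - 0.45
  - 105
viscosity:
  dialect: referenced
  K0_Pasn: 4720000.0
  E_over_R_K: 9235.0
  alpha: 26.1
  beta_kgkJ: 0.00165
  n0: -1.02
  a1: 0.0072
  a2: 2.54
  a3: 0.000156
  a4: 0.0
  a5: 0.0
  a6: 0.0
meta:
  viscosity_provenance: published parameter table
  melting_curve_provenance: reconstructed (anchored to printed T_m where available)
  thermal_provenance: generic molten-starch defaults; user-overridable
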