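name: hb
description: Honey/malt-based breakfast-cereal recipe (corn flour, malt extract, sugar,
  salt)
composition:
  starch: 0.823
  protein: 0.046
  fiber: 0.0052
  lipid: 0.014
  ash: 0.0017
  sugar: 0.1
  salt: 0.01
  amylose_of_starch: 0.24
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
  - 149
- - 0.15
  - 133
- - 0.19
  - 122
- - 0.23
  - 113
- - 0.3
  - 100
- - 0.4
  - 86
viscosity:
  dialect: referenced
  K0_Pasn: 12200000.0
  E_over_R_K: 11153.0
  alpha: 13.7
  beta_kgkJ: 0.0
  n0: 0.0
  a1: 0.0037
  a2: -2.55
  a3: 0.0
  a4: 0.0095
  a5: 0.0
  a6: 0.0
meta:
  viscosity_provenance: published parameter table
  melting_curve_provenance: reconstructed (anchored to printed T_m where available)
  thermal_provenance: generic molten-starch defaults; user-overridable
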