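name: cb
description: Cacao-based breakfast-cereal recipe (rice/wheat flour, cacao, sugar,
  salt)
composition:
  starch: 0.727
  protein: 0.063
  fiber: 0.013
  lipid: 0.028
  ash: 0.008
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
  - 183
- - 0.15
  - 165
- - 0.19
  - 152
- - 0.23
  - 141
- - 0.3
  - 125
- - 0.4
  - 107
viscosity:
  dialect: referenced
  K0_Pasn: 1710000.0
  E_over_R_K: 6765.0
  alpha: 13.6
  beta_kgkJ: 0.0
  n0: 0.0
  a1: 0.00328
  a2: -2.18
  a3: 0.0
  a4: 0.00805
  a5: 0.0
  a6: 0.0
meta:
  viscosity_provenance: published parameter table
  melting_curve_provenance: reconstructed (anchored to printed T_m where available)
  thermal_provenance: generic molten-starch defaults; user-overridable
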