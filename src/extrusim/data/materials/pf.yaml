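name: pf
description: Pea flour (expanded legume snacks)
composition:
  starch: 0.463
  protein: 0.239
  fiber: 0.257
  lipid: 0.02
  ash: 0.021
  amylose_of_starch: 0.35
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
  - 170
- - 0.15
  - 156
- - 0.18
  - 149
- - 0.21
  - 142
- - 0.26
  - 132
- - 0.3
  - 126
- - 0.4
  - 112
viscosity:
  dialect: referenced
  K0_Pasn: 810000.0
  E_over_R_K: 4210.0
  alpha: 11.4
  beta_kgkJ: 0.0
  n0: 0.29
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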