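name: potato_1
description: Potato starch (expanded products)
composition:
  starch: 0.957
  protein: 0.0008
  fiber: 0.01
  lipid: 0.0006
  ash: 0.006
  amylose_of_starch: 0.21
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
- - 0.22
  - 143
- - 0.28
  - 131
- - 0.35
  - 119
- - 0.45
  - 105
viscosity:
  dialect: referenced
  K0_Pasn: 3670000.0
  E_over_R_K: 6421.0
  alpha: 14.9
  beta_kgkJ: 0.00308
  n0: 0.01
  a1: 0.00155
  a2: 0.0996
  a3: 0.000275
  a4: 0.153
  a5: -3.47e-05
  a6: -1.27e-07
meta:
  viscosity_provenance: published parameter table
  melting_curve_provenance: reconstructed (anchored to printed T_m where available)
  thermal_provenance: generic molten-starch defaults; user-overridable
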