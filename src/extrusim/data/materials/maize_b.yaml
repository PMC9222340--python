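name: maize_b
description: Maize starch blend, 47% amylose (A/D = 2/1)
composition:
  starch: 0.93
  protein: 0.0018
  fiber: 0.01
  lipid: 0.011
  ash: 0.0013
  amylose_of_starch: 0.47
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
  - 195
- - 0.15
  - 180
- - 0.2
  - 167
- - 0.25
  - 156
- - 0.3
  - 147
- - 0.36
  - 137
- - 0.45
  - 125
viscosity:
  dialect: referenced
  K0_Pasn: 1910000.0
  E_over_R_K: 7983.0
  alpha: 17.9
  beta_kgkJ: 7.44e-05
  n0: 1.81
  a1: -0.00736
  a2: -1.93
  a3: -0.00489
  a4: 0.0
  a5: 1.98e-05
  a6: 0.00919
meta:
  viscosity_provenance: published parameter table
  melting_curve_provenance: reconstructed (anchored to printed T_m where available)
  thermal_provenance: generic molten-starch defaults; user-overridable
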