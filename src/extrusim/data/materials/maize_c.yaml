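name: maize_c
description: Maize starch blend, 23.5% amylose (A/D = 1/1)
composition:
  starch: 0.929
  protein: 0.002
  fiber: 0.01
  lipid: 0.0067
  ash: 0.0013
  amylose_of_starch: 0.235
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
- - 0.2
  - 157
- - 0.25
  - 146
- - 0.3
  - 137
- - 0.36
  - 127
- - 0.45
  - 115
viscosity:
  dialect: referenced
  K0_Pasn: 45700000.0
  E_over_R_K: 10850.0
  alpha: 29.5
  beta_kgkJ: 0.00106
  n0: 3.54
  a1: -0.0154
  a2: -3.19
  a3: -0.00872
  a4: 0.0
  a5: 4.1e-05
  a6: 0.0112
meta:
  viscosity_provenance: published parameter table
  melting_curve_provenance: reconstructed (anchored to printed T_m where available)
  thermal_provenance: generic molten-starch defaults; user-overridable
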