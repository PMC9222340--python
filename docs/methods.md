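# Methods

`extrusim` implements a one-dimensional global model of co-rotating
twin-screw extrusion for starchy and leguminous food melts. This note
records the model, its closures, the numerical scheme, what the shipped
fixtures represent, and the limits of what the test suite demonstrates.

## Flow model

Each screw element is treated as a C-chamber whose volumetric throughput
obeys the drag/pressure balance

    Qv = A·Ω + (B/η)·(ΔP/Δθ)

with `A` (m³/rad) the drag coefficient, `Ω` the screw speed (rad/s), `B`
the pressure-flow coefficient and `ΔP/Δθ` the pressure gradient over the
element's angular extent. `A` and `B` come from shallow-rectangular-channel
lubrication theory: the channel width follows from pitch, flight count and
flight-tip land width; the helix angle from pitch and diameter. `B` also
carries a leakage conductance through the flight-tip clearances (slit flow
across the flight lands, crossings in series once per flight per turn),
which dominates the pressure flow of left-handed (reverse) elements.

The melt is an Ostwald–de Waele power-law fluid, `η = K·γ̇^(n−1)`, applied
through a local Newtonian linearization at the representative channel shear
rate `γ̇ = πDN/h`. The consistency `K` carries an Arrhenius temperature
term, exponential moisture plasticization and an exponential dependence on
cumulative specific mechanical energy (thermomechanical history); the flow
index `n` is an empirical polynomial in T (°C), moisture fraction and SME,
clamped to [0.05, 1] with a logged warning because the polynomial is only
valid inside its calibration window while the power law requires
0 ≤ n ≤ 1. Both the referenced (explicit reference state T₀ = 353 K,
MC₀ = 0.10, SME₀ = 350 kJ/kg) and the absolute parameter dialects are
supported, with a closed-form conversion between them.

Die elements (circular, slit; series and parallel groupings) use the exact
power-law Poiseuille solutions; parallel groups split the flow by a 1D root
find that equalizes the branch pressure drops. Wall shear rates are
reported per element so the die-exit viscosity η_com is evaluated at the
actual die wall shear.

## Energy balance

Per unit mass of throughput, over each (sub-)element:

    Cp·ΔT = Ev − Ecd,   Ev = Ẇ/(ρ_m·Qv),   Ecd = h_t·S·(T − T_b)/(ρ_m·Qv)

`Ẇ = ∫η γ̇² dV` is approximated as the sum of a channel term (at `γ̇_ch =
πDN/h`) and a flight-gap term (at `γ̇_gap = πDN/δ`); the gap term only acts
where the channel is pressurized, because in starved sections the melt pool
does not feed the clearances. Partially filled chambers dissipate and
exchange heat in proportion to their filled fraction `f = Qv/(A·Ω)`.

The barrel heat-transfer coefficient uses a Nusselt closure `h_t =
Nu·k_melt/L_c` with Nu = 20 and the characteristic length `L_c` equal to
the channel hydraulic scale `2h` (twice the channel depth). With typical
melt conductivity this gives h_t ≈ 500–700 W·m⁻²·K⁻¹, in the range
measured for twin-screw barrels; taking the channel depth alone makes
conduction overwhelm dissipation everywhere (the melt could never stay
above the barrel temperature, contradicting the observed behaviour), and
taking the screw diameter leaves the die-fed zone essentially adiabatic.
The die contributes its pressure work `ΔP·Qv` as heating and exchanges
heat with the die wall at its own hydraulic diameter, which produces the
characteristic slight temperature rise through the die.

Melt density, heat capacity and conductivity are mass-fraction blends of
dry-melt and water values. The dry-melt constants shipped in the material
files (ρ 1400 kg/m³, Cp 1550 J/kg/K, k 0.25 W/m/K, melting enthalpy
14 kJ/kg) are generic molten-starch defaults and are user-editable inputs,
not literature claims for the specific recipes.

## Melting rule and backward shooting

Melting is instantaneous at the first restrictive element counted from the
feed (kneading block or reverse element); the melt boundary sits where the
backed-up pressure vanishes at or upstream of that element, and the melt
temperature there equals the melting temperature T_m(MC) interpolated from
the material's melting curve.

Because the die-exit temperature is unknown, the march starts at the die
and proceeds upstream, element by element: the die pressure drop gives the
die-entrance pressure, then each element updates pressure and temperature.
Fully filled stations (pressure present, or drag deficit as in reverse or
over-fed elements) integrate the pressure step; starved stations carry zero
pressure at fill `Qv/(A·Ω)`. The exit temperature is iterated by
bracketing bisection until the temperature computed at the melting point
matches T_m within 0.1 °C (≤ 60 outer iterations). Plain bisection is used
deliberately: the forward energy balance is self-regulating (hotter melt →
thinner → less dissipation), so the backward march is anti-damped and die
perturbations amplify by one to two orders of magnitude on the way to the
melting point, far too steep for secant steps.

Cumulative SME is itself an input of the viscosity model but is only known
after a march; a damped Picard iteration (damping 0.5, relative tolerance
10⁻³ on SME_com, fresh flat start per residual evaluation so the shooting
residual is deterministic) resolves the circularity.

SME_com is the sum of per-element dissipated power over the mass flow from
the melting point to the die. The melting enthalpy (≈ 14 kJ/kg, an order of
magnitude below typical SME_com) is reported separately and added only when
`include_melting_enthalpy=True`.

### Numerics

Elements are sub-divided into at least 4 sub-steps (and at least one per
12 mm). Each sub-step uses a midpoint (RK2) rule: rates are evaluated at a
half-step temperature. Where the pressure vanishes inside a sub-step, the
filled and starved contributions are blended by the pressurized length
fraction, which removes filled-length quantization; together these keep the
die-exit temperature stable to < 0.5% under four-fold refinement.
Shooting guesses far outside the physical branch are truncated at
[1, 450] °C; the residual keeps its sign, so bracketing is unaffected.

## Machine fixtures are reconstructions

Only the coarse facts of the reference machines are public: screw diameter,
screw length, the element sequence, moisture/temperature ranges and the die
size. Channel depths (0.16–0.2 D), pitches (≈ 1 D conveying, ≈ 0.66 D
reverse), flight lands (0.05 pitch), clearances (0.022 D, 0.03 D for
reverse), the C-chamber intermeshing transfer efficiency (0.68), the
kneading-block equivalent model (apparent pitch `360/stagger · disc
thickness`, drag efficiency `cos(stagger)`, enlarged inter-disc leakage)
and the reverse-element closures (drag efficiency 0.4, dissipation
intensification 1.4 standing in for recirculation through the clearances)
are reconstructions. They were fixed once against the published qualitative
and quantitative profile landmarks for the 25.5 mm breakfast-cereal machine
— temperature steps of 5–10 °C across the kneading blocks and 35–60 °C
across the three reverse elements, pressure support confined to the
reverse/die-fed regions, maximum melt temperatures near 230 °C (cacao
recipe) and 185 °C (honey recipe) at MC 15%, 500 rpm, 20 kg/h — and are not
adjusted per simulation. Every geometric value is overridable in the
machine YAML files. The `zsk26_like` profile includes a 50 mm conveying
spacer between the kneading and reverse zones, which is what confines the
pressure peak to the reverse region as observed.

"Last barrel temperature" in sweeps (`OperatingPoint.with_(
last_barrel_temp_c=...)`) retunes the contiguous tail of equal-temperature
zones — the melt-region zones of a 20/40/60/90/90/90/90 profile — plus the
die, which is how that control is meant on these machines.

## Material database

The eleven shipped parameter sets (four maize starches spanning 1–70%
amylose, potato starch, two breakfast-cereal recipes, pea flour, wheat
flour with two bran levels) are published values; table entries printed as
"-" are exact zeros (the dependence was not retained by the original fit).
The three wheat sets use the absolute dialect. Melting curves are
reconstructed monotone tables anchored to the two published DSC values
(cacao recipe 165 °C, honey recipe 133 °C, both at MC 15%) with
literature-shaped slopes (≈ −2 to −3 °C per moisture percent); they are
inputs, not claims, and interpolation refuses to extrapolate outside the
tabulated moisture range.

`fit_viscosity_params` calibrates the model from rheometry tables by
ordinary least squares on log η (the model is log-linear in every
coefficient once the flow-index terms are multiplied by log γ̇).
Coefficients of factors that do not vary in the data are pinned to zero;
rank deficiency raises an error naming the unidentifiable terms (detected
on the column-normalized design).

## Design layer

Product features are linked to computed variables by monotone one-predictor
models (linear, power, exponential), fit by log-linearization plus
nonlinear refinement, each carrying R², residual SE and a validity interval
(the fitted predictor range; predictions outside it warn). Inversion
intersects the target with the image of the validity interval, so
one-sided targets resolve to validity endpoints; non-monotone (constant)
models are rejected rather than pseudo-inverted. Operating-chart grids
solve every node of a Cartesian sweep, masking unconverged nodes, and
feasible regions intersect closed-interval constraints on the grid
responses. Multiple features sharing a predictor intersect on the
predictor; otherwise regions intersect on the grid.

The published numeric fit parameters behind the feature charts are not
available, so the shipped correlation models are *reconstructions* anchored
to printed chart landmarks (for example the starch-depolymerization power
law through (625 kJ/kg, 45%) and (875 kJ/kg, 55%), the snack-density onset
of 200 kg/m³ at 155 °C, insoluble protein reaching 10% at 165 °C, starch
solubility 50% at 375 kJ/kg). Where two printed statements are mutually
inconsistent — the density chart's 800→100 kg/m³ span over 125→175 °C
cannot pass exactly through 200 kg/m³ at 155 °C — the onset pair is honored
exactly because the published design windows derive from it. All such
models carry `provenance="reconstructed"` and are intended to be replaced
by `fit_correlation` on real measurement tables.

## Synthetic data

`generate_rheometry` and `generate_feature_data` draw observations
lognormally around the respective model truths (exact at zero noise,
deterministic for a fixed seed). They emulate the *statistical* structure
of rheometer and product-measurement tables — factorial designs,
multiplicative noise — but not their systematic errors (slit-die entrance
effects, moisture loss during measurement, inter-laboratory bias). Passing
recovery tests therefore demonstrates the estimators, not the instruments.

## Known limitations

- Solid conveying upstream of the melting section is not modelled (no
  friction energy, no solids pressure); consistent with the 1D global
  approach, which is known to underestimate measured SME for this reason.
- The kneading-block and reverse-element closures are equivalent-element
  approximations behind `shape_factors`; dedicated staggered-disc and
  reverse-channel models can replace them without touching the solver.
- The moisture sensitivity of SME is weaker than the published three-fold
  drop for the cacao recipe between MC 19% and 23% (this model yields
  ≈ 1.7-fold). With that recipe's published coefficients (no SME feedback,
  α = 13.6) the isothermal viscosity ratio over ΔMC = 0.04 is e^0.544 ≈
  1.7, and thermal self-regulation erodes part of it because the colder,
  wetter run is locally more viscous near its own melting point. A
  stronger response would require either a moisture-dependent machine
  closure or viscosity coefficients beyond the published set.
- Mean residence time only (no residence-time distribution); no transient
  dynamics; no vent-flow mass loss; no melt-pressure dependence of
  viscosity; no expansion model at the die (density and cell structure are
  handled only through the empirical correlation layer).
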