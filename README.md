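# extrusim

A 1D global simulator of co-rotating twin-screw extrusion for starchy and
leguminous food melts, with a product-design layer that maps the computed
process variables onto extruded-product features.

Extrusion cooking turns starch- and legume-based feeds into breakfast
cereals, snacks and texturized ingredients. The product's structure —
starch depolymerization, protein cross-linking, density, cellular fineness
— is controlled by the thermomechanical history inside the machine: melt
temperature `T`, cumulative specific mechanical energy `SME` (kJ/kg),
pressure and melt viscosity. Those quantities are hard to measure where
they matter (inside the screws and at the die core), so process and product
designers simulate them. `extrusim` is for food-process engineers and
researchers who want those predictions, operating charts over screw speed
`N`, feed rate `Q`, moisture `MC` and barrel temperature `Tb`, and feasible
operating windows for product targets, from a plain-text machine/material
description.

## Model

Every screw element is a C-chamber with throughput

    Qv = A·Ω + (B/η)·(ΔP/Δθ)

(`A`, `B` from channel geometry; drag plus pressure flow), the melt is an
Ostwald–de Waele power-law fluid

    η = K·γ̇ⁿ⁻¹
    K = K₀·exp(E/R·(1/T − 1/T₀) − α·(MC − MC₀) − β·(SME − SME₀))
    n = n₀ + α₁T + α₂MC + α₃SME + α₄T·MC + α₅T·SME + α₆MC·SME

and the axial temperature follows the energy balance `Cp·ΔT = Ev − Ecd`
(viscous dissipation vs conduction to the barrel through a Nusselt closure,
Nu = 20). Melting is instantaneous at the first restrictive element;
because the die-exit temperature is unknown, the solver marches backward
from the die and shoots on the exit temperature until the melting-point
temperature matches T_m(MC), resolving the SME–viscosity circularity by an
inner fixed-point iteration. A database of published power-law parameter
sets (maize starches of 1–70% amylose, potato starch, two breakfast-cereal
recipes, pea flour, wheat flour ± bran) ships with the package, together
with reconstructed machine fixtures. See `docs/methods.md` for closures,
numerics and provenance of every fixture.

## Worked example

Simulate the honey/malt breakfast-cereal recipe (HB) on the reconstructed
25.5 mm machine at 15% moisture, 500 rpm, 20 kg/h, barrel zones
20/40/60/90/90/90/90 °C:

```sh
extrusim simulate --machine zsk26_like --material hb --mc 15% \
    --n-rpm 500 --q-kgh 20 --barrel 20,40,60,90,90,90,90 --die-temp 90 \
    --out hb_profile.csv
```

prints (abridged):

```json
{
  "T_com_C": 186.1,
  "SME_com_kJkg": 262.9,
  "P_com_Pa": 6062429,
  "eta_com_Pas": 163.2,
  "mean_residence_s": 16.3,
  "melting_position_m": 0.3769,
  "melting_temp_C": 133.0
}
```

The melt forms 377 mm upstream of the die at its melting temperature
(133 °C at this moisture), accumulates ≈ 263 kJ/kg of mechanical energy —
mostly across the kneading blocks and the three left-handed elements, where
the axial profile in `hb_profile.csv` shows the temperature stepping up by
≈ 15 °C and ≈ 42 °C respectively to a ≈ 189 °C peak — and exits the die at
186 °C and 163 Pa·s against a 6.1 MPa die pressure. The same run with the
more viscous cacao recipe (`--material cb`) peaks near 223 °C, hot enough
that thermal degradation becomes a design concern.

Library use mirrors the CLI:

```python
import extrusim as ex

machine = ex.load_machine("zsk26_like")
material = ex.load_material("hb")
op = ex.OperatingPoint(n_rpm=500, q_kgh=20, mc=0.15,
                       barrel_temps_c=(20, 40, 60, 90, 90, 90, 90))
res = ex.solve_profile(machine, material, op)
res.profile_frame()        # tidy axial profile (T, P, SME, eta, fill)
```

and the design workflow (chart grid → invert feature targets → feasible
window) is available through `extrusim.design` / the `design` subcommand,
with reconstructed feature correlations
(`extrusim.reconstructed_correlations()`) that users should replace by
`fit_correlation` on their own measurements. For example, requiring a pea
snack no denser than 200 kg/m³ with insoluble protein under 10% inverts
to a die-exit temperature window of 155–165 °C, from which the chart grid
returns admissible (N, Q, Tb) combinations.

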