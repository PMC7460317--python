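# mangrofate

Coupled simulation of heavy-metal fate in mangrove estuaries: depth-averaged
shallow-water hydrodynamics, advection–dispersion transport of dissolved
chromium, and linear water–soil–plant compartment kinetics, with a scenario
engine for weighing management alternatives (natural mangrove cover,
deforestation, constructed treatment wetlands, or no ecosystem services at
all) on synthetic tidal catchments.

The package is aimed at ecohydrologists and environmental engineers who want
a transparent, fully testable desk-scale model of phytoremediation at
catchment scale: how much of an industrial metal load do mangroves and
constructed wetlands actually retain, and how does the water, soil and plant
burden respond to land-use change?

## Model

**Hydrodynamics.** Depth-averaged continuity and momentum on a structured
grid, with total depth `h = d + ζ`:

    ∂ζ/∂t + ∂(hu)/∂x + ∂(hv)/∂y = 0
    ∂u/∂t + u ∂u/∂x + v ∂u/∂y = −g ∂ζ/∂x + f v − τ_bx/(ρ_w h) + F_x/(ρ_w h) + K ∇²u
    ∂v/∂t + u ∂v/∂x + v ∂v/∂y = −g ∂ζ/∂y − f u − τ_by/(ρ_w h) + F_y/(ρ_w h) + K ∇²v

Bed friction is quadratic through the Chézy coefficient, `τ_b = ρ_w g |U| (u,v) / C²`
with `C = h^(1/6)/n` and Manning `n` assigned per land class (0.005 riverbed,
0.15 mangrove floodplain). Open boundaries carry harmonic tidal water levels
(default one semidiurnal constituent of 2.7 m amplitude) or prescribed bulk
inflow.

**Transport.** Dissolved chromium `c` (g/m³ ≡ mg/L) obeys the
advection–dispersion equation with point wastewater sources `F(x,y,t)`
discharging on a daily clock window, coupled to the soil through
`γ(−k01 c + k10 Sl)`.

**Compartments.** Per cell, chromium in the soil liquid (`Sl`), soil solid
(`Ss`) and plant (`Pl`) pools follows first-order kinetics:

    dSl/dt = k01 c − (k12 + k13 + k10) Sl + k21 Ss
    dSs/dt = k12 Sl − k21 Ss
    dPl/dt = k13 Sl

`k13` depends on mangrove age (young trees: 7×10⁻⁸ s⁻¹; mature forest an
order of magnitude lower; zero without vegetation), and exchange only occurs
while a cell is inundated. Constructed wetlands are continuously stirred
tanks with residence time τ whose steady transfer is `1/(1 + k τ)`.

All runs keep a chromium ledger — injected, stored per compartment, exported
through the open boundary, retained in wetlands — that closes to round-off.

## Worked example

Compare the baseline scenario (SC1) against routing every discharge through
constructed mangrove wetlands (SC3) on the toy two-bank catchment, six days
of semidiurnal tide:

```python
from mangrofate import build_scenario, make_toy_catchment, run_simulation

catchment = make_toy_catchment()
for name in ("SC1", "SC3"):
    scenario = build_scenario(name, catchment, duration=6 * 86400.0)
    run = run_simulation(scenario)
    b = run.budget
    print(f"{name}: station-mean c = {run.station_mean_concentration():.4g} mg/L | "
          f"injected {b.injected:.4f} kg | exported {b.exported_boundary:.4f} kg | "
          f"soil+plant {b.stored_Sl + b.stored_Ss + b.stored_Pl:.2e} kg | "
          f"wetland retained {b.wetland_retained:.4f} kg | "
          f"residual {b.residual:.1e} kg")
```

prints

```
SC1: station-mean c = 6.877e-07 mg/L | injected 0.2030 kg | exported 0.1073 kg | soil+plant 2.73e-03 kg | wetland retained 0.0000 kg | residual -1.1e-16 kg
SC3: station-mean c = 6.557e-07 mg/L | injected 0.2030 kg | exported 0.0765 kg | soil+plant 2.42e-03 kg | wetland retained 0.0108 kg | residual 1.0e-13 kg
```

Reading the numbers: the five industrial sources emit 0.203 kg of chromium
over six days (4.7 mg/s for two hours daily). In the baseline, most of what
reaches the river is flushed to sea and a few grams sorb into soil and
plants. Pre-treating the same load in wetlands (SC3) retains 0.011 kg in the
wetland pools, visibly lowers the in-river concentration, and the budget
residual stays at machine precision in both runs. Station-mean
concentrations across all four scenarios order as
NonEco ≥ SC2 ≥ SC1 ≥ SC3: every ecosystem service removed raises the
metal burden of the water.

The same runs are available from the shell:

```
mangrofate simulate --scenario SC3 --out runs/sc3 --duration-days 30
mangrofate budget --run runs/sc3
mangrofate compare --runs runs/sc1 --runs runs/sc3
mangrofate make-fixtures --kind greenhouse --seed 7 --out fixtures/
```

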