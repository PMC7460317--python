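# Methods

## Scope and model structure

The simulator couples three sub-models on a shared structured grid:

1. **Depth-averaged shallow-water flow** with harmonic tidal forcing,
   quadratic bed friction (Chézy–Manning), Coriolis acceleration, constant
   horizontal eddy viscosity, optional external surface forces, and
   wetting/drying of intertidal flats.
2. **Advection–dispersion transport** of dissolved chromium with point
   wastewater sources on a daily clock window.
3. **Linear compartment kinetics** moving chromium between the water
   column and the soil liquid, soil solid and plant pools of every cell,
   with plant uptake controlled by a mangrove age class.

A scenario engine instantiates four management templates on a synthetic
two-bank catchment and accounts a chromium mass ledger for each run.

## Hydrodynamic solver

State is staggered on an Arakawa C-grid: water level ζ at cell centers,
velocities on cell faces. Time stepping is explicit forward–backward: the
flux-form continuity update runs first, then momentum is integrated against
the new water level. Momentum advection is first-order upwind; bed friction
is treated semi-implicitly (`u_new = (u + dt·rhs)/(1 + dt g n² |U| / h^{4/3})`),
which remains stable on centimetre-deep flood plains. The pressure-gradient
term of the v-momentum equation acts along y (`g ∂ζ/∂y`); a transposed form
sometimes seen in print is a typographical slip, since the x-gradient in
both momentum equations would leave the y-momentum budget unforced.

Wetting and drying: a face is open when the higher adjacent water level
stands more than `h_dry` (default 0.01 m, a common drying threshold for 2-D
estuarine solvers) above the higher adjacent bed level; closed faces carry
zero velocity, so dry cells never hold momentum. Face fluxes use the
upwind-side water column above the face sill, which keeps depths and tracer
masses non-negative under the CFL bound `dt ≤ cfl·min(dx,dy)/(√(gh)+|U|)`
(`cfl` default 0.7). Because continuity is in flux form, closed-basin volume
is conserved to round-off.

Open boundaries are cell-based. Tide cells carry a Dirichlet water level
synthesized as `mean + Σ A_k cos(2πt/T_k − φ_k)`; upstream discharge enters
as a volume source distributed uniformly over the designated inflow cells —
with only bulk discharge known, this is equivalent to prescribing face
velocities at this level of abstraction and is simpler to keep conservative.

Verification oracles: the lake-at-rest steady state is preserved exactly
(well-balancedness); the fundamental seiche period of a closed basin matches
the Merian formula `T = 2L/√(gH)` to ~10⁻⁵ relative; the interior amplitude
of a frictionless tidal channel matches the linear standing-wave solution
`ζ = a·cos(k(L−x))/cos(kL)` to ~0.1 %.

## Transport scheme

The conserved variable is the areal tracer mass `m = c·h` (g/m²). One step
moves `m` with the same upwind face fluxes as continuity (plus central
dispersive fluxes `−D h ∂c/∂n`), then recovers `c = m/h_new`. Sharing fluxes
between volume and mass makes tracer conservation exact and the scheme
positivity-preserving; at Courant number one, pure upwind advection is
exact. Cells that dry keep their mass in place (faces are closed) and
re-dissolve it on rewetting; sources aimed at dry cells buffer their mass
likewise, so injected mass can never vanish.

Boundary cells of the tide segment hold an imposed concentration (default
0) on inflow; outflow advects interior concentration outward through
upwinding. Dispersive fluxes are suppressed across boundary faces so the
zero-gradient outflow condition does not generate artificial exchange. Mass
crossing those faces is logged as exported.

The scheme is verified against the 1-D Gaussian plume
`c = M/(h√(4πDt))·exp(−(x−x₀−ut)²/(4Dt))`: relative L2 error ≈ 1.5 % at
10 m resolution, roughly halving at 5 m. Default dispersion is
`Dx = Dy = 10 m²/s`, a typical estuarine magnitude; the verification is
against the analytic solution, not a particular default.

## Compartment kinetics and unit closure

Pools are carried in mg per kg of active soil (bulk density ρ_b = 1300
kg/m³, layer thickness z_s = 0.3 m — ordinary muddy intertidal values), so
the areal pool mass is `pool·ρ_b·z_s·10⁻³` g/m². Requiring that the water
column (c in g/m³ over depth h) lose exactly what the soil gains fixes the
water-side exchange as

    dc/dt = γ (−k01 c + k10 Sl),   γ = ρ_b z_s / (1000 h).

One conversion factor multiplies both exchange terms; any other placement
of γ breaks the joint budget with the pool equations. All three pools use
the soil-mass basis in the ledger — converting the plant pool through a
separate biomass density would make the internal `k13` transfer appear to
create or destroy mass, so the biomass density `B` (default 10 kg/m²) is
kept only to express plant concentrations per kilogram of plant tissue in
reports.

Integration uses the exact affine propagator of the forced linear system
(`x(t+dt) = e^{A dt} x + (∫e^{As}ds) b` via one augmented matrix
exponential, cached per age class and step size) with the water
concentration frozen over the step. This is unconditionally stable for
stiff rate combinations and reduces the coupling error to the O(dt)
operator splitting of the outer loop. An explicit Euler variant exists for
cross-checks. The homogeneous rate matrix is dissipative (eigenvalues with
non-positive real part) for any non-negative rates, and the plant pool is
non-decreasing because it has no loss term.

Rate defaults (s⁻¹): k01 = 10⁻⁶, k10 = 10⁻⁸, k12 = 10⁻⁶, k21 = 10⁻⁷ are
order-of-magnitude working values — sorption faster than desorption,
water→soil faster than return — exercised through fitting and the analytic
oracle rather than relied on as truth. Young-tree uptake k13 = 7×10⁻⁸ s⁻¹
follows greenhouse phytoremediation estimates; the mature-forest value is
set one order of magnitude lower (7×10⁻⁹ s⁻¹) to represent the reduced
root permeability of aged stands, and is the natural target of field
tuning (`tune_k13`).

## Constructed wetlands

Each wetland unit is a continuously stirred tank (CSTR) with residence
time τ (default 24 h) and internal water depth 0.5 m rather than a resolved
basin: influent raises the internal concentration, young-mangrove kinetics
move chromium into the unit's pools, and the effluent `C·V/τ` discharges to
the river cell of its source. The cumulative effluent is carried as an
extra integrated state of the unit's linear system, so the discharge is
exact for piecewise-constant influent. With a single removal pathway the
steady-state transfer is the classical `1/(1 + kτ)`. Wetland cells sit
above the tidal range on the grid (their chemistry lives in the unit), so
no exchange is double-counted.

## Scenarios

* **SC1** (baseline): mangrove floodplain west of the channel (mature age
  class), bare industrial east bank, five direct discharges
  (0.5, 1, 1, 0.2, 2 mg/s) active 12:00–14:00 daily.
* **SC2** (deterioration): west-bank mangroves become bare ground — uptake
  stops, soil sorption continues. Discharges are identical to SC1 in
  location and rate; the deterioration is purely the loss of the ecosystem.
  The Manning field is kept at baseline values because a fresh clear-cut
  retains its root mats and stumps at the one-month scale; this also keeps
  the SC1/SC2 contrast a controlled uptake experiment instead of a mixed
  hydraulic one.
* **SC3** (eco-friendly): a constructed-wetland strip on the east bank;
  every discharge is routed through a wetland unit before reaching the
  river.
* **NonEco**: SC1 geometry with all soil/plant absorption disabled;
  isolates the ecosystem service.

Initial chromium is zero everywhere in all scenarios to make the
comparison clean. With identical loads, station-mean water concentrations
order strictly as NonEco ≥ SC2 ≥ SC1 ≥ SC3: each removal pathway added
lowers the water burden. (A doubled-source reading of the deterioration
scenario would invert the first inequality for weak exchange, which is why
identical discharges are the consistent interpretation.)

## Mass ledger

Injected mass integrates each source rate over the exact overlap of every
step with its discharge window, so it equals Σ rate × active-time to
round-off. Storage terms sum the water column (areal mass × cell area,
including ponded and buffered mass), the soil-basis pools outside wetlands,
and the wetland units' internal water and pools; exports accumulate the
advective fluxes into tide-boundary cells. The residual of every scenario
run closes to ~10⁻¹⁴ relative, against a 10⁻⁶ acceptance bound.

## Synthetic data

The toy catchment emulates a heavily industrialized tropical estuary: a
15 km × 450 m channel, 10 m deep, on a 150 m grid (100 × 21 cells), flanked
by 1.35 km flood plains 0.3 m above datum; semidiurnal tide of 2.7 m
amplitude at the southern mouth; 20 m³/s freshwater inflow upstream;
east-bank sources and two monitoring stations (M1 downstream, M5 upstream)
in the channel. The first east-bank column is a raised industrial platform
above the tidal range in every scenario; SC3 builds its wetlands there, so
scenarios differ only in land use, uptake and routing — never in
hydrodynamics (an early design that raised this strip only in SC3 removed
intertidal storage from the domain and confounded the comparison). It reproduces the mechanisms that matter — tidal pumping,
intermittent floodplain inundation, source windows, bank asymmetry — but
not the real system's bathymetric complexity, multi-constituent tides,
salinity stratification, sediment-bound transport or metal speciation, so
passing tests demonstrate correct model mechanics, not site-specific
predictions. Greenhouse datasets sample the closed-form pool trajectories
at 0, 3 and 6 months under constant water concentration (renewed-water
assumption) with multiplicative Gaussian noise; they are pure functions of
their seed.

## Numerical and design choices

* Fixed step `dt` chosen once per run from the gravity-wave bound with
  headroom for the tidal excursion and a 4 m/s current margin (≈ 6.8 s on
  the default catchment); transport and exchange share it (operator
  splitting hydro → transport → compartments, O(dt)).
* Runs start from a level surface at the instantaneous tide to avoid an
  artificial initial surge.
* The inner loop of scenario runs is a numba-compiled kernel that fuses
  the three sub-steps; the module-level numpy operations are the canonical
  definitions, the two paths agree to 10⁻¹² on coupled runs (enforced by a
  test), and the numpy path is used automatically when numba is absent.
* The parameter fit weights each observed pool by its series' standard
  deviation (mg/L and mg/kg scales would otherwise be dominated by the
  largest magnitude), uses bounded trust-region least squares
  (ftol/xtol 10⁻¹², non-negative bounds), and flags non-identifiability
  when the scaled Jacobian at the solution is rank-deficient or has a
  condition number beyond 10⁸ (the finite-difference noise bound).
  Confidence intervals come from the Gauss–Newton curvature.
* Test and verification problem sizes: eight-day scenario runs for the
  ordering and engine-agreement checks, one 30-day baseline run for budget
  closure, 100-cell channels for the hydrodynamic oracles, 100 random draws
  for the compartment oracle, and 120 seeded replicates for the
  noise-recovery study. The acceptance script runs all four scenarios at
  the full 30 days.

## Known limitations

* First-order upwind transport is diffusive; plume verification quantifies
  the error at the shipped resolutions.
* The exchange closure (γ) is an interpretation: the source equations mix
  mg/kg and g/m³ without printing a conversion, and results in
  per-cell units should be read accordingly.
* No sediment transport, no Cr(III)/Cr(VI) speciation, no toxicity
  feedback, no forest growth dynamics; wetlands are lumped CSTRs.
* The fit recovers all five rates exactly from noiseless data, but k10 and
  k21 are weakly identified under realistic noise at three sample times —
  the replicate study shows their estimate spread honestly.
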