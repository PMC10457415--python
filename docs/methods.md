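# Methods

`osmosim` implements the mechanical picture of osmosis in which a
semipermeable membrane is a region of repulsive potential energy `U(x)` for
solute molecules.  The membrane's force `F = -dU/dx` excludes solute, and
mechanical balance of the fluid then *requires* a pressure drop of `R T c_s`
across each membrane-solution interface.  Osmotic flow is nothing but
pressure-driven (Darcy) flow down the resulting intramembrane pressure
gradient.  Everything in the package is a computable consequence of that
single idea, checked at three levels of description.

## Conventions and constants

All internal quantities are SI: concentrations in mol m^-3, pressures in Pa,
temperatures in K.  The membrane is perpendicular to the x axis and occupies
`[0, h]`; the solution chamber of higher osmolarity is on the right, all
differences are `Δq = q_right − q_left`, and fluxes are positive in +x.
The gas constant is fixed at `R = 8.314 J mol^-1 K^-1`; the molar volume of
pure water defaults to `v_w0 = 1.802e-5 m^3 mol^-1` (the reciprocal of the
55.5 M concentration of pure water).  When no temperature is given,
298.15 K is used and logged.  Reduced-unit runs (convenient for the particle
simulations) set `T = 1/R` so that `R T = 1`.

## Phenomenological layer (`transport`)

The module is the algebra of the flux laws:

- van 't Hoff equilibrium `ΔP = R T Δc_s`;
- Darcy flow `Φ_V = −Lp ΔP`;
- the combined law `Φ_V = −Lp (ΔP − R T Δc_s)`, whose single coefficient
  `Lp` answers both hydrostatic and osmotic driving;
- the molar form `ϕ_w = −Pf (ΔP/RT − Δc_s)` with `Pf = R T Lp / v_w0`
  (the division by `v_w0` is forced by dimensional consistency between the
  molar and volume forms);
- tracer diffusion `ϕ_w* = −Pd Δc_w*` and the identification of the same
  `Pd` in the force-driven diffusive flux `−Pd ΔP/RT`;
- the convective fraction `Pc/Pd = Pf/Pd − 1` (with `Pf < Pd` rejected as
  inconsistent with a non-negative convective contribution);
- the solubility-diffusion bilayer model `Pf = Pd = K D / h`, hence
  `Pf/Pd = 1` exactly for a membrane crossed by independent water
  molecules.

## Continuum profiles (`continuum`)

An infinite hard wall is replaced by finite smooth barriers so the force is
defined everywhere: a flat-topped plateau (logistic edges) and a Gaussian
bump, both parametrized by height `U_max`, span `h`, and an interface width
`w` (default `h/20`).  A barrier is declared *impermeable* when
`U_max ≥ 30 RT`: the Boltzmann leakage factor `e^-30 < 1e-13` is far below
every tolerance used.

Equilibrium profiles are closed-form: zero solute flux gives
`c(x) = c_bulk e^{-U(x)/RT}` on each side of the barrier midpoint, and
integrating the mechanical balance `dP/dx = c F = RT dc/dx` from the
right-chamber boundary condition gives `P(x)`.  The chamber-to-chamber
pressure difference is `R T (c_r − c_l)(1 − e^{-U_max/RT})` — the shape of
`F` cancels, which the tests verify across shapes, widths and heights
(`U_max ∈ [30, 100] RT`, invariance to 1e-6 relative).

The osmotic steady state keeps the interfaces quasi-equilibrated (chambers
are well stirred) and adds a constant viscous gradient inside the membrane:

    dP/dx = RT dc/dx − (Φ_V / (h Lp)) · 1_[0,h](x),

with `Φ_V = −Lp (ΔP − R T Δc_s)`.  This construction is exactly
self-consistent: integrating it from the right chamber recovers the left
chamber pressure identically, and the interior slope satisfies
`Φ_V = −h Lp dP/dx`.  The within-membrane profile is restricted to this
linear form; structured membranes with a nonuniform interior are out of
scope.  The full zero-flux/balance ODE system is also integrated directly
(`numeric_ode_solution`, LSODA at rtol 1e-12) as an independent cross-check
of the closed form; agreement is required to 1e-8 of the bulk scales.

**Vegard drop.**  The interfacial drop is read off the pressure array at the
barrier maximum (membrane midpoint), where exclusion is complete.  With
smooth finite-width barriers the interface region and the viscous gradient
overlap spatially, so for a flowing steady state the viscous ramp
accumulated between the membrane face and the measurement point is
subtracted; what remains is the purely osmotic interfacial drop, equal to
`R T c_s,r`.

**Grids.**  Default grids hold 2001 points over the membrane plus two
chambers of width `5h`, graded so that ~60% of the points resolve the
interface region (≥ 20 points per interface width); a too-coarse grid is
rejected with the required spacing in the error message.  Profile solves
complete in well under a second.

## Particle simulations (`particles`)

The particle level drops the continuum assumption and asks whether
membrane-solute repulsion alone produces the van 't Hoff pressure.  Ideal
(non-interacting) solute particles follow overdamped Langevin dynamics

    x += μ F(x) dt + sqrt(2 D_s dt) ξ,     μ = D_s / (R T),

in a closed box with reflecting outer walls and the barrier in the middle —
the solvent is implicit, entering only through the mobility and the noise.
The measured observable is the time-averaged total force the membrane
exerts on the right-chamber particles per unit area, whose stationary
expectation is `R T c_b (1 − e^{-U_max/RT})` for bulk concentration `c_b`
(set by N, the box, and the Boltzmann accessible volume).

Protocol choices that matter:

- **Warm start.**  Initial positions are rejection-sampled from the
  stationary density `e^{-U/RT}`.  A uniform start strands particles on the
  barrier; the expelled excess piles up near the membrane face and decays
  only on the chamber mixing time `L²/2D`, biasing the force upward by tens
  of percent at short run lengths.
- **Error bars across particles, not time blocks.**  The force statistic
  carries slow components (single-particle chamber re-visits at `L²/D`, and
  the left/right particle split frozen at initialization), so time blocks
  of any feasible length underestimate the error.  Because the particles
  are independent, the per-particle time-averaged forces are i.i.d., and
  `stderr = sqrt(N) · std(per-particle means) / A` is exact.  Calibration
  over 10 seeds gives z-scores with mean −0.5 and standard deviation 0.8.
  Twenty time-block means are still recorded as a trajectory summary.
- **Stability bound.**  `dt` must satisfy `μ |F|_max dt ≤ w/10`; a
  violating configuration is refused with the largest admissible `dt`.
- **Histogram comparison.**  The sampled concentration histogram is
  compared with the *bin-averaged* Boltzmann profile (center evaluation
  misrepresents bins straddling an interface).  The predicted per-bin noise
  combines binomial occupancy, the diffusive correlation of successive
  snapshots (`τ_bin = Δ²/2D`), and the frozen chamber-split binomial.

The generator's default test geometry is reduced-unit: `h = 1`, `w = 0.05`,
chambers of length 4, `D_s = 1`, `R T = 1`, `U_max = 30 RT`.  The headline
verification runs N = 10,000 particles for 1e5 production steps at
`dt = 1e-5`.  What passing shows: the collision-level force balance
reproduces the continuum prediction within its honest statistical error.
What it does not show: explicit-solvent effects, momentum transfer, or
water flux — solute statics suffice to exhibit the interfacial pressure.

## Donnan pump-leak model (`donnan`)

A pliant-membrane "cell" exchanges a permeant solute A with an infinite
bath (first-order rate `k`) and carries `b` moles of impermeant B:

    dA_in/dt = k (A_e − A_in) − p,
    dw/dt    = λ (A_in + b/w − A_e − B_e).

The volume law is the package's closure: with a pliant membrane the
hydrostatic difference is ≈ 0 and the combined flux law reduces to a volume
change proportional to the osmolarity imbalance (coupling `λ`,
m³ s⁻¹ per mol m⁻³).  The permeant equation is kept in concentration form
(no dilution term); the qualitative conclusions — and the exponential
relaxation of `A_in` at rate `k` — are unchanged, and this matches the
kinetic constraint as usually written.  The pump is constant-rate removal
`p`, the simplest mechanism; first-order pumping would shift the fixed
point but not the regime structure.  `p/k ≥ A_e` is rejected (it would
drive `A_in` negative).

Fixed points: `A_in* = A_e − p/k` always; the volume stabilizes at
`w* = b/(B_e + p/k)` when the denominator is positive.  With `b > 0` and no
countermeasure the kinetic and osmotic constraints are incompatible at any
finite volume and `w` grows without bound (as `sqrt(w0² + 2 λ b t)` once
`A_in` has relaxed).  `classify_regime` names the four regimes; the
integrator (LSODA, rtol 1e-9) guards against `w ≤ 0` and reports a collapse
instead of integrating through it.

## Mixture arithmetic (`mixtures`)

From mole bookkeeping with composition-independent partial molar volumes,

    c_w + c_s = (1/v_w) / (1 + X_s (v_s/v_w − 1)),
    Δc_w(pure → solution) = c_s v_s / v_w,

so the water-concentration deficit at fixed osmolarity depends on the
solute's partial molar volume — it is species-specific, unlike osmotic
flow, which is why "water diffuses down its own concentration gradient" is
not a tenable mechanism.  The 55.5 M total is recovered exactly when
`v_s = v_w = v_w0` (a D₂O-like solute).  Inputs with solute volume fraction
`c_s v_s ≥ 0.1` are rejected as non-dilute.

## Configuration and outputs (`config`, `cli`)

Scenario configs are YAML with `{value, unit}` pairs for every physical
quantity and strict schemas (unknown keys rejected, offending key named).
Units convert to SI at the boundary; barrier heights may be given in `RT`.
Each run logs the resolved SI parameters, the seed, and the package
version; summaries are JSON and tables (profiles, histograms, time series)
are CSV.  `generate_fixtures` emits one canonical config per scenario
family, all runnable in seconds except the particle scenario (a reduced
N = 2000 run, under a minute).

## Known limitations

- Dilute ideal solutions only: no activity coefficients, no
  osmolarity/osmolality distinction, no solute-solute interactions.
- Strictly semipermeable membranes in the continuum steady state; leaky
  barriers are rejected rather than approximated.
- 1-D geometry throughout; no reflection coefficients or partially
  permeable solutes; no charged solutes or electro-neutrality constraints
  in the Donnan model.
- Euler-Maruyama discretization has O(dt) weak bias; the stability bound
  keeps it well below the statistical resolution of the shipped
  configurations, but very long runs at the bound would eventually resolve
  it.
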