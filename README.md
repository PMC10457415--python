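# osmosim

A Python library for the **mechanical model of osmosis**: the picture in
which a semipermeable membrane repels solute molecules through a potential
barrier `U(x)`, and that repulsion — via mechanical balance of the fluid —
creates the interfacial pressure drops that drive osmotic water flow.

The package is for biophysicists, physiologists and membrane scientists who
want the mechanism of osmosis as runnable, testable code rather than as a
thermodynamic identity: why the same hydraulic coefficient answers both a
pressure difference and an osmolarity difference, what the pressure profile
inside a membrane actually looks like, why a water-concentration-gradient
("water diffuses") explanation fails, and how an impermeant intracellular
solute blows a cell up unless it pumps.

## The model

Zero solute flux against the membrane force `F = -dU/dx` gives the
Boltzmann exclusion profile, and mechanical balance of each fluid slice
turns it into a pressure profile:

    RT dc/dx = c F,        dP/dx = c F        =>   P_r - P_0 = R T c_s,r

— van 't Hoff's law, with the shape of `F` cancelling from the result.  Out
of equilibrium the interfacial drop `R T c_s` is unbalanced and appears as
a linear pressure gradient across the membrane interior, driving Darcy
flow; the combined law

    Φ_V = -Lp (ΔP - R T Δc_s)

emerges with one coefficient for both drivers.  The same framework yields
the permeability algebra `Pf = R T Lp / v_w0`, the convective diagnostic
`Pf/Pd - 1 = Pc/Pd`, the solubility-diffusion bilayer result
`Pf = Pd = K D / h` (so `Pf/Pd = 1`), a Brownian-dynamics verification that
solute-membrane repulsion alone generates `R T c`, and the Donnan pump-leak
cell-volume model.

## Worked example

```python
from osmosim import (MembranePotential, SolutionState, R,
                     steady_state_profile, vegard_drop)

T = 300.0
pot = MembranePotential.plateau(U_max=30 * R * T, span=1e-8)  # 10 nm membrane
prof = steady_state_profile(
    pot, Lp=1e-12,
    left=SolutionState(c_s=0.0, P=0.0, T=T),      # pure water
    right=SolutionState(c_s=100.0, P=0.0, T=T),   # 0.1 osmolar solution
)
print(prof.phi_V)          # +2.4942e-07  m/s, water flows toward the solution
print(vegard_drop(prof))   # 249420 Pa, the interfacial drop R T c_s
```

The flux equals `-Lp(ΔP - RTΔc) = 1e-12 × 8.314 × 300 × 100 = 2.4942e-7 m/s`
even though the chamber pressures are equal: the 249,420 Pa (~2.5 atm)
pressure drop at the solution-side interface tilts the pressure inside the
membrane, and water runs down that gradient.  Applying exactly 249,420 Pa of
excess pressure to the solution chamber stops the flow — van 't Hoff's
equilibrium.

The `examples/` directory has one short script per capability (flux-law
algebra, continuum profiles, the Brownian-dynamics pressure measurement,
Donnan regimes, mixture arithmetic), each printing annotated numbers.  A
thin CLI mirrors the library for batch runs from YAML configs:

```bash
osmosim fixtures --out fixtures            # canonical scenario configs
osmosim profile --config fixtures/vegard_steady_state.yaml --out results
```

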