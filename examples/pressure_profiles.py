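"""Continuum solute and pressure profiles across a repulsive-barrier membrane.

Builds a 10 nm membrane as a 30 RT plateau barrier, solves the equilibrium
and osmotic-steady-state profiles, and prints the chamber pressure
difference, the interfacial (Vegard) pressure drop and the volume flux.
The steady-state numbers show osmosis as pressure-driven flow: the
interface drop R T c_s tilts the pressure inside the membrane, and water
runs down that gradient toward the solution.
"""

from osmosim import (
    MembranePotential,
    R,
    SolutionState,
    equilibrium_profile,
    steady_state_profile,
    vegard_drop,
)

T = 300.0
c_right = 100.0  # mol m^-3 solution in the right chamber, pure water left
pot = MembranePotential.plateau(U_max=30 * R * T, span=1e-8)

eq = equilibrium_profile(pot, c_bulk_right=c_right, P_right=0.0, T=T)
print("equilibrium (no flow):")
print(f"  chamber delta-P   = {eq.delta_p_chambers():,.0f} Pa  (van 't Hoff: R T c = {R*T*c_right:,.0f} Pa)")
print(f"  Vegard drop       = {vegard_drop(eq):,.0f} Pa at the solution-side interface")

ss = steady_state_profile(
    pot, Lp=1e-12,
    left=SolutionState(c_s=0.0, P=0.0, T=T),
    right=SolutionState(c_s=c_right, P=0.0, T=T),
)
print("osmotic steady state (equal chamber pressures):")
print(f"  volume flux       = {ss.phi_V:+.4e} m/s (left to right, into the solution)")
print(f"  Vegard drop       = {vegard_drop(ss):,.0f} Pa (same interfacial drop as at equilibrium)")
print("  the drop is no longer balanced: it appears as a linear pressure")
print("  gradient across the membrane interior and drives Darcy flow")
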