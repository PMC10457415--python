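"""Combined flux law and permeability algebra for a synthetic membrane.

A membrane with hydraulic permeability Lp separates pure water from a
100 mol/m^3 (0.1 osmolar) solution at 300 K with equal chamber pressures.
The script prints the osmotic volume flux, the equilibrium (van 't Hoff)
pressure that would stop it, and the convective fraction implied by a
measured Pf/Pd ratio.
"""

from osmosim import (
    convective_fraction,
    fundamental_flux,
    pf_from_lp,
    van_t_hoff_delta_p,
)

Lp = 1e-12      # m s^-1 Pa^-1
T = 300.0       # K
delta_c = 100.0  # mol m^-3, right minus left

res = fundamental_flux(Lp, delta_P=0.0, delta_c=delta_c, T=T)
print(f"volume flux phi_V          = {res.phi_V:+.4e} m/s (toward the solution)")
print(f"molar water flux phi_w     = {res.phi_w:+.4e} mol m^-2 s^-1")

dP_eq = van_t_hoff_delta_p(delta_c, T)
print(f"equilibrium delta-P        = {dP_eq:,.0f} Pa  (~2.5 atm stops the flow)")
stopped = fundamental_flux(Lp, delta_P=dP_eq, delta_c=delta_c, T=T)
print(f"flux at that pressure      = {stopped.phi_V:.1e} m/s")

Pf = pf_from_lp(Lp, T)
print(f"osmotic permeability Pf    = {Pf:.4e} m/s  (= R T Lp / v_w0)")

# a porous synthetic membrane where tracer diffusion carries 1/730 of the flow
Pd = Pf / 730.0
print(f"convective fraction Pc/Pd  = {convective_fraction(Pf, Pd):.0f}"
      "  (flow through this membrane is almost entirely convective)")
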