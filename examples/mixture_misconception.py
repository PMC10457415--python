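"""Why "water diffuses down its concentration gradient" cannot explain osmosis.

Compares the water-concentration deficit of solutions with the same
osmolarity but different solute partial molar volumes.  The deficit is
species-specific while the osmotic flux is not, so a water-concentration
gradient cannot be the driving quantity.  Also evaluates the c_w + c_s sum,
which collapses to 55.5 M only for a D2O-like solute.
"""

from osmosim import MixtureSpec, V_W0, concentration_sum, water_concentration_difference

c_s = 100.0  # mol m^-3, same osmolarity for every solute below

print(f"solutions at c_s = {c_s:.0f} mol/m^3:")
for label, v_s in [("D2O-like (v_s = v_w0)", V_W0), ("sucrose-like (v_s ~ 12 v_w0)", 12 * V_W0)]:
    dcw = water_concentration_difference(c_s, v_s)
    print(f"  {label:30s} water deficit = {dcw:7.1f} mol/m^3")
print("same osmolarity, different water gradients -> water concentration")
print("cannot be what drives the (species-independent) osmotic flux")

print()
X_s = 0.018
for label, v_s in [("v_s = v_w0", V_W0), ("v_s = 2 v_w0", 2 * V_W0)]:
    total = concentration_sum(MixtureSpec(X_s=X_s, v_w=V_W0, v_s=v_s))
    print(f"c_w + c_s at X_s = {X_s}, {label:12s} = {total / 1000:.2f} M")
print("the 55.5 M total is itself a special case, not a law")
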