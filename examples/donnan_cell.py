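"""Donnan swelling and its stabilization in the pump-leak toy cell.

Three scenarios for a 1 femtoliter-scale cell in a 100 mol/m^3 bath:
no impermeant load (stable), an impermeant load with no countermeasure
(unbounded swelling), and the same load with active extrusion of the
permeant solute (volume pinned at w* = b k / p).
"""

from osmosim import DonnanParams, DonnanState, classify_regime, fixed_point, simulate_donnan

w0 = 1e-15  # m^3
initial = DonnanState(w=w0, A_in=100.0)

for label, params in [
    ("no impermeant load", DonnanParams(k=1.0, A_e=100.0, lam=1e-18)),
    ("load b = 1e-13 mol, no countermeasure", DonnanParams(k=1.0, A_e=100.0, b=1e-13, lam=1e-18)),
    ("load + pump p = 10 mol m^-3 s^-1", DonnanParams(k=1.0, A_e=100.0, b=1e-13, p=10.0, lam=1e-15)),
]:
    series = simulate_donnan(initial, params, t_end=600.0)
    regime = classify_regime(params)
    line = f"{label:42s} regime={regime:22s} w(600 s)/w0 = {series['w'].iloc[-1] / w0:8.2f}"
    fp = fixed_point(params)
    if fp is not None and fp[0] == fp[0] and fp[0] != float("inf"):
        line += f"   w* = {fp[0]:.2e} m^3"
    print(line)

print()
print("without a countermeasure the osmotic and exchange constraints are")
print("incompatible at any finite volume: the cell swells without ceasing;")
print("pumping the permeant out pins the volume at w* = b k / p")
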