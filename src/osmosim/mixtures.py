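"""Water-plus-solute concentration arithmetic in the dilute ideal regime.

These helpers quantify why "osmosis is diffusion of water down its own
concentration gradient" fails: the water-concentration difference between
pure water and a solution depends not only on the solute concentration but
on the ratio of the solute's partial molar volume to that of water — it is
solute-species-specific, whereas the osmotic flux is not.

With mole fraction X_s = n_s/(n_w + n_s) and partial molar volumes v_w, v_s
treated as composition-independent constants, the total molar concentration
is

    c_w + c_s = (n_w + n_s)/(n_w v_w + n_s v_s)
              = (1/v_w) / (1 + X_s (v_s/v_w - 1)),

which collapses to the constant 1/v_w0 = 55.5 M only when v_s = v_w = v_w0,
i.e. for a solute essentially identical to water (D2O).
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import V_W0

__all__ = ["MixtureSpec", "concentration_sum", "water_concentration_difference"]

#: Largest solute volume fraction c_s * v_s accepted as "dilute".
DILUTE_LIMIT = 0.1


@dataclass(frozen=True)
class MixtureSpec:
    """A binary water-solute mixture.

    X_s : solute mole fraction, 0 <= X_s < 1
    v_w : partial molar volume of water [m^3 mol^-1], > 0
    v_s : partial molar volume of solute [m^3 mol^-1], > 0
    """

    X_s: float
    v_w: float = V_W0
    v_s: float = V_W0

    def __post_init__(self) -> None:
        if not 0 <= self.X_s < 1:
            raise ValueError(f"mole fraction must be in [0, 1), got {self.X_s}")
        if self.v_w <= 0 or self.v_s <= 0:
            raise ValueError(
                f"partial molar volumes must be > 0, got v_w={self.v_w}, v_s={self.v_s}"
            )


def concentration_sum(spec: MixtureSpec) -> float:
    """Total molar concentration c_w + c_s [mol m^-3].

    Equals (n_w + n_s)/(n_w v_w + n_s v_s) for any mole numbers consistent
    with the mole fraction; independent of X_s exactly when v_s = v_w.
    """
    denom = 1.0 + spec.X_s * (spec.v_s / spec.v_w - 1.0)
    if denom <= 0:
        raise ValueError(
            f"nonphysical volumes: mixture molar volume v_w*denom = "
            f"{spec.v_w * denom:.3e} m^3/mol <= 0"
        )
    return (1.0 / spec.v_w) / denom


def water_concentration_difference(
    solute_conc: float, v_s: float, v_w: float = V_W0
) -> float:
    """Water-concentration deficit of a dilute solution vs pure water [mol m^-3].

    From the exact mole balance c_w = (1 - c_s v_s)/v_w,

        delta_c_w = c_w(pure) - c_w(solution) = c_s * v_s / v_w,

    which equals c_s only for v_s = v_w (a D2O-like solute): at fixed
    osmolarity the water-concentration difference varies with the solute
    species, so it cannot be the quantity driving the species-independent
    osmotic flux.
    """
    if solute_conc < 0:
        raise ValueError(f"solute concentration must be >= 0, got {solute_conc}")
    if v_s <= 0 or v_w <= 0:
        raise ValueError("partial molar volumes must be > 0")
    volume_fraction = solute_conc * v_s
    if volume_fraction >= DILUTE_LIMIT:
        raise ValueError(
            f"solution is not dilute: c_s*v_s = {volume_fraction:.3g} >= {DILUTE_LIMIT}"
        )
    return solute_conc * v_s / v_w
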