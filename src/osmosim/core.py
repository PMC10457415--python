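"""Physical constants, unit conversions, and shared state types.

Everything downstream works in SI internally: concentrations in mol m^-3,
pressures in Pa, temperatures in K, lengths in m.  Conversions from
bench-top units (molar, atm) are explicit helper functions — never implicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "R",
    "V_W0",
    "DEFAULT_TEMPERATURE",
    "ATM",
    "SolutionState",
    "TransportCoefficients",
    "to_si_concentration",
    "from_si_concentration",
    "atm_to_pa",
    "pa_to_atm",
]

#: Universal gas constant [J mol^-1 K^-1].
R: float = 8.314

#: Molar volume of pure water [m^3 mol^-1]; reciprocal of the 55.5 M
#: concentration of pure water.
V_W0: float = 1.802e-5

#: Temperature assumed when a caller does not specify one [K].
DEFAULT_TEMPERATURE: float = 298.15

#: One standard atmosphere [Pa].
ATM: float = 101325.0


def to_si_concentration(value_molar: float) -> float:
    """Convert a concentration from mol L^-1 (M) to mol m^-3.

    Parameters
    ----------
    value_molar : float
        Concentration in molar units; must be non-negative.

    Returns
    -------
    float
        The same concentration in mol m^-3 (``value_molar * 1000``).
    """
    if value_molar < 0:
        raise ValueError(f"concentration must be >= 0, got {value_molar} M")
    return value_molar * 1000.0


def from_si_concentration(value_si: float) -> float:
    """Convert a concentration from mol m^-3 to mol L^-1 (M)."""
    if value_si < 0:
        raise ValueError(f"concentration must be >= 0, got {value_si} mol/m^3")
    return value_si / 1000.0


def atm_to_pa(value_atm: float) -> float:
    """Convert a pressure from atmospheres to pascals."""
    return value_atm * ATM


def pa_to_atm(value_pa: float) -> float:
    """Convert a pressure from pascals to atmospheres."""
    return value_pa / ATM


@dataclass(frozen=True)
class SolutionState:
    """A well-stirred solution chamber.

    Attributes
    ----------
    c_s : float
        Osmolarity (total impermeant solute concentration) [mol m^-3], >= 0.
    P : float
        Hydrostatic pressure [Pa].  Only pressure *differences* matter
        physically, so any reference is acceptable.
    T : float
        Absolute temperature [K], > 0.
    """

    c_s: float
    P: float = 0.0
    T: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.c_s < 0:
            raise ValueError(f"osmolarity must be >= 0, got {self.c_s}")
        if self.T <= 0:
            raise ValueError(f"temperature must be > 0, got {self.T}")

    @property
    def rt_c(self) -> float:
        """The van 't Hoff term R*T*c_s [Pa] for this chamber."""
        return R * self.T * self.c_s


@dataclass(frozen=True)
class TransportCoefficients:
    """Membrane water-transport coefficients and their algebraic relations.

    ``Pf`` (osmotic/filtration permeability) and ``Pd`` (diffusional
    permeability, from tracer exchange) are molar-flux coefficients; their
    ratio diagnoses convection: ``Pf/Pd = 1`` for purely diffusive transport
    (lipid bilayer) and ``Pf/Pd >> 1`` for convective pore flow.  The
    additivity assumption ``Pf = Pc + Pd`` makes ``Pf/Pd >= 1`` whenever the
    convective part ``Pc`` is non-negative.

    Any subset of fields may be provided; cross-relations are only checked
    among the fields that are set (non-None).
    """

    Lp: float | None = None  # hydraulic permeability [m s^-1 Pa^-1]
    Pf: float | None = None  # osmotic permeability [m s^-1]
    Pd: float | None = None  # diffusional permeability [m s^-1]
    Pc: float | None = None  # convective contribution [m s^-1]
    v_w0: float = V_W0       # molar volume of pure water [m^3 mol^-1]
    K: float | None = None   # partition coefficient [-]
    D: float | None = None   # in-membrane water diffusion constant [m^2 s^-1]
    h: float | None = None   # membrane thickness [m]

    _REL_TOL = 1e-9

    def __post_init__(self) -> None:
        for name in ("Lp", "Pf", "Pd", "Pc", "K", "D"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.v_w0 <= 0:
            raise ValueError(f"v_w0 must be > 0, got {self.v_w0}")
        if self.h is not None and self.h <= 0:
            raise ValueError(f"membrane thickness h must be > 0, got {self.h}")
        if self.Pf is not None and self.Pc is not None and self.Pd is not None:
            scale = max(self.Pf, self.Pc + self.Pd, 1e-300)
            if abs(self.Pf - (self.Pc + self.Pd)) > self._REL_TOL * scale:
                raise ValueError(
                    f"inconsistent permeabilities: Pf={self.Pf} != Pc+Pd="
                    f"{self.Pc + self.Pd}"
                )
        if self.Pf is not None and self.Pd is not None and self.Pd > 0:
            if self.Pf / self.Pd < 1.0 - self._REL_TOL:
                raise ValueError(
                    f"Pf/Pd = {self.Pf / self.Pd} < 1 is inconsistent with a "
                    "non-negative convective contribution"
                )
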