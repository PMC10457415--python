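"""Phenomenological water-transport laws across a semipermeable membrane.

Sign convention, used throughout the package: the membrane is perpendicular
to x, the solution of higher osmolarity sits on the right, every difference
is Δq = q_right − q_left, and flux is positive in the +x (left→right)
direction.

The central relation is the combined flux law

    Φ_V = −Lp (ΔP − R T Δc_s),

which reduces to Darcy's law for pure water (Δc_s = 0) and to van 't Hoff's
equilibrium condition ΔP = R T Δc_s when the flux vanishes.  The same
hydraulic permeability Lp governs both the hydrostatic and the osmotic
driver — osmotic flow is pressure-driven flow.

The molar-flux form uses the osmotic permeability Pf = R T Lp / v_w0, and a
separate tracer experiment defines the diffusional permeability Pd.  Their
ratio Pf/Pd separates convective from diffusive water transport; the
solubility–diffusion model of a lipid bilayer (water partitioning into the
membrane and diffusing as independent molecules) predicts Pf = Pd = K D / h,
i.e. Pf/Pd = 1 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import R, V_W0

__all__ = [
    "FluxResult",
    "van_t_hoff_delta_p",
    "darcy_flux",
    "fundamental_flux",
    "molar_flux_form",
    "pf_from_lp",
    "lp_from_pf",
    "tracer_flux",
    "diffusive_flux_under_pressure",
    "convective_fraction",
    "solubility_diffusion_pf",
    "solubility_diffusion_pd",
    "bilayer_osmotic_flux",
    "bilayer_pressure_flux",
]


@dataclass(frozen=True)
class FluxResult:
    """A volume flux and the equivalent molar water flux.

    phi_V is the volume flux per unit membrane area [m s^-1], positive
    rightward; phi_w = phi_V / v_w0 is the molar water flux
    [mol m^-2 s^-1] when water alone carries the volume.
    """

    phi_V: float
    phi_w: float

    @classmethod
    def from_volume_flux(cls, phi_V: float, v_w0: float = V_W0) -> "FluxResult":
        return cls(phi_V=phi_V, phi_w=phi_V / v_w0)


def van_t_hoff_delta_p(delta_c: float, T: float) -> float:
    """Equilibrium pressure difference ΔP = R T Δc_s [Pa].

    Linear in the osmolarity difference and independent of solute identity
    (dilute ideal regime).
    """
    if T <= 0:
        raise ValueError(f"temperature must be > 0, got {T}")
    return R * T * delta_c


def darcy_flux(Lp: float, delta_P: float, v_w0: float = V_W0) -> FluxResult:
    """Hydraulic flow of pure water, Φ_V = −Lp ΔP.

    Flux is directed toward the lower-pressure side.
    """
    if Lp < 0:
        raise ValueError(f"Lp must be >= 0, got {Lp}")
    return FluxResult.from_volume_flux(-Lp * delta_P, v_w0)


def fundamental_flux(
    Lp: float, delta_P: float, delta_c: float, T: float, v_w0: float = V_W0
) -> FluxResult:
    """Combined flux law Φ_V = −Lp (ΔP − R T Δc_s).

    Zero exactly at the van 't Hoff balance ΔP = R T Δc_s; reduces to
    :func:`darcy_flux` when Δc_s = 0.
    """
    if Lp < 0:
        raise ValueError(f"Lp must be >= 0, got {Lp}")
    if T <= 0:
        raise ValueError(f"temperature must be > 0, got {T}")
    return FluxResult.from_volume_flux(-Lp * (delta_P - R * T * delta_c), v_w0)


def molar_flux_form(Pf: float, delta_P: float, delta_c: float, T: float) -> float:
    """Molar water flux ϕ_w = −Pf (ΔP/RT − Δc_s) [mol m^-2 s^-1].

    Algebraically identical to ``fundamental_flux(...).phi_w`` when
    Pf = R T Lp / v_w0.
    """
    if Pf < 0:
        raise ValueError(f"Pf must be >= 0, got {Pf}")
    if T <= 0:
        raise ValueError(f"temperature must be > 0, got {T}")
    return -Pf * (delta_P / (R * T) - delta_c)


def pf_from_lp(Lp: float, T: float, v_w0: float = V_W0) -> float:
    """Osmotic permeability Pf = R T Lp / v_w0 [m s^-1]."""
    if v_w0 <= 0:
        raise ValueError(f"v_w0 must be > 0, got {v_w0}")
    if T <= 0:
        raise ValueError(f"temperature must be > 0, got {T}")
    return R * T * Lp / v_w0


def lp_from_pf(Pf: float, T: float, v_w0: float = V_W0) -> float:
    """Invert :func:`pf_from_lp`: Lp = Pf v_w0 / (R T)."""
    if T <= 0:
        raise ValueError(f"temperature must be > 0, got {T}")
    return Pf * v_w0 / (R * T)


def tracer_flux(Pd: float, delta_c_star: float) -> float:
    """Diffusional flux of isotopically labeled water, ϕ_w* = −Pd Δc_w*.

    Measured with no pressure or osmolarity difference; defines Pd.
    """
    if Pd < 0:
        raise ValueError(f"Pd must be >= 0, got {Pd}")
    return -Pd * delta_c_star


def diffusive_flux_under_pressure(Pd: float, delta_P: float, T: float) -> float:
    """Diffusive component of pressure-driven water flux, ϕ_w,d = −Pd ΔP/RT.

    The same Pd measured by tracer exchange governs the force-driven
    diffusive component (Einstein-relation argument).
    """
    if Pd < 0:
        raise ValueError(f"Pd must be >= 0, got {Pd}")
    if T <= 0:
        raise ValueError(f"temperature must be > 0, got {T}")
    return -Pd * delta_P / (R * T)


def convective_fraction(Pf: float, Pd: float) -> float:
    """Convective-to-diffusive ratio Pc/Pd = Pf/Pd − 1.

    Raises if Pf < Pd: with additive convective and diffusive contributions
    (Pf = Pc + Pd, Pc >= 0) the smallest possible Pf/Pd is unity.
    """
    if Pd <= 0:
        raise ValueError(f"Pd must be > 0, got {Pd}")
    if Pf < Pd:
        raise ValueError(
            f"Pf/Pd = {Pf / Pd} < 1 is inconsistent with a non-negative "
            "convective contribution Pc"
        )
    return Pf / Pd - 1.0


def solubility_diffusion_pf(K: float, D: float, h: float) -> float:
    """Osmotic permeability of a lipid bilayer, Pf = K D / h [m s^-1].

    K is the water partition coefficient (membrane/bulk), D the diffusion
    constant of independent water molecules inside the membrane, h the
    membrane thickness.
    """
    if K < 0 or D < 0:
        raise ValueError(f"K and D must be >= 0, got K={K}, D={D}")
    if h <= 0:
        raise ValueError(f"membrane thickness must be > 0, got {h}")
    return K * D / h


def solubility_diffusion_pd(K: float, D: float, h: float) -> float:
    """Diffusional permeability of a lipid bilayer: also K D / h.

    By inspection the tracer route gives the same coefficient as the osmotic
    route, so Pf/Pd = 1 for a membrane crossed by independent molecules.
    """
    return solubility_diffusion_pf(K, D, h)


def bilayer_pressure_flux(K: float, D: float, h: float, delta_P: float, T: float) -> float:
    """Pressure-driven molar water flux through a bilayer, ϕ_w = −(KD/h) ΔP/RT."""
    if T <= 0:
        raise ValueError(f"temperature must be > 0, got {T}")
    return -solubility_diffusion_pf(K, D, h) * delta_P / (R * T)


def bilayer_osmotic_flux(K: float, D: float, h: float, c_s: float) -> float:
    """Osmotic molar water flux through a bilayer, ϕ_w = (KD/h) c_s.

    c_s is the osmolarity of the solution chamber (pure water on the other
    side); the interfacial pressure drop R T c_s replaces ΔP in the
    pressure-driven expression, so the flux is toward the solution.
    """
    if c_s < 0:
        raise ValueError(f"osmolarity must be >= 0, got {c_s}")
    return solubility_diffusion_pf(K, D, h) * c_s
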