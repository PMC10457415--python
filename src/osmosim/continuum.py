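"""Continuum solute and pressure profiles across a repulsive-barrier membrane.

The mechanistic picture: a semipermeable membrane acts on solute molecules
with a repulsive force F(x) = -dU/dx derived from a potential barrier U(x)
spanning the membrane.  Requiring zero solute flux,

    j_s = -D dc/dx + c (D/RT) F = 0,

gives the Boltzmann concentration profile c(x) = c_bulk exp(-U(x)/RT), and
mechanical balance of a fluid slice, dP/dx = c F, then forces a pressure
drop R T c_bulk across each membrane-solution interface — van 't Hoff's law
emerges with the detailed shape of F cancelling from the result.

Away from equilibrium the interfaces stay quasi-equilibrated (well-stirred
chambers) while the interfacial pressure drops no longer cancel: a pressure
gradient appears inside the membrane and drives water exactly as an applied
hydrostatic difference would,

    Phi_V = -h Lp (dP/dx - RT dc/dx),   Phi_V = -h Lp dP/dx inside,

reproducing the combined flux law Phi_V = -Lp (dP - RT dc_s).

Barriers are finite and smooth (the infinite-wall picture is a limit); a
barrier is treated as impermeable once U_max >= 30 RT, where the Boltzmann
leakage factor e^-30 < 1e-13.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .core import R, SolutionState

__all__ = [
    "IMPERMEABLE_RT_MULTIPLE",
    "MembranePotential",
    "SpatialGrid",
    "ContinuumProfile",
    "equilibrium_profile",
    "steady_state_profile",
    "vegard_drop",
    "numeric_ode_solution",
]

#: Barrier height, in units of RT, above which the membrane is treated as
#: completely impermeable (exclusion error e^-30 < 1e-13).
IMPERMEABLE_RT_MULTIPLE: float = 30.0


def _logistic(t: np.ndarray) -> np.ndarray:
    # numerically safe logistic, no overflow for large |t|
    out = np.empty_like(t, dtype=float)
    pos = t >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-t[pos]))
    ez = np.exp(t[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass(frozen=True)
class MembranePotential:
    """Repulsive membrane-solute potential barrier on the interval [0, h].

    Two smooth families are provided; both vanish in the bulk chambers and
    exert a finite force F(x) = -dU/dx everywhere:

    - ``smooth-plateau``: a flat-topped barrier, U_max multiplied by a
      product of logistic edges of width ``interface_width``.
    - ``gaussian-barrier``: a Gaussian bump centered at h/2 with standard
      deviation ``interface_width``.

    Parameters
    ----------
    shape : {"smooth-plateau", "gaussian-barrier"}
    U_max : float
        Barrier height [J mol^-1], >= 0.
    span : float
        Membrane thickness h [m]; the barrier occupies [0, h].
    interface_width : float
        Smoothing length of each edge [m].
    """

    shape: str
    U_max: float
    span: float
    interface_width: float

    SHAPES = ("smooth-plateau", "gaussian-barrier")

    def __post_init__(self) -> None:
        if self.shape not in self.SHAPES:
            raise ValueError(f"unknown potential shape {self.shape!r}; choose from {self.SHAPES}")
        if self.U_max < 0:
            raise ValueError(f"U_max must be >= 0, got {self.U_max}")
        if self.span <= 0:
            raise ValueError(f"membrane span must be > 0, got {self.span}")
        if not 0 < self.interface_width <= self.span / 4:
            raise ValueError(
                f"interface_width must be in (0, span/4], got {self.interface_width} "
                f"for span {self.span}"
            )

    @classmethod
    def plateau(cls, U_max: float, span: float, interface_width: float | None = None) -> "MembranePotential":
        """Smooth-plateau barrier; default edge width span/20."""
        return cls("smooth-plateau", U_max, span, interface_width or span / 20)

    @classmethod
    def gaussian(cls, U_max: float, span: float, interface_width: float | None = None) -> "MembranePotential":
        """Gaussian barrier; default width span/20."""
        return cls("gaussian-barrier", U_max, span, interface_width or span / 20)

    def energy(self, x: np.ndarray) -> np.ndarray:
        """Potential energy U(x) [J mol^-1]."""
        x = np.asarray(x, dtype=float)
        h, w = self.span, self.interface_width
        if self.shape == "smooth-plateau":
            return self.U_max * _logistic(x / w) * _logistic((h - x) / w)
        return self.U_max * np.exp(-((x - h / 2) ** 2) / (2 * w**2))

    def force(self, x: np.ndarray) -> np.ndarray:
        """Membrane force on solute, F(x) = -dU/dx [J mol^-1 m^-1] (analytic)."""
        x = np.asarray(x, dtype=float)
        h, w = self.span, self.interface_width
        if self.shape == "smooth-plateau":
            a = _logistic(x / w)
            b = _logistic((h - x) / w)
            # d/dx [a*b] = a'(x/w)/w * b - a * b'((h-x)/w)/w
            da = a * (1 - a) / w
            db = b * (1 - b) / w
            return -self.U_max * (da * b - a * db)
        u = self.energy(x)
        return u * (x - h / 2) / w**2

    def max_force(self) -> float:
        """Largest |F| on a fine sample of the barrier region (for stability bounds)."""
        xs = np.linspace(-4 * self.interface_width, self.span + 4 * self.interface_width, 20001)
        return float(np.max(np.abs(self.force(xs))))

    def is_impermeable(self, T: float) -> bool:
        """True once U_max >= 30 RT (Boltzmann leakage below 1e-13)."""
        return self.U_max >= IMPERMEABLE_RT_MULTIPLE * R * T


@dataclass(frozen=True)
class SpatialGrid:
    """Strictly increasing 1-D grid; the membrane occupies [0, h].

    The solution chamber sits on the right (x > h), pure solvent or the
    lower-osmolarity chamber on the left (x < 0).
    """

    x: np.ndarray
    h: float

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        object.__setattr__(self, "x", x)
        if x.ndim != 1 or x.size < 3:
            raise ValueError("grid must be a 1-D array with at least 3 points")
        if not np.all(np.diff(x) > 0):
            raise ValueError("grid coordinates must be strictly increasing")
        if self.h <= 0:
            raise ValueError(f"membrane thickness must be > 0, got {self.h}")

    @classmethod
    def for_membrane(
        cls,
        potential: MembranePotential,
        n_points: int = 2001,
        chamber_width: float | None = None,
        core_fraction: float = 0.6,
    ) -> "SpatialGrid":
        """Graded grid: fine inside the interface region, coarse in chambers.

        The core region [-4w, h+4w] receives ``core_fraction`` of the points
        so that each interface width is resolved by >= 20 points at the
        default sizes; chambers (default width 5h each) are sampled coarsely.
        """
        h, w = potential.span, potential.interface_width
        L = chamber_width if chamber_width is not None else 5 * h
        lo, hi = -4 * w, h + 4 * w
        n_core = int(n_points * core_fraction)
        n_side = (n_points - n_core) // 2
        left = np.linspace(-L, lo, n_side, endpoint=False)
        core = np.linspace(lo, hi, n_core, endpoint=False)
        right = np.linspace(hi, h + L, n_points - n_core - n_side)
        return cls(np.concatenate([left, core, right]), h)

    def check_resolves(self, interface_width: float, points_per_width: int = 20) -> None:
        """Raise if the grid is too coarse near the interfaces."""
        h, w = self.h, interface_width
        mask = (self.x >= -3 * w) & (self.x <= h + 3 * w)
        if mask.sum() < 2:
            raise ValueError("grid does not cover the membrane interface region")
        dx = np.diff(self.x[mask.nonzero()[0]])
        required = w / points_per_width
        if dx.max() > required:
            raise ValueError(
                f"grid too coarse near the interfaces: max spacing {dx.max():.3e} m "
                f"exceeds interface_width/{points_per_width} = {required:.3e} m"
            )


@dataclass(frozen=True)
class ContinuumProfile:
    """Solute concentration c(x), pressure P(x) and the scalar volume flux.

    ``flow_gradient`` stores the intramembrane viscous pressure gradient
    -phi_V/(h Lp) (zero at equilibrium); :func:`vegard_drop` uses it to
    separate the interfacial (osmotic) pressure drop from the viscous ramp,
    which overlap spatially for smooth finite-width barriers.
    """

    grid: SpatialGrid
    c: np.ndarray
    P: np.ndarray
    phi_V: float
    potential: MembranePotential | None = None
    T: float | None = None
    c_bulk_left: float = 0.0
    c_bulk_right: float = 0.0
    flow_gradient: float = 0.0

    def delta_p_chambers(self) -> float:
        """Chamber-to-chamber pressure difference, right minus left [Pa]."""
        return float(self.P[-1] - self.P[0])

    def _viscous_ramp(self, x: np.ndarray) -> np.ndarray:
        """Pressure contribution of the intramembrane viscous gradient at x,

        relative to the right bulk: flow_gradient * (overlap of [x, inf)
        with the membrane interval [0, h])."""
        h = self.grid.h
        return -self.flow_gradient * (h - np.clip(np.asarray(x, dtype=float), 0.0, h))


def _boltzmann_concentration(
    potential: MembranePotential,
    grid: SpatialGrid,
    T: float,
    c_bulk_left: float,
    c_bulk_right: float,
) -> np.ndarray:
    """Two-sided Boltzmann profile: each half-space equilibrates with its chamber.

    c(x) = c_bulk exp(-U(x)/RT) using the bulk of the same side of the
    barrier midpoint; for an impermeable barrier the mismatch at the
    midpoint is below the e^-30 exclusion error.
    """
    x = grid.x
    boltz = np.exp(-potential.energy(x) / (R * T))
    mid = potential.span / 2
    c = np.where(x < mid, c_bulk_left * boltz, c_bulk_right * boltz)
    return c


def equilibrium_profile(
    potential: MembranePotential,
    c_bulk_right: float,
    P_right: float,
    T: float,
    grid: SpatialGrid | None = None,
    c_bulk_left: float = 0.0,
) -> ContinuumProfile:
    """Equilibrium concentration and pressure profiles (closed form).

    c(x) is the Boltzmann profile; P follows from dP/dx = RT dc/dx anchored
    at the right-chamber pressure.  The left-chamber pressure comes out as
    P_right - RT (c_r - c_l) (1 - e^{-U_max/RT}) for matching exclusion on
    both sides; with pure solvent on the left and an impermeable barrier it
    is lower than P_right by the full van 't Hoff term R T c_r.
    """
    if c_bulk_right < 0 or c_bulk_left < 0:
        raise ValueError("bulk concentrations must be >= 0")
    if T <= 0:
        raise ValueError(f"temperature must be > 0, got {T}")
    if grid is None:
        grid = SpatialGrid.for_membrane(potential)
    grid.check_resolves(potential.interface_width)

    x = grid.x
    c = _boltzmann_concentration(potential, grid, T, c_bulk_left, c_bulk_right)
    mid = potential.span / 2
    right = x >= mid
    P = np.empty_like(c)
    # right half: integrate dP = RT dc inward from the right bulk
    P[right] = P_right - R * T * (c_bulk_right - c[right])
    # continuity of P at the midpoint, then integrate out to the left bulk
    i_mid = int(np.argmax(right))  # first index of the right half
    boltz_mid_left = np.exp(-potential.energy(np.array([x[i_mid - 1]])) / (R * T))[0] if i_mid > 0 else 0.0
    P_mid = P_right - R * T * (c_bulk_right - c[i_mid])
    P[~right] = P_mid + R * T * (c[~right] - c_bulk_left * boltz_mid_left)
    return ContinuumProfile(
        grid=grid, c=c, P=P, phi_V=0.0, potential=potential, T=T,
        c_bulk_left=c_bulk_left, c_bulk_right=c_bulk_right, flow_gradient=0.0,
    )


def steady_state_profile(
    potential: MembranePotential,
    Lp: float,
    left: SolutionState,
    right: SolutionState,
    grid: SpatialGrid | None = None,
    T: float | None = None,
) -> ContinuumProfile:
    """Osmotic steady state between two well-stirred chambers.

    The interfaces stay quasi-equilibrated (Boltzmann in c against the
    adjacent bulk) while a constant viscous pressure gradient
    -phi_V/(h Lp) spans the membrane interval, so that

        dP/dx = RT dc/dx - (phi_V / (h Lp)) * 1_[0,h](x),

    integrated from the right-chamber boundary condition.  The resulting
    scalar flux satisfies the combined law phi_V = -Lp (dP - RT dc) exactly,
    and the left-chamber pressure is recovered identically.
    """
    if Lp < 0:
        raise ValueError(f"Lp must be >= 0, got {Lp}")
    if T is None:
        if abs(left.T - right.T) > 1e-9 * left.T:
            raise ValueError(f"chamber temperatures differ: {left.T} vs {right.T}")
        T = left.T
    if not potential.is_impermeable(T):
        raise ValueError(
            f"barrier U_max = {potential.U_max:.3e} J/mol is below the impermeable "
            f"threshold {IMPERMEABLE_RT_MULTIPLE} RT = {IMPERMEABLE_RT_MULTIPLE * R * T:.3e} J/mol; "
            "leaky membranes are out of scope"
        )
    if grid is None:
        grid = SpatialGrid.for_membrane(potential)
    grid.check_resolves(potential.interface_width)

    h = potential.span
    delta_P = right.P - left.P
    delta_c = right.c_s - left.c_s
    phi_V = -Lp * (delta_P - R * T * delta_c)
    flow_gradient = -phi_V / (h * Lp) if Lp > 0 else 0.0

    x = grid.x
    c = _boltzmann_concentration(potential, grid, T, left.c_s, right.c_s)
    mid = h / 2
    right_half = x >= mid
    # constant gradient dP/dx = flow_gradient inside [0, h]: relative to the
    # right bulk its contribution at x is -flow_gradient * (membrane length
    # between x and the right chamber); relative to the left bulk it is
    # +flow_gradient * (membrane length between the left chamber and x)
    P = np.empty_like(c)
    P[right_half] = (
        right.P - R * T * (right.c_s - c[right_half])
        - flow_gradient * (h - np.clip(x[right_half], 0.0, h))
    )
    # left half anchored at the left chamber; the construction is continuous
    # at the midpoint because phi_V satisfies the combined flux law
    P[~right_half] = (
        left.P - R * T * (left.c_s - c[~right_half])
        + flow_gradient * np.clip(x[~right_half], 0.0, h)
    )
    return ContinuumProfile(
        grid=grid, c=c, P=P, phi_V=phi_V, potential=potential, T=T,
        c_bulk_left=left.c_s, c_bulk_right=right.c_s, flow_gradient=flow_gradient,
    )


def vegard_drop(profile: ContinuumProfile) -> float:
    """Pressure drop from the right (solution) bulk to just inside the membrane.

    Measured at the barrier maximum (membrane midpoint), where solute
    exclusion is complete; for a flowing steady state the viscous ramp
    accumulated between the membrane face and the measurement point is
    subtracted, leaving the purely interfacial (osmotic) drop, which equals
    R T c_s,r in the impermeable regime.
    """
    if profile.potential is None or profile.T is None:
        raise ValueError("profile does not carry its membrane potential; cannot locate the interface")
    x = profile.grid.x
    mid = profile.potential.span / 2
    i_star = int(np.argmin(np.abs(x - mid)))
    if not (-profile.potential.interface_width < x[i_star] - mid < profile.potential.interface_width):
        raise ValueError("grid does not resolve the membrane interior")
    raw = profile.P[-1] - profile.P[i_star]
    ramp_correction = profile._viscous_ramp(np.array([x[i_star]]))[0]
    return float(raw + ramp_correction)


def numeric_ode_solution(
    potential: MembranePotential,
    c_bulk_right: float,
    T: float,
    grid: SpatialGrid | None = None,
    P_right: float = 0.0,
    c_bulk_left: float = 0.0,
    rtol: float = 1e-12,
) -> ContinuumProfile:
    """Direct numerical integration of the zero-flux + mechanical-balance ODEs.

    Integrates dc/dx = c F/(RT) and dP/dx = c F with the analytic force
    F(x) = -dU/dx, from each bulk inward to the barrier midpoint, as an
    independent cross-check of the closed-form Boltzmann construction in
    :func:`equilibrium_profile`.
    """
    if T <= 0:
        raise ValueError(f"temperature must be > 0, got {T}")
    if grid is None:
        grid = SpatialGrid.for_membrane(potential)
    grid.check_resolves(potential.interface_width)

    x = grid.x
    mid = potential.span / 2
    scale_c = max(c_bulk_right, c_bulk_left, 1.0)
    atol = [scale_c * 1e-16, R * T * scale_c * 1e-16]

    def rhs(xi: float, y: np.ndarray) -> list[float]:
        F = float(potential.force(np.array([xi]))[0])
        return [y[0] * F / (R * T), y[0] * F]

    c_out = np.empty_like(x)
    P_out = np.empty_like(x)
    right_half = x >= mid

    # right (solution) side: integrate from the right bulk inward (decreasing x)
    xr = x[right_half]
    sol_r = solve_ivp(
        rhs, (xr[-1], mid), [c_bulk_right, P_right], t_eval=xr[::-1],
        rtol=rtol, atol=atol, method="LSODA",
        max_step=potential.interface_width / 4,
    )
    if not sol_r.success:
        raise RuntimeError(f"ODE integration failed on the solution side near x={sol_r.t[-1]:.3e}: {sol_r.message}")
    c_out[right_half] = sol_r.y[0][::-1]
    P_out[right_half] = sol_r.y[1][::-1]

    # pressure continuity at the midpoint anchors the left-side integration
    c_mid_r, P_mid = sol_r.y[0][-1], sol_r.y[1][-1]
    xl = x[~right_half]
    if xl.size:
        c_mid_l = c_bulk_left * np.exp(-potential.energy(np.array([mid])) / (R * T))[0]
        sol_l = solve_ivp(
            rhs, (mid, xl[0]), [c_mid_l, P_mid], t_eval=xl[::-1],
            rtol=rtol, atol=atol, method="LSODA",
            max_step=potential.interface_width / 4,
        )
        if not sol_l.success:
            raise RuntimeError(f"ODE integration failed on the solvent side near x={sol_l.t[-1]:.3e}: {sol_l.message}")
        c_out[~right_half] = sol_l.y[0][::-1]
        P_out[~right_half] = sol_l.y[1][::-1]
    np.clip(c_out, 0.0, None, out=c_out)
    return ContinuumProfile(
        grid=grid, c=c_out, P=P_out, phi_V=0.0, potential=potential, T=T,
        c_bulk_left=c_bulk_left, c_bulk_right=c_bulk_right, flow_gradient=0.0,
    )
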