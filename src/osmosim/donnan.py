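"""Pump-leak toy model of the Donnan effect on cell volume.

A spherical "cell" with a pliant, water-permeable membrane exchanges an
uncharged permeant solute A with an infinite bath (first-order rate k) and
carries b moles of an impermeant solute B.  With the membrane pliant, the
hydrostatic pressure difference stays near zero and water flux follows the
osmolarity imbalance, giving

    dA_in/dt = k ([A]_e - A_in) - p
    dw/dt    = lam (A_in + b/w - [A]_e - B_e)

where p is a constant-rate pump extruding A, B_e an extracellular impermeant
concentration, and lam a linear osmotic volume-coupling coefficient.

Without impermeant load (b = 0) the cell is stable at A_in = [A]_e.  With
b > 0 and no countermeasure the kinetic constraint (A_in -> [A]_e) and the
osmotic constraint (A_in + b/w = [A]_e) are incompatible at any finite
volume, so the cell swells without bound — the Donnan catastrophe.  The
volume is stabilized either by external impermeants (w* = b/B_e) or by
pumping (w* = b k/p); with both, w* = b/(B_e + p/k).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "DonnanParams",
    "DonnanState",
    "donnan_rhs",
    "simulate_donnan",
    "classify_regime",
    "fixed_point",
]


@dataclass(frozen=True)
class DonnanParams:
    """Rate and coupling constants of the pump-leak model.

    k : first-order exchange rate of the permeant A [s^-1]
    A_e : external permeant concentration [mol m^-3]
    b : moles of internal impermeant B [mol]
    B_e : external impermeant concentration [mol m^-3]
    p : pump rate removing A from the cell [mol m^-3 s^-1]
    lam : osmotic volume coupling [m^3 s^-1 per mol m^-3]
    """

    k: float
    A_e: float
    b: float = 0.0
    B_e: float = 0.0
    p: float = 0.0
    lam: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k", "A_e", "b", "B_e", "p", "lam"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.p > 0 and self.k > 0 and self.p / self.k >= self.A_e:
            raise ValueError(
                f"pump rate p = {self.p} would drive the internal permeant "
                f"concentration negative (p/k = {self.p / self.k} >= A_e = {self.A_e})"
            )


@dataclass(frozen=True)
class DonnanState:
    """Instantaneous cell state: volume w [m^3], internal permeant
    concentration A_in [mol m^-3], and time t [s]."""

    w: float
    A_in: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ValueError(f"cell volume must be > 0, got {self.w}")
        if self.A_in < 0:
            raise ValueError(f"A_in must be >= 0, got {self.A_in}")


def donnan_rhs(state: DonnanState, params: DonnanParams) -> tuple[float, float]:
    """Time derivatives (dA_in/dt, dw/dt) of the pump-leak model."""
    if state.w <= 0:
        raise ValueError("cell volume must be > 0")
    dA = params.k * (params.A_e - state.A_in) - params.p
    osm_in = state.A_in + params.b / state.w
    osm_out = params.A_e + params.B_e
    dw = params.lam * (osm_in - osm_out)
    return dA, dw


def simulate_donnan(
    initial: DonnanState,
    params: DonnanParams,
    t_end: float,
    n_out: int = 200,
    rtol: float = 1e-9,
) -> pd.DataFrame:
    """Integrate the pump-leak ODEs and return a sampled time series.

    Returns a DataFrame with columns ``t, w, A_in, osm_in, osm_out``
    (n_out rows, including the initial state).  The permeant concentration
    relaxes exponentially at rate k toward A_e - p/k regardless of the
    volume dynamics.
    """
    if t_end <= 0:
        raise ValueError(f"t_end must be > 0, got {t_end}")

    w_floor = initial.w * 1e-9

    def rhs(t: float, y: np.ndarray) -> list[float]:
        # trial steps may probe w <= 0 before the collapse event terminates
        # the solve; floor w to keep b/w finite there
        A_in = max(y[0], 0.0)
        w = max(y[1], w_floor)
        dA = params.k * (params.A_e - A_in) - params.p
        dw = params.lam * (A_in + params.b / w - params.A_e - params.B_e)
        return [dA, dw]

    def collapse(t: float, y: np.ndarray) -> float:
        return y[1]  # w = 0 is nonphysical; stop before it

    collapse.terminal = True
    collapse.direction = -1

    t_eval = np.linspace(0.0, t_end, n_out)
    sol = solve_ivp(
        rhs, (0.0, t_end), [initial.A_in, initial.w], t_eval=t_eval,
        method="LSODA", rtol=rtol, atol=[params.A_e * 1e-12 + 1e-30, initial.w * 1e-12],
        events=collapse,
    )
    if not sol.success:
        raise RuntimeError(
            f"integration failed at t = {sol.t[-1] if sol.t.size else 0.0:.3e} s "
            f"(w = {sol.y[1][-1] if sol.t.size else initial.w:.3e}): {sol.message}"
        )
    if sol.t_events[0].size:
        raise RuntimeError(
            f"cell volume collapsed to zero at t = {sol.t_events[0][0]:.3e} s; "
            "check parameters (e.g. B_e exceeding the Donnan load)"
        )
    A_in = sol.y[0]
    w = sol.y[1]
    return pd.DataFrame(
        {
            "t": sol.t,
            "w": w,
            "A_in": A_in,
            "osm_in": A_in + params.b / w,
            "osm_out": np.full_like(sol.t, params.A_e + params.B_e),
        }
    )


def fixed_point(params: DonnanParams) -> tuple[float, float] | None:
    """Steady state (w*, A_in*) of the model, or None if none exists.

    A_in* = A_e - p/k; the osmotic balance then requires
    b/w* = B_e + p/k, so w* = b/(B_e + p/k) when the right side is
    positive.  With b > 0 but no stabilizer the volume has no fixed point.
    """
    if params.k <= 0:
        return None
    A_star = params.A_e - params.p / params.k
    if params.b == 0:
        return None if params.B_e > 0 or params.p > 0 else (np.nan, A_star)
    denom = params.B_e + params.p / params.k
    if denom <= 0:
        return None
    return params.b / denom, A_star


def classify_regime(params: DonnanParams) -> str:
    """Classify the long-time behaviour of the cell volume.

    Returns one of ``stable`` (no impermeant load), ``unbounded-swelling``
    (load with no countermeasure), ``externally-stabilized`` (extracellular
    impermeant, w* = b/B_e) or ``pump-stabilized`` (active extrusion,
    w* = b k/p; with both countermeasures the combined fixed point is
    w* = b/(B_e + p/k) and pumping takes naming precedence).
    """
    if params.b == 0:
        return "stable"
    if params.p > 0:
        return "pump-stabilized"
    if params.B_e > 0:
        return "externally-stabilized"
    return "unbounded-swelling"
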