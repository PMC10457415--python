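"""Scenario configuration: strict schemas, explicit units, fixture generator.

Configs are YAML with one scenario per file.  Every physical quantity is a
``{value, unit}`` pair; units are converted to SI at load time and the
resolved SI parameters are logged, so no downstream code ever sees a
non-SI number.  Unknown keys are rejected.
"""

from __future__ import annotations

import json
import logging
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Any, Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import continuum, donnan, mixtures, particles, transport
from .core import ATM, DEFAULT_TEMPERATURE, R, SolutionState

log = logging.getLogger("osmosim")

__all__ = ["ScenarioConfig", "load_config", "run_scenario", "generate_fixtures"]

try:
    _VERSION = version("osmosim")
except PackageNotFoundError:  # pragma: no cover
    _VERSION = "unknown"

# unit -> factor to SI, per dimension
_UNITS: dict[str, dict[str, float]] = {
    "concentration": {"mol/m^3": 1.0, "M": 1000.0, "mM": 1.0},
    "pressure": {"Pa": 1.0, "kPa": 1e3, "MPa": 1e6, "atm": ATM},
    "temperature": {"K": 1.0},
    "length": {"m": 1.0, "um": 1e-6, "nm": 1e-9},
    "time": {"s": 1.0},
    "hydraulic_permeability": {"m/s/Pa": 1.0},
    "permeability": {"m/s": 1.0},
    "diffusivity": {"m^2/s": 1.0},
    "molar_volume": {"m^3/mol": 1.0, "L/mol": 1e-3},
    "energy": {"J/mol": 1.0},  # "RT" handled specially (needs T)
    "rate": {"1/s": 1.0},
    "moles": {"mol": 1.0},
    "pump_rate": {"mol/m^3/s": 1.0},
    "volume_coupling": {"m^3/s per mol/m^3": 1.0},
    "volume": {"m^3": 1.0, "um^3": 1e-18, "L": 1e-3},
    "area": {"m^2": 1.0},
    "dimensionless": {"": 1.0, "-": 1.0},
}


class Quantity(BaseModel):
    """A number with an explicit unit tag."""

    model_config = ConfigDict(extra="forbid")
    value: float
    unit: str

    def si(self, dimension: str, *, T: float | None = None) -> float:
        """Convert to SI for the given dimension; 'RT' energies need T."""
        if dimension == "energy" and self.unit == "RT":
            if T is None:
                raise ValueError("energy given in RT units but no temperature available")
            return self.value * R * T
        table = _UNITS[dimension]
        if self.unit not in table:
            raise ValueError(
                f"unknown unit {self.unit!r} for {dimension}; choose from {sorted(table)}"
            )
        return self.value * table[self.unit]


def _q(value: float, unit: str) -> dict[str, float | str]:
    return {"value": value, "unit": unit}


class ChamberConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    osmolarity: Quantity
    pressure: Quantity = Quantity(value=0.0, unit="Pa")

    def state(self, T: float) -> SolutionState:
        return SolutionState(
            c_s=self.osmolarity.si("concentration"),
            P=self.pressure.si("pressure"),
            T=T,
        )


class PotentialConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    shape: Literal["smooth-plateau", "gaussian-barrier"] = "smooth-plateau"
    U_max: Quantity
    span: Quantity
    interface_width: Quantity | None = None

    def build(self, T: float) -> continuum.MembranePotential:
        span = self.span.si("length")
        width = self.interface_width.si("length") if self.interface_width else span / 20
        return continuum.MembranePotential(
            shape=self.shape,
            U_max=self.U_max.si("energy", T=T),
            span=span,
            interface_width=width,
        )


class GridConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_points: int = 2001
    chamber_width: Quantity | None = None


class FluxParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    Lp: Quantity
    left: ChamberConfig
    right: ChamberConfig
    temperature: Quantity = Quantity(value=DEFAULT_TEMPERATURE, unit="K")
    Pd: Quantity | None = None


class ProfileParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mode: Literal["equilibrium", "steady-state"]
    potential: PotentialConfig
    right: ChamberConfig
    left: ChamberConfig | None = None
    Lp: Quantity | None = None
    temperature: Quantity = Quantity(value=DEFAULT_TEMPERATURE, unit="K")
    grid: GridConfig = GridConfig()

    @model_validator(mode="after")
    def _steady_state_needs(self) -> "ProfileParams":
        if self.mode == "steady-state" and (self.Lp is None or self.left is None):
            raise ValueError("steady-state mode requires both 'Lp' and 'left'")
        return self


class ParticlesParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    N: int
    box_min: Quantity
    box_max: Quantity
    potential: PotentialConfig
    D_s: Quantity
    temperature: Quantity = Quantity(value=DEFAULT_TEMPERATURE, unit="K")
    dt: Quantity
    n_steps: int
    n_equilibration: int
    cross_section_area: Quantity = Quantity(value=1.0, unit="m^2")
    mole_per_particle: float = 1.0
    n_bins: int = 100
    sample_every: int = 10


class DonnanScenarioParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k: Quantity
    A_e: Quantity
    b: Quantity = Quantity(value=0.0, unit="mol")
    B_e: Quantity = Quantity(value=0.0, unit="mol/m^3")
    p: Quantity = Quantity(value=0.0, unit="mol/m^3/s")
    lam: Quantity = Quantity(value=1.0, unit="m^3/s per mol/m^3")
    w0: Quantity
    A0: Quantity
    t_end: Quantity
    n_out: int = 200


class MixtureParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    X_s: float = Field(ge=0, lt=1)
    v_w: Quantity = Quantity(value=1.802e-5, unit="m^3/mol")
    v_s: Quantity = Quantity(value=1.802e-5, unit="m^3/mol")


class OutputConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    json_path: str | None = None
    csv_path: str | None = None


_PARAM_MODELS: dict[str, type[BaseModel]] = {
    "flux": FluxParams,
    "profile": ProfileParams,
    "particles": ParticlesParams,
    "donnan": DonnanScenarioParams,
    "mixture": MixtureParams,
}


class ScenarioConfig(BaseModel):
    """One runnable scenario: name, typed parameter block, seed, outputs."""

    model_config = ConfigDict(extra="forbid")
    scenario: Literal["flux", "profile", "particles", "donnan", "mixture"]
    parameters: dict[str, Any]
    seed: int | None = None
    output: OutputConfig = OutputConfig()

    @model_validator(mode="after")
    def _validate_parameters(self) -> "ScenarioConfig":
        model = _PARAM_MODELS[self.scenario]
        object.__setattr__(self, "parameters", model.model_validate(self.parameters).model_dump())
        return self

    def typed_parameters(self) -> BaseModel:
        return _PARAM_MODELS[self.scenario].model_validate(self.parameters)


def load_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a YAML scenario config; errors name offending keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} is not a mapping")
    cfg = ScenarioConfig.model_validate(raw)
    log.info("loaded %s scenario from %s (package %s)", cfg.scenario, path, _VERSION)
    return cfg


# ---------------------------------------------------------------- runners


def _run_flux(p: FluxParams, seed: int | None) -> tuple[dict, pd.DataFrame | None]:
    T = p.temperature.si("temperature")
    left, right = p.left.state(T), p.right.state(T)
    Lp = p.Lp.si("hydraulic_permeability")
    delta_P = right.P - left.P
    delta_c = right.c_s - left.c_s
    res = transport.fundamental_flux(Lp, delta_P, delta_c, T)
    Pf = transport.pf_from_lp(Lp, T)
    summary = {
        "phi_V": res.phi_V,
        "phi_w": res.phi_w,
        "Pf": Pf,
        "equilibrium_delta_P": transport.van_t_hoff_delta_p(delta_c, T),
    }
    if p.Pd is not None:
        Pd = p.Pd.si("permeability")
        summary["Pd"] = Pd
        summary["Pc_over_Pd"] = transport.convective_fraction(Pf, Pd)
    return summary, None


def _run_profile(p: ProfileParams, seed: int | None) -> tuple[dict, pd.DataFrame]:
    T = p.temperature.si("temperature")
    pot = p.potential.build(T)
    chamber = p.grid.chamber_width.si("length") if p.grid.chamber_width else None
    grid = continuum.SpatialGrid.for_membrane(pot, n_points=p.grid.n_points, chamber_width=chamber)
    right = p.right.state(T)
    if p.mode == "equilibrium":
        prof = continuum.equilibrium_profile(pot, right.c_s, right.P, T, grid)
    else:
        left = p.left.state(T)
        prof = continuum.steady_state_profile(pot, p.Lp.si("hydraulic_permeability"), left, right, grid, T)
    summary = {
        "delta_P_chambers": prof.delta_p_chambers(),
        "vegard_drop": continuum.vegard_drop(prof),
        "phi_V": prof.phi_V,
    }
    table = pd.DataFrame({"x_m": prof.grid.x, "c_mol_per_m3": prof.c, "P_Pa": prof.P})
    return summary, table


def _run_particles(p: ParticlesParams, seed: int | None) -> tuple[dict, pd.DataFrame]:
    T = p.temperature.si("temperature")
    cfg = particles.ParticleSimConfig(
        N=p.N,
        box=(p.box_min.si("length"), p.box_max.si("length")),
        potential=p.potential.build(T),
        D_s=p.D_s.si("diffusivity"),
        T=T,
        dt=p.dt.si("time"),
        n_steps=p.n_steps,
        n_equilibration=p.n_equilibration,
        seed=seed if seed is not None else 0,
        cross_section_area=p.cross_section_area.si("area"),
        mole_per_particle=p.mole_per_particle,
        n_bins=p.n_bins,
        sample_every=p.sample_every,
    )
    log.info("particles: seed=%d dt=%.3e s (stability max %.3e s)", cfg.seed, cfg.dt, cfg.max_stable_dt())
    res = particles.run_brownian(cfg)
    c_b = cfg.bulk_concentration()
    rtc = R * T * c_b * (1.0 - float(np.exp(-cfg.potential.U_max / (R * T))))
    summary = {
        "force_per_area": res.mean_force_per_area,
        "stderr": res.stderr,
        "RTc_reference": rtc,
        "z_score": res.z_score_vs_vant_hoff,
        "seed": cfg.seed,
    }
    table = pd.DataFrame({"x_m": res.bin_centers, "c_mol_per_m3": res.concentration_histogram})
    return summary, table


def _run_donnan(p: DonnanScenarioParams, seed: int | None) -> tuple[dict, pd.DataFrame]:
    params = donnan.DonnanParams(
        k=p.k.si("rate"),
        A_e=p.A_e.si("concentration"),
        b=p.b.si("moles"),
        B_e=p.B_e.si("concentration"),
        p=p.p.si("pump_rate"),
        lam=p.lam.si("volume_coupling"),
    )
    initial = donnan.DonnanState(w=p.w0.si("volume"), A_in=p.A0.si("concentration"))
    series = donnan.simulate_donnan(initial, params, p.t_end.si("time"), p.n_out)
    regime = donnan.classify_regime(params)
    fp = donnan.fixed_point(params)
    summary = {
        "regime": regime,
        "w_final": float(series["w"].iloc[-1]),
        "A_in_final": float(series["A_in"].iloc[-1]),
        "w_star": None if fp is None or not np.isfinite(fp[0]) else fp[0],
    }
    return summary, series


def _run_mixture(p: MixtureParams, seed: int | None) -> tuple[dict, pd.DataFrame | None]:
    spec = mixtures.MixtureSpec(
        X_s=p.X_s, v_w=p.v_w.si("molar_volume"), v_s=p.v_s.si("molar_volume")
    )
    total = mixtures.concentration_sum(spec)
    c_s = spec.X_s * total
    c_w = (1.0 - spec.X_s) * total
    delta = mixtures.water_concentration_difference(c_s, spec.v_s, spec.v_w) if c_s * spec.v_s < mixtures.DILUTE_LIMIT else None
    summary = {
        "c_w_plus_c_s": total,
        "c_w": c_w,
        "c_s": c_s,
        "delta_c_w_vs_pure": delta,
    }
    return summary, None


_RUNNERS = {
    "flux": _run_flux,
    "profile": _run_profile,
    "particles": _run_particles,
    "donnan": _run_donnan,
    "mixture": _run_mixture,
}


def run_scenario(
    cfg: ScenarioConfig,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run a validated scenario and write its JSON/CSV outputs.

    ``seed`` overrides the config's seed.  Returns the scalar summary dict.
    """
    params = cfg.typed_parameters()
    eff_seed = seed if seed is not None else cfg.seed
    log.info("running %s (seed=%s, SI parameters: %s)", cfg.scenario, eff_seed,
             params.model_dump())
    summary, table = _RUNNERS[cfg.scenario](params, eff_seed)
    summary = {"scenario": cfg.scenario, "package_version": _VERSION, **summary}
    base = Path(out_dir) if out_dir is not None else None
    json_path = cfg.output.json_path
    csv_path = cfg.output.csv_path
    if base is not None:
        base.mkdir(parents=True, exist_ok=True)
        json_path = json_path or f"{cfg.scenario}_summary.json"
        if table is not None:
            csv_path = csv_path or f"{cfg.scenario}_table.csv"
    if json_path is not None:
        path = (base / json_path) if base else Path(json_path)
        path.write_text(json.dumps(summary, indent=2, default=float) + "\n")
        log.info("wrote %s", path)
    if csv_path is not None and table is not None:
        path = (base / csv_path) if base else Path(csv_path)
        table.to_csv(path, index=False)
        log.info("wrote %s", path)
    return summary


# ---------------------------------------------------------- fixtures

def _fixture_configs() -> dict[str, dict]:
    """Canonical configs, one per scenario family; each runs in seconds."""
    conc = lambda v: _q(v, "mol/m^3")
    pa = lambda v: _q(v, "Pa")
    plateau = {
        "shape": "smooth-plateau",
        "U_max": _q(30.0, "RT"),
        "span": _q(1e-8, "m"),
        "interface_width": _q(5e-10, "m"),
    }
    return {
        "vant_hoff_flux": {
            "scenario": "flux",
            "parameters": {
                "Lp": _q(1e-12, "m/s/Pa"),
                "temperature": _q(300.0, "K"),
                "left": {"osmolarity": conc(0.0), "pressure": pa(0.0)},
                "right": {"osmolarity": conc(100.0), "pressure": pa(0.0)},
                "Pd": _q(1e-4, "m/s"),
            },
        },
        "equilibrium_profile": {
            "scenario": "profile",
            "parameters": {
                "mode": "equilibrium",
                "potential": plateau,
                "right": {"osmolarity": conc(100.0), "pressure": pa(0.0)},
                "temperature": _q(300.0, "K"),
            },
        },
        "vegard_steady_state": {
            "scenario": "profile",
            "parameters": {
                "mode": "steady-state",
                "potential": plateau,
                "left": {"osmolarity": conc(0.0), "pressure": pa(0.0)},
                "right": {"osmolarity": conc(100.0), "pressure": pa(0.0)},
                "Lp": _q(1e-12, "m/s/Pa"),
                "temperature": _q(300.0, "K"),
            },
        },
        "particles_vant_hoff": {
            "scenario": "particles",
            # reduced units: RT = 1 (T = 1/R), lengths O(1)
            "parameters": {
                "N": 2000,
                "box_min": _q(-4.0, "m"),
                "box_max": _q(5.0, "m"),
                "potential": {
                    "shape": "smooth-plateau",
                    "U_max": _q(30.0, "RT"),
                    "span": _q(1.0, "m"),
                    "interface_width": _q(0.05, "m"),
                },
                "D_s": _q(1.0, "m^2/s"),
                "temperature": _q(1.0 / R, "K"),
                "dt": _q(2e-5, "s"),
                "n_steps": 20000,
                "n_equilibration": 5000,
            },
            "seed": 12345,
        },
        "donnan_stable": {
            "scenario": "donnan",
            "parameters": {
                "k": _q(1.0, "1/s"),
                "A_e": conc(100.0),
                "w0": _q(1e-15, "m^3"),
                "A0": conc(50.0),
                "t_end": _q(20.0, "s"),
                "lam": _q(1e-18, "m^3/s per mol/m^3"),
            },
        },
        "donnan_unbounded": {
            "scenario": "donnan",
            "parameters": {
                "k": _q(1.0, "1/s"),
                "A_e": conc(100.0),
                "b": _q(1e-13, "mol"),
                "w0": _q(1e-15, "m^3"),
                "A0": conc(100.0),
                "t_end": _q(600.0, "s"),
                "lam": _q(1e-18, "m^3/s per mol/m^3"),
            },
        },
        "donnan_pump": {
            "scenario": "donnan",
            "parameters": {
                "k": _q(1.0, "1/s"),
                "A_e": conc(100.0),
                "b": _q(1e-13, "mol"),
                "p": _q(10.0, "mol/m^3/s"),
                "w0": _q(1e-15, "m^3"),
                "A0": conc(100.0),
                "t_end": _q(50.0, "s"),
                "lam": _q(1e-15, "m^3/s per mol/m^3"),
            },
        },
        "mixture_55M": {
            "scenario": "mixture",
            "parameters": {"X_s": 0.018},
        },
        "bilayer_flux": {
            "scenario": "flux",
            # solubility-diffusion regime expressed through Lp equivalent to
            # Pf = KD/h with K=2e-3, D=1e-9 m^2/s, h=4e-9 m at 300 K
            "parameters": {
                "Lp": _q(5e-4 * 1.802e-5 / (R * 300.0), "m/s/Pa"),
                "temperature": _q(300.0, "K"),
                "left": {"osmolarity": conc(0.0)},
                "right": {"osmolarity": conc(100.0)},
                "Pd": _q(5e-4, "m/s"),
            },
        },
    }


def generate_fixtures(output_dir: str | Path) -> list[Path]:
    """Write the canonical scenario configs as YAML files; returns the paths."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, payload in _fixture_configs().items():
        ScenarioConfig.model_validate(payload)  # every fixture must be loadable
        path = out / f"{name}.yaml"
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
        paths.append(path)
    log.info("wrote %d fixture configs to %s", len(paths), out)
    return paths
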