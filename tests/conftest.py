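import numpy as np
import pytest
from hypothesis import settings

from osmosim import MembranePotential, ParticleSimConfig, R

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

#: temperature at which R*T = 1 (reduced-unit runs)
REDUCED_T = 1.0 / R


@pytest.fixture
def reduced_plateau() -> MembranePotential:
    """Impermeable plateau barrier in reduced units (RT = 1, h = 1)."""
    return MembranePotential("smooth-plateau", 30.0, 1.0, 0.05)


def small_particle_config(
    potential: MembranePotential,
    seed: int = 1,
    N: int = 800,
    n_steps: int = 10000,
    n_equilibration: int = 1000,
    dt: float = 2e-5,
    **kwargs,
) -> ParticleSimConfig:
    """Quick reduced-unit simulation box around a unit-thickness membrane."""
    return ParticleSimConfig(
        N=N,
        box=(-4.0, 5.0),
        potential=potential,
        D_s=1.0,
        T=REDUCED_T,
        dt=dt,
        n_steps=n_steps,
        n_equilibration=n_equilibration,
        seed=seed,
        **kwargs,
    )


def boltzmann_pressure(potential: MembranePotential, T: float, c_bulk: float) -> float:
    """Closed-form osmotic pressure R T c_b (1 - e^{-U_max/RT}) of a barrier."""
    return R * T * c_bulk * (1.0 - float(np.exp(-potential.U_max / (R * T))))
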