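"""Brownian-dynamics verification that membrane-solute repulsion alone
produces the van 't Hoff pressure.

Ideal (non-interacting) solute particles diffuse in a closed 1-D box with a
repulsive potential barrier in the middle representing the membrane.  The
solvent is implicit: it enters only through the mobility mu = D_s/RT
(Einstein relation) and the thermal noise.  Positions advance by
Euler-Maruyama,

    x += mu F(x) dt + sqrt(2 D_s dt) xi,    xi ~ N(0, 1),

with reflecting outer walls (two closed chambers).  After equilibration the
sampled concentration histogram follows the Boltzmann profile
c(x) ∝ exp(-U(x)/RT), and the time-averaged force the membrane exerts on
the particles of the solution-side chamber, divided by the nominal
cross-section area, equals the osmotic pressure R T c_bulk (1 - e^{-U_max/RT})
— the microscopic content of van 't Hoff's law.

Units: quantities are molar-SI (J/mol energies, mol/m^3 concentrations)
with the gas constant fixed; a reduced-unit run (RT = 1) is obtained by
setting T = 1/R and order-one lengths, which conditions the arithmetic well
and keeps tests fast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import R
from .continuum import ContinuumProfile, MembranePotential

__all__ = ["ParticleSimConfig", "SimResult", "ProfileDeviation", "run_brownian", "measure_concentration_profile"]


@dataclass(frozen=True)
class ParticleSimConfig:
    """Configuration of a Brownian (overdamped Langevin) solute simulation.

    Attributes
    ----------
    N : int
        Particle count.
    box : tuple[float, float]
        Closed 1-D domain [x_min, x_max] [m]; must contain the barrier.
    potential : MembranePotential
        The membrane barrier (its span [0, h] must lie inside the box).
    D_s : float
        Solute diffusion constant [m^2 s^-1].
    T : float
        Temperature [K]; the mobility is mu = D_s/(R T).
    dt : float
        Time step [s]; must satisfy mu |F|_max dt <= interface_width / 10.
    n_steps, n_equilibration : int
        Production and discarded equilibration steps.
    seed : int
        RNG seed; runs are bit-reproducible.
    cross_section_area : float
        Nominal membrane area [m^2] used to report force per area.
    mole_per_particle : float
        Moles represented by one simulated particle; sets the concentration
        scale (1/N_A for literal molecules, 1.0 for reduced units).
    n_bins : int
        Histogram bins across the box.
    sample_every : int
        Histogram sampling stride (forces are accumulated every step).
    """

    N: int
    box: tuple[float, float]
    potential: MembranePotential
    D_s: float
    T: float
    dt: float
    n_steps: int
    n_equilibration: int
    seed: int
    cross_section_area: float = 1.0
    mole_per_particle: float = 1.0
    n_bins: int = 100
    sample_every: int = 10
    n_blocks: int = 20

    def __post_init__(self) -> None:
        x_min, x_max = self.box
        if not x_min < 0 < self.potential.span < x_max:
            raise ValueError(
                f"box {self.box} must strictly contain the membrane interval "
                f"[0, {self.potential.span}]"
            )
        for name in ("N", "n_steps", "n_equilibration", "n_bins", "sample_every", "n_blocks"):
            if getattr(self, name) < (1 if name != "n_equilibration" else 0):
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.D_s <= 0 or self.T <= 0 or self.dt <= 0:
            raise ValueError("D_s, T and dt must all be > 0")
        if self.cross_section_area <= 0 or self.mole_per_particle <= 0:
            raise ValueError("cross_section_area and mole_per_particle must be > 0")
        if self.n_steps < self.n_blocks:
            raise ValueError("n_steps must be at least n_blocks")

    @property
    def mobility(self) -> float:
        """Einstein mobility mu = D_s / (R T) [m s^-1 per J mol^-1 m^-1]."""
        return self.D_s / (R * self.T)

    def max_stable_dt(self) -> float:
        """Largest dt satisfying the drift-stability bound mu |F| dt <= w/10."""
        f_max = self.potential.max_force()
        if f_max == 0.0:
            return np.inf
        return self.potential.interface_width / 10 / (self.mobility * f_max)

    def check_stability(self) -> None:
        dt_max = self.max_stable_dt()
        if self.dt > dt_max:
            raise ValueError(
                f"dt = {self.dt:.3e} s violates the drift-stability bound "
                f"mu*|F|*dt <= interface_width/10; use dt <= {dt_max:.3e} s"
            )

    def bulk_concentration(self) -> float:
        """Equilibrium bulk concentration [mol m^-3] implied by N and the box.

        N * mole_per_particle moles distribute over the accessible volume
        A * integral of exp(-U/RT) dx, so the chamber (bulk) concentration is
        N*mole_per_particle / (A * Z) with Z the configurational integral.
        """
        x_min, x_max = self.box
        xs = np.linspace(x_min, x_max, 200001)
        z = np.trapezoid(np.exp(-self.potential.energy(xs) / (R * self.T)), xs)
        return self.N * self.mole_per_particle / (self.cross_section_area * z)


@dataclass(frozen=True)
class SimResult:
    """Output of :func:`run_brownian`.

    ``mean_force_per_area`` is the time-averaged total membrane force on the
    particles of the right (solution-side) chamber, per unit area, with the
    sign such that a repulsive barrier confining the right chamber gives a
    positive value — directly comparable to R T c_bulk.
    """

    config: ParticleSimConfig
    bin_edges: np.ndarray
    concentration_histogram: np.ndarray  # time-averaged c(x) per bin [mol m^-3]
    mean_force_per_area: float           # [Pa]
    stderr: float                        # across-particle standard error [Pa]
    block_means: np.ndarray              # per-block force/area means [Pa]
    n_samples: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[1:] + self.bin_edges[:-1])

    @property
    def z_score_vs_vant_hoff(self) -> float:
        """(measured pressure - R T c_bulk (1-e^{-U_max/RT})) / stderr."""
        cfg = self.config
        expected = (
            R * cfg.T * cfg.bulk_concentration()
            * (1.0 - np.exp(-cfg.potential.U_max / (R * cfg.T)))
        )
        return (self.mean_force_per_area - expected) / self.stderr if self.stderr > 0 else np.nan


def run_brownian(config: ParticleSimConfig) -> SimResult:
    """Run the overdamped Langevin simulation described by ``config``.

    Returns the time-averaged concentration histogram and the membrane
    force-per-area on the right chamber with an across-particle standard
    error.  Deterministic for a fixed config and seed.
    """
    config.check_stability()
    rng = np.random.default_rng(config.seed)
    x_min, x_max = config.box
    mu = config.mobility
    mid = config.potential.span / 2

    # warm start: rejection-sample positions from the stationary Boltzmann
    # density exp(-U/RT).  A uniform start leaves an excess of expelled
    # particles near the membrane face that only decays on the slow chamber
    # mixing time L^2/2D; sampling the stationary law removes that transient
    # so the (short) equilibration only has to relax discretization effects.
    x = np.empty(0)
    while x.size < config.N:
        cand = rng.uniform(x_min, x_max, size=2 * config.N)
        keep = rng.random(cand.size) < np.exp(-config.potential.energy(cand) / (R * config.T))
        x = np.concatenate([x, cand[keep]])
    x = x[: config.N]
    sig = np.sqrt(2.0 * config.D_s * config.dt)

    def step(x: np.ndarray) -> np.ndarray:
        F = config.potential.force(x)
        x = x + mu * F * config.dt + sig * rng.standard_normal(config.N)
        # reflecting outer walls; a single fold suffices under the dt bound
        x = np.where(x < x_min, 2 * x_min - x, x)
        x = np.where(x > x_max, 2 * x_max - x, x)
        return np.clip(x, x_min, x_max)

    for _ in range(config.n_equilibration):
        x = step(x)

    edges = np.linspace(x_min, x_max, config.n_bins + 1)
    hist_accum = np.zeros(config.n_bins)
    n_hist = 0
    force_sums = np.empty(config.n_steps)   # per-step totals, for block means
    per_particle = np.zeros(config.N)       # per-particle running force sums
    for i in range(config.n_steps):
        x = step(x)
        # force the membrane exerts on each solution-side (right-chamber)
        # particle; the barrier pushes them in +x, away from the membrane
        F = config.potential.force(x)
        contrib = np.where(x >= mid, F, 0.0)
        per_particle += contrib
        force_sums[i] = contrib.sum()
        if i % config.sample_every == 0:
            hist_accum += np.histogram(x, bins=edges)[0]
            n_hist += 1
    if config.N != x.size:  # pragma: no cover - conservation guard
        raise RuntimeError("particle count changed during the run")

    # By Newton's third law the solution pushes on the membrane with the
    # opposite of the summed F; the solution-side pressure excess reported
    # here is +sum(F)/A, directly comparable to R T c_bulk.
    scale = config.mole_per_particle / config.cross_section_area
    mean = float(force_sums.mean() * scale)
    # Ideal solute particles are statistically independent, so the exact
    # error estimate is across particles: the per-particle time-averaged
    # forces are i.i.d. (warm start from the stationary law), and their
    # spread covers both the slow single-particle autocorrelation and the
    # binomial left/right chamber split, which time-block averaging at
    # feasible run lengths underestimates.
    per_particle /= config.n_steps
    stderr = float(np.sqrt(config.N) * per_particle.std(ddof=1) * scale)
    blocks = np.array_split(force_sums * scale, config.n_blocks)
    block_means = np.array([b.mean() for b in blocks])

    bin_width = edges[1] - edges[0]
    conc = hist_accum / n_hist * config.mole_per_particle / (
        config.cross_section_area * bin_width
    )
    return SimResult(
        config=config,
        bin_edges=edges,
        concentration_histogram=conc,
        mean_force_per_area=mean,
        stderr=stderr,
        block_means=block_means,
        n_samples=config.n_steps,
    )


@dataclass(frozen=True)
class ProfileDeviation:
    """Sup-norm histogram-vs-Boltzmann deviation with its predicted noise.

    All quantities are normalized by the bulk concentration.  ``sigma`` is
    the total predicted standard error of a single bin (the quadrature sum
    of the snapshot occupancy noise ``sigma_bin`` and the frozen chamber
    split ``sigma_split``).
    """

    deviation: float
    sigma: float
    sigma_bin: float
    sigma_split: float

    def __iter__(self):
        return iter((self.deviation, self.sigma))


def measure_concentration_profile(
    result: SimResult, reference: ContinuumProfile
) -> ProfileDeviation:
    """Sup-norm deviation between the sampled histogram and a continuum profile.

    Compares the time-averaged concentration histogram against the
    bin-averaged closed-form Boltzmann profile (rescaled to the simulation's
    particle content) and predicts the per-bin sampling noise from binomial
    occupancy statistics, snapshot correlation, and the frozen left/right
    chamber split.
    """
    cfg = result.config
    if reference.potential is None or reference.potential != cfg.potential:
        raise ValueError("reference profile geometry does not match the simulation")
    edges = result.bin_edges
    if not (reference.grid.x[0] <= edges[0] and edges[-1] <= reference.grid.x[-1]):
        raise ValueError("reference grid does not cover the simulation box")
    bin_width = edges[1] - edges[0]
    # bin-averaged Boltzmann weights (the histogram measures bin averages;
    # evaluating the reference at bin centers would misrepresent bins that
    # straddle an interface)
    sub = np.linspace(edges[0], edges[-1], edges.size * 32 - 31)
    boltz_sub = np.exp(-cfg.potential.energy(sub) / (R * cfg.T))
    ref_shape = np.histogram(sub, bins=edges, weights=boltz_sub)[0] / np.histogram(sub, bins=edges)[0]
    total = cfg.N * cfg.mole_per_particle / cfg.cross_section_area
    ref = ref_shape / (ref_shape.sum() * bin_width) * total
    c_bulk = cfg.bulk_concentration()
    deviation = float(np.max(np.abs(result.concentration_histogram - ref)) / c_bulk)

    # binomial occupancy noise per snapshot, inflated by the diffusive
    # decorrelation of successive snapshots (a bin forgets its occupancy on
    # the timescale bin_width^2 / 2D)
    n_hist = max(1, result.n_samples // cfg.sample_every)
    p = ref * bin_width / total
    stride_time = cfg.sample_every * cfg.dt
    tau_bin = bin_width**2 / (2.0 * cfg.D_s)
    inflation = np.sqrt(1.0 + tau_bin / stride_time)
    bin_sigma = np.sqrt(np.max(p * (1 - p)) * cfg.N / n_hist) * inflation
    sigma_bin = bin_sigma * cfg.mole_per_particle / (cfg.cross_section_area * bin_width) / c_bulk
    # the left/right chamber split is frozen at initialization (a high
    # barrier blocks exchange), so its binomial scatter never averages out
    # over the run; it offsets every bin of a chamber coherently
    x_mid = cfg.potential.span / 2
    boltz_total = boltz_sub.sum()
    p_right = boltz_sub[sub >= x_mid].sum() / boltz_total
    p_min = min(p_right, 1.0 - p_right)
    sigma_split = 0.0 if p_min == 0 else np.sqrt((1 - p_min) / (cfg.N * p_min)) * np.max(ref) / c_bulk
    return ProfileDeviation(
        deviation=deviation,
        sigma=float(np.hypot(sigma_bin, sigma_split)),
        sigma_bin=float(sigma_bin),
        sigma_split=float(sigma_split),
    )
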