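"""Brownian-dynamics solute against a barrier membrane (reduced units, RT = 1)."""

import numpy as np
import pytest
from scipy import stats

from osmosim import (
    MembranePotential,
    R,
    SpatialGrid,
    equilibrium_profile,
    measure_concentration_profile,
    run_brownian,
)

from conftest import REDUCED_T, boltzmann_pressure, small_particle_config


class TestConfigValidation:
    def test_barrier_must_be_inside_box(self, reduced_plateau):
        with pytest.raises(ValueError, match="contain the membrane"):
            small_particle_config(reduced_plateau).__class__(
                **{**small_particle_config(reduced_plateau).__dict__, "box": (0.5, 5.0)}
            )

    def test_unstable_dt_refused(self, reduced_plateau):
        cfg = small_particle_config(reduced_plateau, dt=1e-3)
        with pytest.raises(ValueError, match="stability"):
            run_brownian(cfg)
        assert cfg.max_stable_dt() < 1e-3

    def test_einstein_mobility(self, reduced_plateau):
        cfg = small_particle_config(reduced_plateau)
        assert cfg.mobility == pytest.approx(cfg.D_s / (R * cfg.T), rel=1e-12)


class TestFreeDiffusion:
    def test_flat_histogram_and_zero_force(self):
        """No barrier: uniform occupancy and exactly zero membrane force."""
        pot = MembranePotential("smooth-plateau", 0.0, 1.0, 0.05)
        cfg = small_particle_config(pot, N=600, n_steps=4000, n_equilibration=200, dt=1e-4)
        res = run_brownian(cfg)
        assert res.mean_force_per_area == 0.0
        assert res.stderr == 0.0
        c_mean = cfg.N / (cfg.box[1] - cfg.box[0])
        # per-bin relative scatter at ~5 sigma of binomial occupancy noise
        n_hist = cfg.n_steps // cfg.sample_every
        bin_p = 1.0 / cfg.n_bins
        sigma = np.sqrt(cfg.N * bin_p * (1 - bin_p) / n_hist) / ((cfg.box[1] - cfg.box[0]) / cfg.n_bins)
        # correlated snapshots inflate the effective noise; allow a decade
        assert np.max(np.abs(res.concentration_histogram - c_mean)) < 10 * 5 * sigma

    def test_particle_content_conserved(self, reduced_plateau):
        cfg = small_particle_config(reduced_plateau, N=400, n_steps=2000, n_equilibration=100)
        res = run_brownian(cfg)
        bin_width = res.bin_edges[1] - res.bin_edges[0]
        total = res.concentration_histogram.sum() * bin_width * cfg.cross_section_area
        assert total == pytest.approx(cfg.N * cfg.mole_per_particle, rel=1e-12)


class TestDeterminism:
    def test_same_seed_bit_identical(self, reduced_plateau):
        cfg = small_particle_config(reduced_plateau, N=300, n_steps=1500, n_equilibration=100)
        a, b = run_brownian(cfg), run_brownian(cfg)
        assert a.mean_force_per_area == b.mean_force_per_area
        assert a.stderr == b.stderr
        assert np.array_equal(a.concentration_histogram, b.concentration_histogram)
        assert np.array_equal(a.block_means, b.block_means)

    def test_different_seed_differs(self, reduced_plateau):
        cfg1 = small_particle_config(reduced_plateau, seed=1, N=300, n_steps=1500, n_equilibration=100)
        cfg2 = small_particle_config(reduced_plateau, seed=2, N=300, n_steps=1500, n_equilibration=100)
        assert run_brownian(cfg1).mean_force_per_area != run_brownian(cfg2).mean_force_per_area


class TestVanTHoffPressure:
    def test_impermeable_barrier_force_matches_rtc(self, reduced_plateau):
        cfg = small_particle_config(reduced_plateau, seed=11)
        res = run_brownian(cfg)
        expected = boltzmann_pressure(reduced_plateau, cfg.T, cfg.bulk_concentration())
        assert abs(res.mean_force_per_area - expected) <= 3 * res.stderr

    def test_finite_barrier_boltzmann_factor(self):
        """A leaky 2 RT barrier holds only the fraction (1 - e^-2) of the
        van 't Hoff pressure."""
        pot = MembranePotential("smooth-plateau", 2.0, 1.0, 0.05)
        cfg = small_particle_config(pot, seed=5, dt=1e-4, n_steps=6000, n_equilibration=500)
        res = run_brownian(cfg)
        expected = boltzmann_pressure(pot, cfg.T, cfg.bulk_concentration())
        assert expected == pytest.approx(
            R * cfg.T * cfg.bulk_concentration() * (1 - np.exp(-2.0)), rel=1e-12
        )
        assert abs(res.mean_force_per_area - expected) <= 3 * res.stderr

    def test_force_independent_of_barrier_shape(self):
        """At fixed impermeable height, plateau and gaussian barriers press
        equally (stochastic F-cancellation)."""
        results = []
        for shape in ("smooth-plateau", "gaussian-barrier"):
            pot = MembranePotential(shape, 30.0, 1.0, 0.05)
            # gaussian peak force exceeds the plateau's; one dt fits both
            cfg = small_particle_config(pot, seed=7, dt=1e-5, n_steps=16000, n_equilibration=2000)
            results.append(run_brownian(cfg))
        diff = results[0].mean_force_per_area - results[1].mean_force_per_area
        sigma = np.hypot(results[0].stderr, results[1].stderr)
        assert abs(diff) <= 3 * sigma

    def test_z_scores_standard_normal_over_seeds(self, reduced_plateau):
        """The particle-level van 't Hoff statement: across seeds, the force
        z-scores are consistent with a standard normal."""
        zs = []
        for seed in range(1, 11):
            cfg = small_particle_config(
                reduced_plateau, seed=seed, N=500, n_steps=6000, n_equilibration=600
            )
            zs.append(run_brownian(cfg).z_score_vs_vant_hoff)
        zs = np.asarray(zs)
        assert stats.kstest(zs, "norm").pvalue > 0.01
        assert abs(zs.mean()) < 1.5


class TestProfileMeasurement:
    def make_reference(self, pot, cfg):
        grid = SpatialGrid.for_membrane(pot, n_points=4001, chamber_width=4.0)
        return equilibrium_profile(
            pot, cfg.bulk_concentration(), 0.0, cfg.T, grid,
            c_bulk_left=cfg.bulk_concentration(),
        )

    def test_histogram_matches_boltzmann(self):
        pot = MembranePotential("smooth-plateau", 5.0, 1.0, 0.05)
        cfg = small_particle_config(
            pot, seed=3, N=2000, n_steps=20000, n_equilibration=1000,
            dt=5e-5, sample_every=100, n_bins=60,
        )
        res = run_brownian(cfg)
        deviation, sigma = measure_concentration_profile(res, self.make_reference(pot, cfg))
        assert deviation <= 3 * sigma

    def test_predicted_stderr_clt_scaling(self):
        pot = MembranePotential("smooth-plateau", 5.0, 1.0, 0.05)
        sigmas = []
        for n_steps in (4000, 8000):
            cfg = small_particle_config(
                pot, seed=3, N=500, n_steps=n_steps, n_equilibration=500,
                dt=5e-5, sample_every=100, n_bins=40,
            )
            res = run_brownian(cfg)
            dev = measure_concentration_profile(res, self.make_reference(pot, cfg))
            sigmas.append(dev.sigma_bin)
        # snapshot-noise component halves in variance with doubled sampling
        assert sigmas[0] / sigmas[1] == pytest.approx(np.sqrt(2), rel=0.05)

    def test_geometry_mismatch_rejected(self, reduced_plateau):
        cfg = small_particle_config(reduced_plateau, N=100, n_steps=200, n_equilibration=50)
        res = run_brownian(cfg)
        other = MembranePotential("gaussian-barrier", 30.0, 1.0, 0.05)
        ref = self.make_reference(other, cfg)
        with pytest.raises(ValueError, match="geometry"):
            measure_concentration_profile(res, ref)
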