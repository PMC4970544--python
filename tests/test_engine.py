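"""Tests of the Brownian-dynamics propagator."""

import numpy as np
import pytest

from vwforce import (ChainConfig, ChainState, EngineConfig, kbt,
                     lifetime_under_shear, random_displacement, run, step,
                     stokes_mobility, tensile_profile)
from vwforce.bdmodel import initial_positions
from vwforce.engine import _run_numpy, drift_correction, mobility_matrix


class TestRandomDisplacement:
    def test_zero_dt_gives_zero(self, rng):
        mu = np.eye(6)
        assert np.all(random_displacement(mu, 0.0, 298.0, rng) == 0.0)

    def test_isotropic_covariance(self, rng):
        mu0 = 2.0e6  # nm/(pN s)
        mu = mu0 * np.eye(3)
        dt = 55e-9
        draws = np.array([random_displacement(mu, dt, 298.0, rng)
                          for _ in range(50_000)])
        cov = draws.T @ draws / draws.shape[0]
        target = 2 * kbt() * dt * mu
        np.testing.assert_allclose(cov, target,
                                   atol=0.03 * target.max())


class TestStep:
    CFG = ChainConfig(n_beads=4)

    def test_quiescent_state_unchanged(self):
        """A two-bead chain at its joint LJ/spring minimum does not move
        without shear or noise."""
        cfg = ChainConfig(n_beads=2)
        eng = EngineConfig(shear_rate=0.0, thermal_noise=False,
                           hydrodynamics="free", wall=False, grafted=False,
                           backend="numpy")
        pos = np.array([[0.0, 0.0, 500.0], [2 * cfg.a, 0.0, 500.0]])
        out = step(ChainState(pos), cfg, eng, np.random.default_rng(0))
        np.testing.assert_allclose(out.positions, pos, atol=1e-12)

    def test_pure_shear_advection(self):
        """With free-draining hydrodynamics a bead at height z advects by
        shear_rate * z * dt along x."""
        cfg = ChainConfig(n_beads=4, epsilon=1e-30, kappa=1e-30)
        eng = EngineConfig(shear_rate=1000.0, thermal_noise=False,
                           hydrodynamics="none", wall=False, grafted=False,
                           backend="numpy")
        pos = initial_positions(cfg, "line")
        pos[:, 2] = [100.0, 200.0, 300.0, 400.0]
        out = step(ChainState(pos), cfg, eng, np.random.default_rng(0))
        np.testing.assert_allclose(out.positions[:, 0] - pos[:, 0],
                                   1000.0 * pos[:, 2] * eng.dt, rtol=1e-9)

    def test_grafted_bead_fixed(self):
        cfg = ChainConfig(n_beads=5)
        eng = EngineConfig(shear_rate=5453.0, n_steps=2000, n_equil=0,
                           seed=3, backend="numba")
        res = run(cfg, eng)
        start = initial_positions(cfg, "coil", seed=eng.seed)
        np.testing.assert_array_equal(res.final_positions[0], start[0])

    def test_drift_correction_zero_without_wall(self):
        eng = EngineConfig(hydrodynamics="free")
        st = ChainState(initial_positions(self.CFG, "coil", seed=1))
        assert np.all(drift_correction(st, self.CFG, eng) == 0.0)

    def test_drift_correction_positive_above_wall(self):
        """The spurious drift points away from the wall wherever the
        truncated far-field mobility is monotone (z >= 1.2a)."""
        eng = EngineConfig(hydrodynamics="wall")
        pos = initial_positions(self.CFG, "line")
        pos[:, 2] = self.CFG.a * np.array([1.25, 1.5, 3.0, 10.0])
        st = ChainState(pos)
        assert np.all(drift_correction(st, self.CFG, eng) > 0.0)


class TestRun:
    def test_same_seed_same_blocks(self):
        cfg = ChainConfig(n_beads=6)
        eng = EngineConfig(shear_rate=545.0, n_steps=2000, n_equil=200,
                           seed=7, backend="numba")
        a = run(cfg, eng)
        b = run(cfg, eng)
        np.testing.assert_array_equal(a.block_bond_lengths,
                                      b.block_bond_lengths)

    def test_numba_and_numpy_paths_agree_without_noise(self):
        cfg = ChainConfig()
        eng = EngineConfig(shear_rate=5453.0, n_steps=300, n_equil=0,
                           thermal_noise=False, seed=1, backend="numpy")
        pos0 = initial_positions(cfg, "coil", seed=1)
        bm_np, fp_np, _ = _run_numpy(pos0, cfg, eng)
        from vwforce.fastengine import run_kernel_wrapper
        bm_nb, fp_nb, _ = run_kernel_wrapper(pos0, cfg, eng)
        np.testing.assert_allclose(fp_np, fp_nb, atol=1e-10)
        np.testing.assert_allclose(bm_np, bm_nb, atol=1e-10)

    def test_zero_temperature_relaxation_to_rest_bonds(self):
        """A stretched straight chain relaxes to bond length 2a."""
        cfg = ChainConfig()
        pos0 = initial_positions(cfg, "line")
        pos0[:, 0] *= 1.2
        eng = EngineConfig(thermal_noise=False, wall=False, grafted=False,
                           hydrodynamics="free", n_steps=20_000, n_equil=0,
                           backend="numba", seed=0)
        res = run(cfg, eng, initial=pos0)
        bonds = np.linalg.norm(np.diff(res.final_positions, axis=0), axis=1)
        np.testing.assert_allclose(bonds, 2 * cfg.a, atol=0.1)

    def test_cohesive_chain_collapses(self):
        """eps = 2 kBT collapses the untethered multimer relative to the
        phantom (spring-only) chain."""
        rgs = {}
        for eps in (2.0, 1e-9):
            cfg = ChainConfig(epsilon=eps)
            eng = EngineConfig(hydrodynamics="free", wall=False,
                               grafted=False, n_steps=120_000,
                               n_equil=40_000, record_positions=True,
                               backend="numba", seed=9)
            res = run(cfg, eng)
            P = res.block_positions
            rg = np.sqrt(((P - P.mean(axis=1, keepdims=True)) ** 2)
                         .sum(axis=2).mean(axis=1))
            rgs[eps] = rg.mean()
        assert rgs[2.0] < 0.9 * rgs[1e-9]


class TestTensileProfile:
    CFG = ChainConfig()

    def test_rest_length_gives_zero_force(self):
        p = tensile_profile(np.full(19, 60.0), self.CFG)
        np.testing.assert_allclose(p.tensile_force, 0.0, atol=1e-12)

    def test_unit_conversion(self):
        cfg = ChainConfig(kappa=203.0)  # kBT/nm^2
        p = tensile_profile(np.full(19, 2 * cfg.a + 1.0), cfg)
        assert p.tensile_force[0] == pytest.approx(203 * 4.1124, rel=1e-6)
        assert p.tensile_force[0] == pytest.approx(834.8, rel=1e-3)

    def test_contour_length_in_profile(self):
        p = tensile_profile(np.full(19, 60.0), self.CFG)
        assert p.contour_length == pytest.approx(1140.0)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            tensile_profile(np.full(5, 60.0), self.CFG)


class TestLifetime:
    def test_zero_tension_gives_tau0(self):
        p = tensile_profile(np.full(19, 60.0), ChainConfig())
        assert lifetime_under_shear(p, 12.0, 0.3) == pytest.approx(12.0)

    def test_one_thermal_unit(self):
        cfg = ChainConfig()
        ext = kbt() / 0.3 / cfg.kappa_pn_nm
        p = tensile_profile(np.full(19, 60.0 + ext), cfg)
        assert lifetime_under_shear(p, 12.0, 0.3) \
            == pytest.approx(12.0 / np.e, rel=1e-9)

    def test_compression_clamped_with_warning(self):
        p = tensile_profile(np.full(19, 55.0), ChainConfig())
        with pytest.warns(UserWarning):
            tau = lifetime_under_shear(p, 12.0, 0.3)
        assert tau == pytest.approx(12.0)
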