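"""Tests of the shape, distance, end-to-end and rotation diagnostics."""

import numpy as np
import pytest

import shearchain as sc


def _square_shape():
    return np.array([[1.0, 0, 0], [0, 1.0, 0], [-1.0, 0, 0], [0, -1.0, 0]])


class TestRotationDiagnostics:
    def test_rigid_rotation_recovered_exactly(self):
        spec = sc.RigidMotionSpec(base_shape=_square_shape(), angular_rate=0.1,
                                  rotation_axis="z", n_frames=50)
        rot = sc.rotation_diagnostics(sc.make_rigid_trajectory(spec))
        assert rot.z.omega == pytest.approx(0.1, abs=1e-13)
        assert rot.z.term_ab == pytest.approx(-rot.z.term_ba, abs=1e-13)
        # planar rotation about z induces no apparent x/y rotation
        assert rot.x.omega == pytest.approx(0.0, abs=1e-13)
        assert rot.y.omega == pytest.approx(0.0, abs=1e-13)

    def test_pure_translation_has_no_angular_motion(self, rng):
        spec = sc.RigidMotionSpec(base_shape=rng.normal(size=(6, 3)),
                                  translation_velocity=(0.3, -1.0, 2.0), n_frames=40)
        rot = sc.rotation_diagnostics(sc.make_rigid_trajectory(spec))
        for ax in "xyz":
            assert rot[ax].L == pytest.approx(0.0, abs=1e-12)

    def test_identity_omega_times_moment_is_L(self):
        spec = sc.RigidMotionSpec(base_shape=_square_shape(), angular_rate=-0.4,
                                  n_frames=30)
        rot = sc.rotation_diagnostics(sc.make_rigid_trajectory(spec))
        assert rot.z.omega * rot.z.moment == pytest.approx(rot.z.L, rel=1e-12)

    def test_missing_displacements_rejected(self, rng):
        traj = sc.Trajectory(rng.normal(size=(5, 4, 3)), np.arange(1.0, 6.0),
                             sc.SimulationConfig(n_beads=4))
        with pytest.raises(ValueError, match="displacement"):
            sc.rotation_diagnostics(traj)


class TestShapeMoments:
    def test_point_chain_all_zero(self):
        traj = sc.Trajectory(np.zeros((3, 4, 3)), np.arange(1.0, 4.0),
                             sc.SimulationConfig(n_beads=4))
        sm = sc.shape_moments(traj)
        assert np.all(sm.second == 0) and np.all(sm.fourth == 0) and sm.rg2 == 0

    def test_symmetry_and_trace(self, short_run):
        sm = sc.shape_moments(short_run)
        assert np.allclose(sm.second, sm.second.T)
        assert sm.rg2 == pytest.approx(np.trace(sm.second))
        assert np.all(np.diag(sm.second) > 0)

    def test_zero_shear_isotropy(self, short_run):
        sm = sc.shape_moments(short_run)
        d = np.diag(sm.second)
        assert np.all(np.abs(d - d.mean()) < 5 * np.diag(sm.second_err) + 0.05 * d.mean())


class TestEndToEnd:
    def test_frozen_chain_correlators_constant(self, rng):
        frame = rng.normal(size=(6, 3))
        traj = sc.Trajectory(np.repeat(frame[None], 10, axis=0), np.arange(1.0, 11.0),
                             sc.SimulationConfig(n_beads=6))
        vec, unit = sc.end_to_end_correlations(traj, max_lag=5)
        re = frame[-1] - frame[0]
        assert np.allclose(vec.values, re @ re)
        assert np.allclose(unit.values, 1.0)

    def test_unit_vector_normalized_at_lag_zero(self, short_run):
        _, unit = sc.end_to_end_correlations(short_run, max_lag=10)
        assert unit.values[0] == pytest.approx(1.0)

    def test_zero_shear_decay_matches_mode_expansion(self, zero_shear_run):
        """Re = RN - R1 expands over odd Rouse modes, so its autocorrelation is
        sum_n 12 D_n^2 <C_n^2> exp(-Gamma_n t) with D_n the end-minus-end cosine
        difference; the early-time fitted rate must match the same fit applied
        to this closed-form curve (dominated by, but not equal to, Gamma_1)."""
        cfg = zero_shear_run.config
        n_beads = cfg.n_beads
        rates = sc.analytic_rates(cfg).rates
        var = sc.mode_stationary_variance(cfg)
        i = np.arange(1, n_beads + 1)
        vec, _ = sc.end_to_end_correlations(zero_shear_run, max_lag=4000)
        theory = np.zeros_like(vec.values)
        for n in range(1, n_beads):
            d_n = np.cos(n * np.pi * (n_beads - 0.5) / n_beads) - np.cos(
                n * np.pi * 0.5 / n_beads
            )
            theory += 3 * (2 * d_n) ** 2 * var[n] * np.exp(-rates[n] * vec.lags)
        theory_fit = sc.fit_initial_exponential(
            sc.CorrelationFunction(vec.lags, theory, vec.n_samples)
        )
        fit = sc.fit_initial_exponential(vec)
        gamma1 = rates[1]
        assert fit.rate == pytest.approx(theory_fit.rate, rel=0.10)
        assert gamma1 < fit.rate < 3 * gamma1


class TestDistanceDistributions:
    def test_two_bead_chain_identical_histograms(self):
        cfg = sc.SimulationConfig(n_beads=2, n_production_steps=2000,
                                  n_thermalization_steps=1000, seed=8)
        dd = sc.distance_distributions(sc.simulate(cfg))
        assert np.array_equal(dd.all_pairs.counts, dd.nearest_neighbor.counts)
        assert dd.second_nearest_neighbor.n_samples == 0

    def test_frozen_chain_single_bins(self):
        pos = np.zeros((4, 3, 3))
        pos[:, 1, 0] = 1.0
        pos[:, 2, 0] = 2.0
        traj = sc.Trajectory(pos, np.arange(1.0, 5.0), sc.SimulationConfig(n_beads=3))
        dd = sc.distance_distributions(traj, n_bins=10)
        assert np.count_nonzero(dd.nearest_neighbor.counts) == 1
        assert dd.nearest_neighbor.n_samples == 8  # 2 bonds x 4 frames

    def test_bond_length_statistics(self, short_run):
        # Gaussian bonds: <b^2> = 3 kBT / k per bond
        bonds = np.diff(short_run.positions, axis=1)
        b2 = (bonds**2).sum(axis=2).mean()
        assert b2 == pytest.approx(3.0, rel=0.05)
        dd = sc.distance_distributions(short_run, n_bins=200)
        centers = 0.5 * (dd.nearest_neighbor.edges[1:] + dd.nearest_neighbor.edges[:-1])
        hist_mean_sq = (centers**2 * dd.nearest_neighbor.counts).sum() / dd.nearest_neighbor.n_samples
        assert hist_mean_sq == pytest.approx(3.0, rel=0.06)

    def test_bad_bin_width_rejected(self, short_run):
        with pytest.raises(ValueError):
            sc.distance_distributions(short_run, bin_width=0.0)


class TestComDiffusion:
    def test_com_msd_slope(self, short_run):
        cfg = short_run.config
        _, msd, slope = sc.observables.com_msd(short_run, max_lag=10)
        expected = 6 * cfg.thermal_energy / (cfg.n_beads * cfg.friction)
        assert slope == pytest.approx(expected, rel=0.05)
        assert np.all(np.diff(msd) > 0)
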