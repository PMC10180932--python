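"""Unit and property tests of the Euler-Maruyama chain integrator."""

import numpy as np
import pytest

import shearchain as sc
from shearchain.simulator import ChainState, DivergenceError


class TestSpringDrift:
    def test_two_bead_hooke(self):
        pos = np.array([[0.0, 0, 0], [2.5, 0, 0]])
        drift = sc.spring_drift(pos, 1.0, 1.0)
        assert np.allclose(drift, [[2.5, 0, 0], [-2.5, 0, 0]])

    def test_coincident_beads_no_force(self):
        pos = np.ones((5, 3))
        assert np.all(sc.spring_drift(pos, 3.0, 2.0) == 0)

    def test_matches_connectivity_matrix_oracle(self, rng):
        pos = rng.normal(size=(16, 3))
        k, f = 1.7, 0.6
        expected = -(k / f) * sc.connectivity_matrix(16) @ pos
        assert np.allclose(sc.spring_drift(pos, k, f), expected, atol=1e-13)

    @pytest.mark.parametrize("n", [2, 3, 16, 33])
    def test_internal_forces_cancel(self, rng, n):
        drift = sc.spring_drift(rng.normal(size=(n, 3)), 2.0, 1.0)
        assert np.allclose(drift.sum(axis=0), 0, atol=1e-12)

    def test_single_bead_rejected(self):
        with pytest.raises(ValueError):
            sc.spring_drift(np.zeros((1, 3)), 1.0, 1.0)


class TestShearDrift:
    def test_uniform_y_gives_zero(self):
        pos = np.column_stack([np.arange(4.0), np.full(4, 2.0), np.zeros(4)])
        assert np.all(sc.shear_drift(pos, 0.3) == 0)

    def test_linear_profile(self):
        pos = np.array([[0.0, 1, 0], [0.0, -1, 0]])
        drift = sc.shear_drift(pos, 0.1)
        assert np.allclose(drift, [[0.1, 0, 0], [-0.1, 0, 0]])

    def test_zero_shear(self, rng):
        assert np.all(sc.shear_drift(rng.normal(size=(6, 3)), 0.0) == 0)

    def test_com_never_advected(self, rng):
        drift = sc.shear_drift(rng.normal(size=(10, 3)), 0.25)
        assert abs(drift[:, 0].mean()) < 1e-14
        assert np.all(drift[:, 1:] == 0)


class TestThermalDisplacement:
    def test_zero_temperature(self, rng):
        cfg = sc.SimulationConfig(thermal_energy=0.0)
        assert np.all(sc.thermal_displacement(rng, cfg) == 0)

    def test_amplitude_matches_diffusion_step(self):
        cfg = sc.SimulationConfig()  # kBT=1, dt=1e-3, f=1
        rng = np.random.default_rng(9)
        draws = np.concatenate(
            [sc.thermal_displacement(rng, cfg).ravel() for _ in range(21_000)]
        )
        assert draws.std() == pytest.approx(np.sqrt(0.002), rel=0.01)

    def test_seeded_streams_identical(self):
        cfg = sc.SimulationConfig()
        a = sc.thermal_displacement(np.random.default_rng(3), cfg)
        b = sc.thermal_displacement(np.random.default_rng(3), cfg)
        assert np.array_equal(a, b)


class TestStep:
    def test_pure_relaxation_contracts_span(self):
        cfg = sc.SimulationConfig(n_beads=8, thermal_energy=0.0)
        pos = np.zeros((8, 3))
        pos[:, 0] = np.linspace(-1, 1, 8)
        state = ChainState(pos)
        rng = np.random.default_rng(0)
        span = 2.0
        for _ in range(50):
            state, _ = sc.step(state, cfg, rng)
            new_span = np.ptp(state.positions[:, 0])
            assert new_span < span
            span = new_span

    def test_collapsed_pair_is_fixed_point(self):
        cfg = sc.SimulationConfig(n_beads=2, thermal_energy=0.0)
        state = ChainState(np.zeros((2, 3)))
        new, disp = sc.step(state, cfg, np.random.default_rng(0))
        assert np.all(new.positions == 0) and np.all(disp == 0)

    def test_pure_advection(self):
        # springless athermal chain: bead at y=+1 relative to COM drifts in +x at G
        cfg = sc.SimulationConfig(n_beads=2, thermal_energy=0.0, spring_constant=0.0,
                                  shear_rate=0.2)
        state = ChainState(np.array([[0.0, 1.0, 0], [0.0, -1.0, 0]]))
        new, disp = sc.step(state, cfg, np.random.default_rng(0))
        assert disp[0, 0] == pytest.approx(0.2 * cfg.time_step)
        assert np.allclose(new.positions[:, 1:], state.positions[:, 1:])

    def test_displacement_is_position_difference(self, rng):
        cfg = sc.SimulationConfig(n_beads=4, shear_rate=0.1)
        state = ChainState(rng.normal(size=(4, 3)))
        new, disp = sc.step(state, cfg, np.random.default_rng(1))
        assert np.allclose(new.positions - state.positions, disp)
        assert new.time == pytest.approx(cfg.time_step)


class TestSimulate:
    def test_frame_count_and_times(self):
        cfg = sc.SimulationConfig(n_beads=4, n_production_steps=105,
                                  n_thermalization_steps=10, sample_stride=10, seed=1)
        traj = sc.simulate(cfg)
        assert traj.n_frames == 10
        assert np.allclose(traj.times, 0.01 * np.arange(1, 11))
        assert traj.frame_spacing == pytest.approx(0.01)

    def test_seed_reproducibility_bitwise(self):
        cfg = sc.SimulationConfig(n_beads=6, n_production_steps=5000,
                                  n_thermalization_steps=500, seed=77)
        a, b = sc.simulate(cfg), sc.simulate(cfg)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.displacements, b.displacements)

    def test_linear_step_operator_eigenvalues(self):
        # with G=0, kBT=0 a pure-mode configuration contracts by (1 - dt*Gamma_n)
        cfg = sc.SimulationConfig(n_beads=16, thermal_energy=0.0)
        rates = sc.analytic_rates(cfg).rates
        for n in (1, 5, 15):
            state = sc.make_single_mode_chain(16, n, 0.7)
            new, _ = sc.step(state, cfg, np.random.default_rng(0))
            assert np.allclose(
                new.positions, (1 - cfg.time_step * rates[n]) * state.positions,
                atol=1e-14,
            )

    def test_athermal_bond_energy_decreases(self, rng):
        cfg = sc.SimulationConfig(n_beads=8, thermal_energy=0.0,
                                  n_production_steps=300, n_thermalization_steps=0,
                                  sample_stride=1, seed=3)
        traj = sc.simulate(cfg, initial=rng.normal(size=(8, 3)))
        bonds = np.diff(traj.positions, axis=1)
        energy = (bonds**2).sum(axis=(1, 2))
        assert np.all(np.diff(energy) <= 1e-12)

    def test_equilibrium_bond_statistics(self, short_run):
        # stationary OU: each bond component Gaussian with variance kBT/k
        bonds = np.diff(short_run.positions, axis=1)
        var = bonds.var(axis=(0, 1))
        # per-component estimates carry ~10% sampling noise at this length;
        # the pooled estimate is much tighter
        assert np.allclose(var, 1.0, rtol=0.15)
        assert var.mean() == pytest.approx(1.0, rel=0.05)

    def test_divergence_reported_with_step_index(self):
        cfg = sc.SimulationConfig(n_beads=16, time_step=0.9,
                                  n_production_steps=100_000,
                                  n_thermalization_steps=0, seed=0)
        with pytest.raises(DivergenceError) as exc:
            sc.simulate(cfg)
        assert exc.value.step_index > 0

    def test_shear_com_x_not_advected(self):
        cfg = sc.SimulationConfig(n_beads=8, shear_rate=0.15, thermal_energy=0.0,
                                  n_production_steps=2000, n_thermalization_steps=0,
                                  sample_stride=10, seed=2)
        init = np.random.default_rng(4).normal(size=(8, 3))
        traj = sc.simulate(cfg, initial=init)
        com_x = traj.positions[:, :, 0].mean(axis=1)
        assert np.allclose(com_x, init[:, 0].mean(), atol=1e-12)


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs", [dict(n_beads=1), dict(time_step=0.0), dict(sample_stride=0),
                   dict(friction=-1.0)]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            sc.SimulationConfig(**kwargs)

    def test_noise_scale(self):
        cfg = sc.SimulationConfig(thermal_energy=2.0, time_step=0.01, friction=4.0)
        assert cfg.noise_scale == pytest.approx(0.1)

    def test_yaml_roundtrip(self, tmp_path):
        cfg = sc.SimulationConfig(n_beads=8, shear_rate=0.05, seed=9)
        sc.save_config(cfg, tmp_path / "c.yaml")
        assert sc.load_config(tmp_path / "c.yaml") == cfg
        assert sc.load_config(tmp_path / "c.yaml", seed=10).seed == 10

    def test_unknown_key_named(self, tmp_path):
        (tmp_path / "c.yaml").write_text("n_beads: 4\nbogus_key: 1\n")
        with pytest.raises(KeyError, match="bogus_key"):
            sc.load_config(tmp_path / "c.yaml")
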