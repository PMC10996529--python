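"""Simulator physics: force correctness, integrator statistics, protocol."""

import numpy as np
import pytest

import lcd_llps as m
from lcd_llps.constants import KB
from lcd_llps.simulate import compute_forces, potential_energy


@pytest.fixture(scope="module")
def three_chain(model0):
    wt = m.build_variant("WT")
    return m.initialize_system(wt, 3, (20.0, 20.0, 20.0), seed=21,
                               temperature=model0.temperature)


class TestForces:
    def test_newtons_third_law(self, three_chain, model0):
        f = compute_forces(three_chain, model0)
        net = f.sum(axis=0)
        assert np.abs(net).max() < 1e-9 * np.abs(f).max()

    def test_neighbor_list_matches_brute_force(self, three_chain, model0):
        """Cell-list pair search reproduces the O(N^2) double loop."""
        f_cell = compute_forces(three_chain, model0)
        f_brute = compute_forces(three_chain, model0, brute_force=True)
        np.testing.assert_allclose(f_cell, f_brute, rtol=1e-10,
                                   atol=1e-10 * np.abs(f_brute).max())

    def test_neighbor_list_matches_brute_force_after_dynamics(self, model0):
        wt = m.build_variant("WT")
        state = m.initialize_system(wt, 3, (12.0, 12.0, 12.0), seed=22)
        sim = m.SimConfig(seed=3, damping_time=5.0, frame_interval=1.0,
                          total_time=20.0, equilibration_time=10.0)
        m.langevin_propagate(state, model0, sim, 10.0, record=False)
        f_cell = compute_forces(state, model0)
        f_brute = compute_forces(state, model0, brute_force=True)
        np.testing.assert_allclose(f_cell, f_brute, rtol=1e-10,
                                   atol=1e-10 * np.abs(f_brute).max())

    def test_electrostatic_cutoff_respected(self, model0):
        """Two charged beads at 3.6 nm feel no electrostatic force."""
        arg = m.build_variant("custom", "R")
        box = np.array([20.0, 20.0, 20.0])
        for dist, expect_zero in ((3.6, True), (3.4, False)):
            pos = np.array([[0.0, 0, 0], [dist, 0, 0]])
            state = m.SystemState(arg, 2, box, pos, np.zeros((2, 3)))
            f = compute_forces(state, model0)
            if expect_zero:
                assert np.all(f == 0.0)   # MLJ cutoff (2 nm) already passed
            else:
                assert f[0, 0] < 0.0      # like charges repel

    def test_forces_are_negative_energy_gradient(self, three_chain, model0):
        """Central-difference check of a random coordinate subset."""
        state = three_chain.copy()
        f = compute_forces(state, model0)
        rng = np.random.default_rng(23)
        h = 1e-6
        for _ in range(12):
            i = int(rng.integers(state.n_beads))
            d = int(rng.integers(3))
            state.positions[i, d] += h
            e_plus = potential_energy(state, model0)
            state.positions[i, d] -= 2 * h
            e_minus = potential_energy(state, model0)
            state.positions[i, d] += h
            grad = (e_plus - e_minus) / (2 * h)
            assert f[i, d] == pytest.approx(-grad, rel=2e-4, abs=2e-3)


class TestLangevin:
    def test_bitwise_seed_determinism(self, model0):
        wt = m.build_variant("WT")
        sim = m.SimConfig(seed=11, damping_time=2.0, frame_interval=1.0,
                          total_time=20.0, equilibration_time=10.0)
        outs = []
        for _ in range(2):
            state = m.initialize_system(wt, 2, (15., 15., 15.), seed=11)
            traj = m.langevin_propagate(state, model0, sim, 10.0)
            outs.append((traj.frames.copy(), state.velocities.copy()))
        np.testing.assert_array_equal(outs[0][0], outs[1][0])
        np.testing.assert_array_equal(outs[0][1], outs[1][1])
        # a different seed diverges
        state = m.initialize_system(wt, 2, (15., 15., 15.), seed=11)
        sim2 = m.SimConfig(seed=12, damping_time=2.0, frame_interval=1.0,
                          total_time=20.0, equilibration_time=10.0)
        traj2 = m.langevin_propagate(state, model0, sim2, 10.0)
        assert not np.array_equal(outs[0][0], traj2.frames)

    def test_kinetic_temperature_equipartition(self, model0):
        """Time-averaged kinetic temperature matches the thermostat set
        point within 3 standard errors over >= 1 ns."""
        wt = m.build_variant("WT")
        state = m.initialize_system(wt, 2, (14.0, 14.0, 14.0), seed=31)
        sim = m.SimConfig(seed=31, damping_time=5.0, thermostat_interval=5,
                          frame_interval=2.0, total_time=1300.0,
                          equilibration_time=100.0)
        m.langevin_propagate(state, model0, sim, 100.0, record=False)
        temps = []
        for _ in range(120):
            m.langevin_propagate(state, model0, sim, 10.0, record=False)
            temps.append(state.kinetic_temperature())
        temps = np.asarray(temps)
        se = temps.std(ddof=1) / np.sqrt(temps.size)
        assert abs(temps.mean() - 298.0) < 3 * max(se, 1e-9) + 1.0

    def test_free_diffusion_msd_slope(self):
        """Non-interacting beads diffuse with MSD slope 6 kT/zeta."""
        gly = m.build_variant("custom", "G")
        n = 400
        box = np.array([200.0, 200.0, 200.0])
        rng = np.random.default_rng(0)
        pos = (rng.random((n, 3)) - 0.5) * 10.0
        mmass = gly.masses[0]
        model = m.InteractionModel(c_nacl=0.0, lambda_scale=0.0,
                                   charge_scale=0.0, eps0=0.0, eps_slope=0.0)
        state = m.SystemState(gly, n, box, pos.copy(), np.zeros((n, 3)))
        tau = 2.0
        sim = m.SimConfig(seed=17, damping_time=tau, frame_interval=10.0,
                          total_time=300.0, equilibration_time=100.0)
        m.langevin_propagate(state, model, sim, 100.0, record=False)
        start = state.positions.copy()
        t_ref = state.step * sim.timestep
        traj = m.langevin_propagate(state, model, sim, 200.0, record=True)
        msd = ((traj.frames - start) ** 2).sum(axis=2).mean(axis=1)
        t = traj.times - t_ref
        slope = np.linalg.lstsq(np.column_stack([t, np.ones_like(t)]),
                                msd, rcond=None)[0][0]
        zeta = mmass / tau
        expected = 6.0 * KB * 298.0 / zeta
        # ballistic correction is tiny at t >> tau; finite-n noise ~ few %
        assert slope == pytest.approx(expected, rel=0.10)

    def test_nve_energy_conservation(self, model0):
        """Thermostat off, small dt: total energy drift < 0.1% over 1e4
        steps of a 2-chain system."""
        wt = m.build_variant("WT")
        state = m.initialize_system(wt, 2, (12.0, 12.0, 12.0), seed=41)
        state.velocities *= 0.5
        sim = m.SimConfig(seed=41, damping_time=-1.0, timestep=0.002,
                          frame_interval=0.2, total_time=30.0,
                          equilibration_time=10.0)
        def total_energy():
            ke = 0.5 * float(np.sum(state.masses[:, None] * state.velocities**2))
            return ke + potential_energy(state, model0)
        m.langevin_propagate(state, model0, sim, 4.0, record=False)  # settle
        e0 = total_energy()
        m.langevin_propagate(state, model0, sim, 20.0, record=False)  # 1e4 steps
        e1 = total_energy()
        ke_scale = 1.5 * state.n_beads * KB * 298.0
        assert abs(e1 - e0) < 1e-3 * max(abs(e0), ke_scale)

    def test_bond_length_statistics(self, model0):
        """Equilibrated bond lengths: mean ~ r0, variance ~ kT/k."""
        wt = m.build_variant("WT")
        state = m.initialize_system(wt, 2, (16.0, 16.0, 16.0), seed=51)
        sim = m.SimConfig(seed=51, damping_time=5.0, thermostat_interval=5,
                          frame_interval=5.0, total_time=600.0,
                          equilibration_time=100.0)
        m.langevin_propagate(state, model0, sim, 100.0, record=False)
        traj = m.langevin_propagate(state, model0, sim, 500.0, record=True)
        L = wt.length
        pos = traj.frames.reshape(traj.n_frames, 2, L, 3)
        bonds = np.linalg.norm(np.diff(pos, axis=2), axis=3).ravel()
        assert bonds.mean() == pytest.approx(0.38, abs=0.01)
        assert bonds.var() == pytest.approx(KB * 298.0 / 8305.0, rel=0.25)
        assert bonds.max() < 1.0   # chains never fragment

    def test_nonfinite_coordinates_abort_with_diagnostics(self, model0):
        """A non-finite degree of freedom aborts the run, reporting the
        step at which it was detected."""
        wt = m.build_variant("WT")
        state = m.initialize_system(wt, 2, (14.0, 14.0, 14.0), seed=61)
        state.velocities[5, 1] = np.nan
        sim = m.SimConfig(seed=61, damping_time=1.0, frame_interval=5.0,
                          total_time=100.0, equilibration_time=50.0)
        with pytest.raises(FloatingPointError, match="step"):
            m.langevin_propagate(state, model0, sim, 50.0, record=False)


class TestSqueezeAndSlab:
    def test_smoke_protocol_geometry(self, model0):
        """Compress to the cube, extend to the slab: box dims correct,
        beads near the slab center, topology intact."""
        wt = m.build_variant("WT")
        sim = m.SimConfig(seed=71, damping_time=1.0, frame_interval=10.0,
                          total_time=200.0, equilibration_time=100.0,
                          initial_box=(22.5, 22.5, 22.5),
                          slab_box=(15.0, 15.0, 45.0), squeeze_steps=2000,
                          squeeze_segments=40)
        state = m.initialize_system(wt, 2, sim.initial_box, seed=71)
        n_beads = state.n_beads
        m.squeeze_and_slab(state, model0, sim)
        assert state.box.tolist() == [15.0, 15.0, 45.0]
        assert state.n_beads == n_beads
        # slab centered at origin: |z| within the old cube plus chain overhang
        assert np.abs(state.positions[:, 2]).max() < 0.5 * 15.0 + 3.0
        # chains unbroken through compression and extension
        pos = state.positions.reshape(2, wt.length, 3)
        bonds = np.linalg.norm(np.diff(pos, axis=1), axis=2)
        assert bonds.max() < 1.0
        # and dynamics continue stably in the slab
        m.langevin_propagate(state, model0, sim, 20.0, record=False)
        assert np.isfinite(state.positions).all()

    def test_density_bookkeeping_after_compression(self, model0):
        wt = m.build_variant("WT")
        sim = m.SimConfig(seed=72, damping_time=1.0, frame_interval=10.0,
                          total_time=200.0, equilibration_time=100.0,
                          initial_box=(18.0, 18.0, 18.0),
                          slab_box=(12.0, 12.0, 36.0), squeeze_steps=1000,
                          squeeze_segments=20)
        state = m.initialize_system(wt, 2, sim.initial_box, seed=72)
        m.squeeze_and_slab(state, model0, sim)
        # all beads belong to the compressed cube volume at slab extension
        inside = np.abs(state.positions[:, :2]).max() < 0.5 * 12.0 + 3.0
        assert inside
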