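"""Integrator, thermostat, barostat and robot-drive behaviour."""

import numpy as np
import pytest

from nanospin.builder import (SpikyRobotGeometry, assemble_scene,
                              build_bilayer)
from nanospin.engine import Engine, InstabilityError, total_energy_forces
from nanospin.forcefield import (BeadKind, BondOverstretchError,
                                 reference_energy_forces)
from nanospin.params import ForceFieldParams, ProtocolParams
from nanospin.system import ParticleSystem, rotation_matrix

FF = ForceFieldParams()


def ideal_gas(n=300, box=12.0, seed=0, T=1.1):
    """Noninteracting CARGO beads (pairwise WCA at 2 sigma, but dilute)."""
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0, box, (n, 3))
    vel = rng.normal(0, np.sqrt(T), (n, 3))
    vel -= vel.mean(axis=0)
    kinds = np.full(n, int(BeadKind.HEAD), dtype=np.int64)
    return ParticleSystem(pos, vel, kinds, np.zeros((0, 3), dtype=np.int64),
                          np.full(n, -1, dtype=np.int64),
                          np.array([box, box, box]))


def proto(**kw):
    base = dict(n_steps=0, seed=1, robot_enabled=False, cargo_count=0,
                box_z=40.0, barostat_enabled=False)
    base.update(kw)
    return ProtocolParams(**base)


class TestForceEquivalence:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_cell_list_matches_all_pairs(self, seed):
        """Cell-list energies/forces equal the brute-force double loop on
        a random-ish bilayer configuration."""
        s = build_bilayer(6, 6, 1.2 + 0.1 * seed, 40.0, seed=seed)
        e_ref, f_ref = reference_energy_forces(s, FF)
        e_fast, f_fast = total_energy_forces(s, FF)
        assert e_fast == pytest.approx(e_ref, rel=1e-9)
        scale = max(1.0, np.abs(f_ref).max())
        assert np.abs(f_fast - f_ref).max() / scale < 1e-9

    def test_cell_list_matches_with_robot_and_cargo(self):
        geom = SpikyRobotGeometry(core_radius=1.5, n_spikes=4,
                                  spike_length_range=(2.0, 3.0), seed=3)
        p = proto(robot_enabled=True, cargo_count=8, box_z=60.0, seed=3)
        s = assemble_scene(p, geom, nx=10, ny=10)
        e_ref, f_ref = reference_energy_forces(s, FF)
        e_fast, f_fast = total_energy_forces(s, FF)
        assert e_fast == pytest.approx(e_ref, rel=1e-9)
        scale = max(1.0, np.abs(f_ref).max())
        assert np.abs(f_fast - f_ref).max() / scale < 1e-9

    def test_net_pair_force_is_zero(self):
        s = build_bilayer(8, 8, 1.2, 40.0, seed=2)
        _, f = total_energy_forces(s, FF)
        assert np.abs(f.sum(axis=0)).max() < 1e-9


class TestThermostat:
    def test_free_particle_equipartition(self):
        """An interaction-free ensemble thermostatted for 10^4 steps has
        mean kinetic energy 3/2 kT per bead within 3%."""
        n, box = 200, 100.0
        rng = np.random.default_rng(4)
        pos = rng.uniform(0, box, (n, 3))
        kinds = np.full(n, int(BeadKind.HEAD), dtype=np.int64)
        s = ParticleSystem(pos, np.zeros((n, 3)), kinds,
                           np.zeros((0, 3), dtype=np.int64),
                           np.full(n, -1, dtype=np.int64),
                           np.array([box, box, box]))
        # spread beads so the WCA never engages: grid placement
        g = int(np.ceil(n ** (1 / 3)))
        idx = np.arange(n)
        s.positions[:, 0] = (idx % g + 0.5) * box / g
        s.positions[:, 1] = (idx // g % g + 0.5) * box / g
        s.positions[:, 2] = (idx // g**2 + 0.5) * box / g
        eng = Engine(s, FF, proto(seed=4, box_z=box, box_xy=box))
        Ts = []
        for _ in range(100):
            for _ in range(100):
                eng.langevin_step()
            Ts.append(eng.kinetic_temperature())
        assert np.mean(Ts[20:]) == pytest.approx(1.1, rel=0.03)

    def test_nve_limit_is_velocity_verlet(self):
        """With thermostat and barostat off, two steps through the engine
        equal a hand-stepped velocity-Verlet on the same system."""
        s = build_bilayer(4, 4, 1.2, 30.0, seed=5)
        p = proto(thermostat_enabled=False, seed=5)
        eng = Engine(s.copy(), FF, p)
        x0 = eng.system.positions.copy()
        v0 = eng.system.velocities.copy()
        f0 = eng.forces.copy()
        eng.langevin_step()
        dt = p.dt
        # manual velocity-Verlet step
        vh = v0 + 0.5 * dt * f0
        x1 = (x0 + dt * vh) % s.box
        ref = s.copy()
        ref.positions = x1.copy()
        _, f1 = total_energy_forces(ref, FF)
        v1 = vh + 0.5 * dt * f1
        assert np.allclose(eng.system.positions, x1, atol=1e-12)
        assert np.allclose(eng.system.velocities, v1, atol=1e-12)

    def test_no_momentum_drift(self):
        s = build_bilayer(6, 6, 1.2, 40.0, seed=6)
        eng = Engine(s, FF, proto(seed=6))
        ps = []
        for _ in range(40):
            for _ in range(50):
                eng.langevin_step()
            ps.append(eng.system.velocities.sum(axis=0))
        mean_p = np.mean(ps, axis=0)
        # noise is zero-mean: the time-averaged momentum stays near zero
        sigma = np.std(ps, axis=0) / np.sqrt(len(ps))
        assert np.all(np.abs(mean_p) < 4 * sigma + 1e-9)


class TestBarostat:
    def test_zero_pressure_is_fixed_point(self):
        s = build_bilayer(6, 6, 1.2, 40.0, seed=7)
        eng = Engine(s, FF, proto(seed=7, barostat_enabled=True),
                     barostat_stochastic=False)
        eng.virial[:] = 0.0
        eng.system.velocities[:] = 0.0
        scale = eng.berendsen_rescale(0.0)
        assert scale == pytest.approx(1.0, abs=1e-12)

    def test_compression_expands_box(self):
        """Positive (compressive) in-plane pressure must expand the box."""
        s = build_bilayer(6, 6, 1.2, 40.0, seed=8)
        eng = Engine(s, FF, proto(seed=8, barostat_enabled=True),
                     barostat_stochastic=False)
        eng.system.velocities[:] = 0.0
        eng.virial[:] = np.array([500.0, 500.0, 0.0])  # compressive
        lx0 = eng.system.box[0]
        scale = eng.berendsen_rescale(0.0)
        assert scale > 1.0
        assert eng.system.box[0] > lx0

    def test_instability_guard(self):
        s = build_bilayer(6, 6, 1.2, 40.0, seed=8)
        eng = Engine(s, FF, proto(seed=8, barostat_enabled=True),
                     barostat_stochastic=False, barostat_max_dlnA=None)
        eng.virial[:] = np.array([1e7, 1e7, 0.0])
        with pytest.raises(InstabilityError):
            eng.berendsen_rescale(0.0)

    def test_ideal_gas_pressure(self):
        """Dilute noninteracting beads: virial pressure equals rho*kB*T
        within 5% when averaged."""
        n, box = 125, 50.0
        g = 5
        idx = np.arange(n)
        pos = np.column_stack([(idx % g + 0.5), (idx // g % g + 0.5),
                               (idx // g**2 + 0.5)]) * box / g
        kinds = np.full(n, int(BeadKind.HEAD), dtype=np.int64)
        rng = np.random.default_rng(9)
        vel = rng.normal(0, np.sqrt(1.1), (n, 3))
        s = ParticleSystem(pos, vel, kinds, np.zeros((0, 3), dtype=np.int64),
                           np.full(n, -1, dtype=np.int64),
                           np.array([box, box, box]))
        eng = Engine(s, FF, proto(seed=9, box_z=box))
        ps = []
        for _ in range(100):
            for _ in range(20):
                eng.langevin_step()
            pxx, pyy, _ = eng.inplane_pressure()
            ps.append((pxx + pyy) / 2)
        rho = n / box**3
        assert np.mean(ps[10:]) == pytest.approx(rho * 1.1, rel=0.05)

    def test_mirror_symmetry(self):
        """Mirroring the configuration leaves P_xx and P_yy unchanged."""
        s = build_bilayer(6, 6, 1.2, 40.0, seed=10)
        eng = Engine(s.copy(), FF, proto(seed=10))
        p1 = eng.inplane_pressure()
        m = s.copy()
        m.positions[:, 0] = (s.box[0] - m.positions[:, 0]) % s.box[0]
        m.velocities[:, 0] *= -1
        eng2 = Engine(m, FF, proto(seed=10))
        p2 = eng2.inplane_pressure()
        assert p1[0] == pytest.approx(p2[0], rel=1e-9)
        assert p1[1] == pytest.approx(p2[1], rel=1e-9)


class TestRobotDrive:
    def _scene(self, freq, static=False):
        geom = SpikyRobotGeometry(core_radius=1.5, n_spikes=4,
                                  spike_length_range=(2.0, 3.0), seed=11)
        p = proto(robot_enabled=True, robot_static=static, cargo_count=0,
                  rotation_frequency=freq, box_z=60.0, seed=11)
        s = assemble_scene(p, geom, nx=10, ny=10)
        eng = Engine(s, FF, p)
        eng.minimize(400)  # resolve builder contact overlaps first
        return eng, s

    def test_static_robot_constant(self):
        eng, s = self._scene(1 / 5000.0, static=True)
        before = s.positions[s.rigid_group.indices].copy()
        for _ in range(25):
            eng.langevin_step()
        assert np.allclose(s.positions[s.rigid_group.indices], before,
                           atol=1e-12)

    def test_full_turn_recovers_reference(self):
        eng, s = self._scene(1 / 5000.0)
        ref = s.positions[s.rigid_group.indices].copy()
        eng.drive_robot(5000.0)  # t = 1/f
        assert np.allclose(s.positions[s.rigid_group.indices], ref,
                           atol=1e-10)

    def test_half_turn_is_rotation_by_pi(self):
        """At t = 2500 tau and f = 1/5000, positions equal the reference
        rotated by pi about the axis (independent rotation-matrix check)."""
        eng, s = self._scene(1 / 5000.0)
        rg = s.rigid_group
        eng.drive_robot(2500.0)
        R = rotation_matrix(np.array([0.0, 0.0, 1.0]), np.pi)
        expected = (rg.center[None, :] + rg.reference @ R.T) % s.box
        assert np.allclose(s.positions[rg.indices], expected, atol=1e-10)

    def test_robot_angle_tracks_time(self):
        eng, s = self._scene(1 / 5000.0)
        for _ in range(50):
            eng.langevin_step()
        t = eng.state.time
        assert eng.state.robot_angle == pytest.approx(2 * np.pi * t / 5000.0)


class TestRunContract:
    def test_zero_steps_single_frame(self):
        s = build_bilayer(5, 5, 1.2, 30.0, seed=12)
        eng = Engine(s, FF, proto(seed=12))
        traj, obs = eng.run(0)
        assert len(traj) == 1
        assert np.allclose(traj.frames[0].positions, s.positions)

    def test_determinism_same_seed(self):
        out = []
        for _ in range(2):
            s = build_bilayer(5, 5, 1.2, 30.0, seed=13)
            eng = Engine(s, FF, proto(seed=13, barostat_enabled=True))
            traj, _ = eng.run(200, frame_interval=100)
            out.append(traj.frames[-1].positions.copy())
        assert np.array_equal(out[0], out[1])

    def test_nve_energy_conservation(self):
        """Thermostat/barostat off on a relaxed patch: relative total
        energy drift below 1e-3 over 10^4 steps at dt = 0.005 tau."""
        s = build_bilayer(5, 5, 1.2, 30.0, seed=14)  # 50 lipids
        # relax first (thermostatted), then measure NVE drift
        p_eq = proto(seed=14, barostat_enabled=True)
        eng = Engine(s, FF, p_eq)
        eng.minimize(300)
        eng.run(5000, frame_interval=10**9)
        s_nve = eng.system.copy()
        p = proto(seed=14, thermostat_enabled=False)
        eng2 = Engine(s_nve, FF, p)
        energies = []
        for _ in range(100):
            for _ in range(100):
                eng2.langevin_step()
            ke = 0.5 * (eng2.system.velocities ** 2).sum()
            energies.append(eng2.potential_energy + ke)
        e = np.asarray(energies)
        drift = abs(e[-1] - e[0]) / abs(e[0])
        assert drift < 1e-3

    def test_overstretch_aborts_with_trajectory(self):
        s = build_bilayer(5, 5, 1.2, 30.0, seed=15)
        # sabotage: give one bead an enormous velocity
        s.velocities[7] = [400.0, 0.0, 0.0]
        eng = Engine(s, FF, proto(seed=15))
        with pytest.raises(InstabilityError) as exc:
            eng.run(1000)
        assert exc.value.trajectory is not None
        assert len(exc.value.trajectory) >= 1

    def test_unwrapped_consistency(self):
        """Image counts reproduce continuous displacements: a bead pushed
        across the boundary keeps its unwrapped trajectory continuous."""
        s = build_bilayer(5, 5, 1.2, 30.0, seed=16)
        eng = Engine(s, FF, proto(seed=16))
        u0 = eng.system.unwrapped.copy()
        for _ in range(500):
            eng.langevin_step()
        du = eng.system.unwrapped - u0
        # no bead can physically travel more than ~a few sigma in 2.5 tau
        assert np.abs(du).max() < 8.0
        assert np.all(eng.system.positions >= 0)
        assert np.all(eng.system.positions <= eng.system.box[None, :])


def test_minimize_reduces_forces():
    geom = SpikyRobotGeometry(core_radius=1.5, n_spikes=4,
                              spike_length_range=(2.0, 3.0), seed=17)
    p = proto(robot_enabled=True, cargo_count=5, box_z=60.0, seed=17)
    s = assemble_scene(p, geom, nx=10, ny=10)
    eng = Engine(s, FF, p)
    f0 = np.linalg.norm(eng.forces[eng.mobile], axis=1).max()
    fmax = eng.minimize(400)
    assert fmax < f0
    assert fmax < 200.0


def test_relaxed_bilayer_stays_connected():
    """5,000 thermostatted+barostatted steps leave every tail bead with
    at least one tail neighbor in attraction range: the membrane stays a
    single cohesive bilayer, nothing evaporates."""
    from scipy.spatial import cKDTree

    s = build_bilayer(6, 6, 1.2, 40.0, seed=21)
    eng = Engine(s, FF, proto(seed=21, barostat_enabled=True))
    eng.minimize(200)
    eng.run(5000, frame_interval=10**9)
    sysm = eng.system
    tails = np.isin(sysm.kinds, (int(BeadKind.TAIL1), int(BeadKind.TAIL2)))
    p = sysm.positions[tails]
    tree = cKDTree(p, boxsize=sysm.box)
    neighbors = tree.query_ball_point(p, FF.rc + FF.wc)
    assert min(len(nb) - 1 for nb in neighbors) >= 1


def test_neighbor_list_maintenance_over_trajectory():
    """After 100 integration steps (several skin-triggered rebuilds) the
    engine's cached forces still equal the all-pairs reference on the
    evolved configuration."""
    s = build_bilayer(5, 5, 1.2, 30.0, seed=22)
    # barostat off: its end-of-step rescale would leave the cached
    # forces one rescale behind the positions by construction
    eng = Engine(s, FF, proto(seed=22), skin=0.3)
    for _ in range(100):
        eng.langevin_step()
    _, f_ref = reference_energy_forces(eng.system, FF)
    scale = max(1.0, np.abs(f_ref).max())
    assert np.abs(eng.forces - f_ref).max() / scale < 1e-9


def test_barostat_area_fluctuations_match_thermodynamics():
    """A dilute WCA gas held at tension -2 eps/sigma^2 must show area
    fluctuations with K_A = kBT<A>/Var(A) equal to its own 2D pressure
    (~2.0-2.3 with the small excluded-volume correction): the barostat's
    stochastic term delivers thermodynamically correct Var(A)."""
    import math
    from nanospin.observables import stretching_modulus

    n, Lz, T = 400, 20.0, 1.1
    L0 = math.sqrt(n * T / 2.0)
    g = int(math.ceil(n ** (1 / 3)))
    idx = np.arange(n)
    pos = np.column_stack([(idx % g + 0.5) * L0 / g,
                           (idx // g % g + 0.5) * L0 / g,
                           (idx // g**2 + 0.5) * Lz / (n // g**2 + 1)])
    rng = np.random.default_rng(7)
    vel = rng.normal(0, math.sqrt(T), (n, 3))
    s = ParticleSystem(pos, vel, np.full(n, int(BeadKind.HEAD),
                                         dtype=np.int64),
                       np.zeros((0, 3), dtype=np.int64),
                       np.full(n, -1, dtype=np.int64),
                       np.array([L0, L0, Lz]))
    eng = Engine(s, FF, proto(seed=7, box_z=Lz))
    areas = []
    for k in range(70000):
        eng.langevin_step()
        eng.berendsen_rescale(-2.0)
        if k % 50 == 0 and k > 15000:
            areas.append(float(s.box[0] * s.box[1]))
    out = stretching_modulus(np.asarray(areas), temperature=T)
    assert 1.6 < out["K_A"] < 2.8, out
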