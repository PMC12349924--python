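"""Time integration: Langevin thermostat, tensionless in-plane barostat,
neighbor management and prescribed rotation of the rigid robot.

Integrator
----------
BAOAB splitting of Langevin dynamics (kick / drift / Ornstein-Uhlenbeck /
drift / kick) with friction ``gamma = 1/tc``.  With the thermostat off the
scheme reduces exactly to velocity Verlet.  Robot beads are excluded from
integration; their positions follow the prescribed rotation angle
``2*pi*f*t`` exactly.

Barostat
--------
The in-plane (membrane-tension) barostat rescales the lateral box and bead
coordinates toward zero in-plane pressure.  The deterministic part is the
classic weak-coupling (Berendsen) relaxation with the compressibility
prefactor folded into the time constant; by default a fluctuation term of
the stochastic-cell-rescaling form is added so that the stationary area
distribution carries correct constant-tension fluctuations (the plain
weak-coupling limit, ``stochastic=False``, damps them artificially, which
would bias any fluctuation-based stretching-modulus estimate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .forcefield import BondOverstretchError, build_pair_table
from .params import ForceFieldParams, ProtocolParams
from .system import ParticleSystem, Trajectory


class EngineError(RuntimeError):
    pass


class InstabilityError(EngineError):
    """Integration became unstable; carries the trajectory so far."""

    def __init__(self, msg: str, trajectory: Trajectory | None = None):
        super().__init__(msg)
        self.trajectory = trajectory


@dataclass
class EngineState:
    system: ParticleSystem
    time: float = 0.0
    step: int = 0
    robot_angle: float = 0.0


@dataclass
class StepObservables:
    """Per-sample scalar series recorded during a run."""

    times: list = field(default_factory=list)
    kinetic_temperature: list = field(default_factory=list)
    potential_energy: list = field(default_factory=list)
    pressure_xx: list = field(default_factory=list)
    pressure_yy: list = field(default_factory=list)
    tension: list = field(default_factory=list)
    box_area: list = field(default_factory=list)
    robot_force: list = field(default_factory=list)  # net force on robot

    def as_dict(self):
        return {k: np.asarray(v) for k, v in self.__dict__.items()}


class Engine:
    """Owns the mutable state of one simulation run."""

    def __init__(
        self,
        system: ParticleSystem,
        forcefield: ForceFieldParams,
        protocol: ProtocolParams,
        skin: float = 0.5,
        barostat_stochastic: bool = True,
        barostat_beta: float = 1.0,
        barostat_stride: int = 1,
        barostat_max_dlnA: float | None = 0.02,
    ):
        self.system = system
        self.ff = forcefield
        self.protocol = protocol
        self.skin = skin
        self.barostat_stochastic = barostat_stochastic
        self.barostat_beta = barostat_beta  # area "compressibility", sigma^2/eps
        self.barostat_stride = barostat_stride
        # response limiter: caps |d ln A| per application so start-up
        # pressure transients relax instead of overshooting
        self.barostat_max_dlnA = barostat_max_dlnA
        self.state = EngineState(system=system)
        self.rng = np.random.default_rng(np.random.PCG64(protocol.seed))

        self.pot_t, self.b_t, self.eps_t, self.cut_t = build_pair_table(forcefield)
        self.mem_mask = system.lipid_mask()
        self.special_idx = np.where(~self.mem_mask)[0].astype(np.int64)
        self.mobile = system.mobile_mask()
        self.n_mobile = int(self.mobile.sum())
        self._mobile_idx = np.where(self.mobile)[0]

        self.axis = np.asarray(protocol.rotation_axis, dtype=float)
        if np.linalg.norm(self.axis) == 0:
            raise EngineError("rotation axis must be non-zero")
        self.axis = self.axis / np.linalg.norm(self.axis)

        system.wrap()
        self._zero_noise = np.zeros_like(system.positions)
        self._nlist = None
        self._max_pairs = max(100_000, 80 * system.n_beads)
        self._build_ref = None
        self.forces = np.zeros_like(system.positions)
        self.potential_energy = 0.0
        self.virial = np.zeros(3)
        self._rebuild_neighbors()
        self._compute_forces()

    # -- neighbor management -------------------------------------------

    def _rebuild_neighbors(self) -> None:
        while True:
            out = _kernels.build_pairs(
                self.system.positions, self.system.kinds, self.system.box,
                self.mem_mask, self.special_idx,
                self.pot_t, self.b_t, self.eps_t, self.cut_t,
                self.skin, self._max_pairs)
            if out[5] >= 0 and out[8] >= 0 and out[12] >= 0:
                break
            self._max_pairs *= 2
        self._nlist = out
        self._build_ref = self.system.positions.copy()
        self._build_box = self.system.box.copy()

    def _maybe_rebuild(self) -> None:
        d2 = _kernels.max_disp2(self.system.positions, self._build_ref,
                                self.system.box)
        if d2 > (0.5 * self.skin) ** 2:
            self._rebuild_neighbors()

    # -- forces ---------------------------------------------------------

    def _compute_forces(self) -> None:
        sysm = self.system
        self.forces[:] = 0.0
        (wi, wj, wb2, weps, wcut2, nw, ci, cj, nc,
         pi_, pj, peps, npn) = self._nlist
        e_pair, wxx, wyy, wzz = _kernels.typed_forces(
            sysm.positions, sysm.box,
            wi, wj, wb2, weps, wcut2, nw, ci, cj, nc, pi_, pj, peps, npn,
            self.ff.rep_shifted, self.ff.b_tail_tail, self.ff.eps_rep,
            self.ff.rc, self.ff.wc, self.ff.b_np, self.ff.rcut_np, True,
            self.forces)
        e_bond, bxx, byy, bzz, bad = _kernels.bond_forces(
            sysm.positions, sysm.box, sysm.bonds, self.ff.k_fene,
            self.ff.r_inf, self.ff.k_bend, self.ff.r0_bend, self.forces)
        if bad >= 0:
            i, j, _ = sysm.bonds[bad]
            d = sysm.positions[i] - sysm.positions[j]
            d -= sysm.box * np.round(d / sysm.box)
            raise BondOverstretchError(int(i), int(j),
                                       float(np.linalg.norm(d)),
                                       self.ff.r_inf, self.state.step)
        self.potential_energy = e_pair + e_bond
        self.virial = np.array([wxx + bxx, wyy + byy, wzz + bzz])

    # -- observables ----------------------------------------------------

    def kinetic_temperature(self) -> float:
        v = self.system.velocities[self.mobile]
        if len(v) == 0:
            return 0.0
        return float((v * v).sum() / (3.0 * len(v)))

    def inplane_pressure(self) -> tuple[float, float, float]:
        """(P_xx, P_yy, tension).  Pressures are 3D virial pressures over
        the full box volume; tension = -(P_xx + P_yy)/2 * box_z, so a
        stretched membrane (negative lateral pressure) has positive
        tension.
        """
        sysm = self.system
        V = float(np.prod(sysm.box))
        v = sysm.velocities[self.mobile]
        kin_x = float((v[:, 0] ** 2).sum())
        kin_y = float((v[:, 1] ** 2).sum())
        pxx = (kin_x + self.virial[0]) / V
        pyy = (kin_y + self.virial[1]) / V
        tension = -(pxx + pyy) / 2.0 * sysm.box[2]
        return pxx, pyy, tension

    # -- barostat -------------------------------------------------------

    def berendsen_rescale(self, target_tension: float = 0.0) -> float:
        """One in-plane rescale toward the target tension; returns the
        linear scale factor applied to x and y."""
        p = self.protocol
        sysm = self.system
        _, _, tension = self.inplane_pressure()
        area = float(sysm.box[0] * sysm.box[1])
        dt_eff = p.dt * self.barostat_stride
        # d ln A: membrane stretched (tension > target) -> shrink the box;
        # compressed (negative tension, positive lateral pressure) -> expand
        deps = -(self.barostat_beta / p.barostat_tc) * (
            tension - target_tension) * dt_eff
        if self.barostat_stochastic:
            amp = math.sqrt(2.0 * p.temperature * self.barostat_beta
                            * dt_eff / (area * p.barostat_tc))
            deps += amp * self.rng.standard_normal()
        if self.barostat_max_dlnA is not None:
            lim = self.barostat_max_dlnA
            deps = min(lim, max(-lim, deps))
        if abs(deps) > 1.0:
            raise InstabilityError(
                f"barostat demanded |d ln A| = {abs(deps):.3g} "
                f"at step {self.state.step}")
        s = math.exp(0.5 * deps)
        if not 0.9 <= s <= 1.1:
            raise InstabilityError(
                f"barostat scale factor {s:.4f} outside [0.9, 1.1] "
                f"at step {self.state.step}")
        sysm.box[0] *= s
        sysm.box[1] *= s
        if sysm.rigid_group is None:
            sysm.positions[:, 0] *= s
            sysm.positions[:, 1] *= s
        else:
            idx = self._mobile_idx
            sysm.positions[idx, 0] *= s
            sysm.positions[idx, 1] *= s
        return s

    # -- robot kinematics -----------------------------------------------

    def drive_robot(self, time: float) -> None:
        """Place robot beads at the prescribed angle for *time*."""
        rg = self.system.rigid_group
        if rg is None:
            return
        f = 0.0 if self.protocol.robot_static else self.protocol.rotation_frequency
        angle = 2.0 * math.pi * f * time
        self.state.robot_angle = angle
        newpos = rg.positions_at(angle, self.axis)
        self.system.positions[rg.indices] = newpos % self.system.box[None, :]
        self.system.velocities[rg.indices] = 0.0

    # -- relaxation ------------------------------------------------------

    def minimize(self, n_steps: int = 300, dmax: float = 0.05,
                 f_tol: float = 10.0) -> float:
        """Displacement-capped steepest descent on the mobile beads.

        Removes builder overlaps (notably between the freshly placed
        robot/cargo and the membrane) before dynamics; the cap keeps FENE
        bonds inside their domain no matter how large the initial forces
        are.  Returns the final maximum force magnitude.
        """
        sysm = self.system
        mob = self.mobile
        fmax = np.inf
        for _ in range(n_steps):
            f = self.forces[mob]
            fmag = np.linalg.norm(f, axis=1)
            fmax = float(fmag.max()) if len(fmag) else 0.0
            if fmax < f_tol:
                break
            # move along the force, displacement capped at dmax per bead
            step = f / np.maximum(fmag, 1e-12)[:, None] * np.minimum(
                fmag * 1e-3, dmax)[:, None]
            sysm.positions[mob] += step
            sysm.wrap()
            self._maybe_rebuild()
            self._compute_forces()
        return fmax

    # -- integration ----------------------------------------------------

    def langevin_step(self) -> None:
        """One BAOAB step (robot driven kinematically, then new forces).

        All beads go through the integrator kernel; the robot beads are
        then overwritten by their prescribed kinematics, so integrating
        them costs nothing and keeps the hot path free of index gathers.
        """
        p = self.protocol
        sysm = self.system
        dt = p.dt
        if p.thermostat_enabled:
            c1 = math.exp(-dt / p.thermostat_tc)
            c2 = math.sqrt(p.temperature * (1.0 - c1 * c1))
            noise = self.rng.standard_normal(sysm.positions.shape)
        else:
            c1 = 1.0
            c2 = 0.0
            noise = self._zero_noise
        _kernels.baoab_pre(sysm.positions, sysm.velocities, self.forces,
                           sysm.images, sysm.box, dt, c1, c2, noise,
                           p.thermostat_enabled)
        self.state.step += 1
        self.state.time += dt
        self.drive_robot(self.state.time)
        self._maybe_rebuild()
        self._compute_forces()
        _kernels.kick(sysm.velocities, self.forces, dt)
        if sysm.rigid_group is not None:
            sysm.velocities[sysm.rigid_group.indices] = 0.0

        if p.barostat_enabled and self.state.step % self.barostat_stride == 0:
            self.berendsen_rescale(0.0)

    def robot_net_force(self) -> np.ndarray:
        rg = self.system.rigid_group
        if rg is None:
            return np.zeros(3)
        return self.forces[rg.indices].sum(axis=0)

    # -- top-level run --------------------------------------------------

    def run(
        self,
        n_steps: int | None = None,
        frame_interval: int | None = None,
        sample_interval: int = 50,
        trajectory: Trajectory | None = None,
        observables: StepObservables | None = None,
    ) -> tuple[Trajectory, StepObservables]:
        """Integrate *n_steps*, recording frames and scalar series.

        On an instability the exception carries everything recorded up to
        the last good step.
        """
        p = self.protocol
        if n_steps is None:
            n_steps = p.n_steps
        if frame_interval is None:
            frame_interval = p.frame_interval
        traj = trajectory if trajectory is not None else Trajectory()
        obs = observables if observables is not None else StepObservables()
        if not traj.frames:
            traj.metadata.update({
                "seed": p.seed, "dt": p.dt,
                "rotation_frequency": p.rotation_frequency,
                "robot_static": p.robot_static,
            })
            traj.append_state(self.system, self.state.time, self.state.step)
        try:
            for k in range(n_steps):
                self.langevin_step()
                if self.state.step % sample_interval == 0:
                    self._sample(obs)
                if self.state.step % frame_interval == 0:
                    traj.append_state(self.system, self.state.time,
                                      self.state.step)
        except (BondOverstretchError, InstabilityError) as err:
            traj.append_state(self.system, self.state.time, self.state.step)
            raise InstabilityError(
                f"run aborted at step {self.state.step}: {err}", traj
            ) from err
        return traj, obs

    def _sample(self, obs: StepObservables) -> None:
        pxx, pyy, tension = self.inplane_pressure()
        obs.times.append(self.state.time)
        obs.kinetic_temperature.append(self.kinetic_temperature())
        obs.potential_energy.append(self.potential_energy)
        obs.pressure_xx.append(pxx)
        obs.pressure_yy.append(pyy)
        obs.tension.append(tension)
        obs.box_area.append(float(self.system.box[0] * self.system.box[1]))
        obs.robot_force.append(self.robot_net_force().tolist())


def total_energy_forces(system: ParticleSystem, params: ForceFieldParams,
                        skin: float = 0.4):
    """Cell-list total potential energy and per-bead forces (production
    path; the brute-force oracle lives in :mod:`nanospin.forcefield`)."""
    from .params import ProtocolParams

    proto = ProtocolParams(n_steps=0, box_xy=float(system.box[0]),
                           box_z=float(system.box[2]),
                           barostat_enabled=False)
    eng = Engine(system.copy(), params, proto, skin=skin)
    return eng.potential_energy, eng.forces.copy()
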