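"""Particle containers, periodic wrapping, and extended-XYZ trajectory I/O."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .forcefield import BeadKind

_KIND_NAMES = {k: k.name for k in BeadKind}
_KIND_FROM_NAME = {k.name: int(k) for k in BeadKind}


class FormatError(ValueError):
    """Malformed trajectory/system file."""


@dataclass
class RigidGroup:
    """A bead set moved as one rigid unit by prescribed kinematics."""

    indices: np.ndarray          # bead indices belonging to the body
    reference: np.ndarray        # (n, 3) positions relative to the center
    center: np.ndarray           # (3,) body center in the box

    def positions_at(self, angle: float, axis: np.ndarray) -> np.ndarray:
        """Body bead positions after rotating by *angle* about *axis*."""
        R = rotation_matrix(axis, angle)
        return self.center[None, :] + self.reference @ R.T


def rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (normalized) axis."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("rotation axis must be non-zero")
    ux, uy, uz = axis / n
    c, s = np.cos(angle), np.sin(angle)
    K = np.array([[0, -uz, uy], [uz, 0, -ux], [-uy, ux, 0]])
    return np.eye(3) * c + s * K + (1 - c) * np.outer([ux, uy, uz], [ux, uy, uz])


@dataclass
class ParticleSystem:
    """Beads in a periodic box.

    ``bonds`` rows are ``(i, j, bond_type)`` with type 0 = FENE,
    1 = head-tail2 straightening spring.  ``images`` counts boundary
    crossings per bead/axis so unwrapped coordinates are recoverable.
    """

    positions: np.ndarray                  # (N, 3) sigma, wrapped
    velocities: np.ndarray                 # (N, 3) sigma/tau
    kinds: np.ndarray                      # (N,) BeadKind ints
    bonds: np.ndarray                      # (M, 3) ints
    molecule_id: np.ndarray                # (N,) ints, -1 = not a lipid
    box: np.ndarray                        # (3,) sigma
    rigid_group: RigidGroup | None = None
    images: np.ndarray = field(default=None)  # (N, 3) ints

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.kinds = np.ascontiguousarray(self.kinds, dtype=np.int64)
        self.bonds = (np.asarray(self.bonds, dtype=np.int64).reshape(-1, 3)
                      if len(self.bonds) else np.zeros((0, 3), dtype=np.int64))
        self.molecule_id = np.ascontiguousarray(self.molecule_id, dtype=np.int64)
        self.box = np.asarray(self.box, dtype=np.float64)
        if self.images is None:
            self.images = np.zeros((len(self.positions), 3), dtype=np.int64)

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def unwrapped(self) -> np.ndarray:
        return self.positions + self.images * self.box[None, :]

    def wrap(self) -> None:
        """Wrap positions into [0, box) updating image counts."""
        shift = np.floor(self.positions / self.box[None, :]).astype(np.int64)
        self.positions -= shift * self.box[None, :]
        self.images += shift

    def lipid_mask(self) -> np.ndarray:
        k = self.kinds
        return ((k == BeadKind.HEAD) | (k == BeadKind.TAIL1)
                | (k == BeadKind.TAIL2) | (k == BeadKind.RECEPTOR_HEAD))

    def robot_mask(self) -> np.ndarray:
        return (self.kinds == BeadKind.ROBOT_CORE) | (
            self.kinds == BeadKind.ROBOT_SPIKE)

    def mobile_mask(self) -> np.ndarray:
        """Beads integrated by the thermostat (everything but the robot)."""
        return ~self.robot_mask()

    def validate(self) -> None:
        """Check container invariants; raises on violation."""
        n = self.n_beads
        if self.velocities.shape != (n, 3) or self.kinds.shape != (n,):
            raise FormatError("inconsistent array shapes")
        if np.any(self.positions < -1e-9) or np.any(
                self.positions > self.box[None, :] + 1e-9):
            raise FormatError("positions outside the periodic box")
        if len(self.bonds):
            if self.bonds[:, :2].min() < 0 or self.bonds[:, :2].max() >= n:
                raise FormatError("bond index out of range")
            if self.rigid_group is not None:
                fene = self.bonds[self.bonds[:, 2] == 0][:, :2]
                if np.isin(fene, self.rigid_group.indices).any():
                    raise FormatError("rigid-body bead appears in a FENE bond")
        for mol in np.unique(self.molecule_id[self.molecule_id >= 0]):
            idx = np.where(self.molecule_id == mol)[0]
            if len(idx) != 3:
                raise FormatError(f"lipid {mol} does not have 3 beads")

    def copy(self) -> "ParticleSystem":
        rg = None
        if self.rigid_group is not None:
            rg = RigidGroup(self.rigid_group.indices.copy(),
                            self.rigid_group.reference.copy(),
                            self.rigid_group.center.copy())
        return ParticleSystem(self.positions.copy(), self.velocities.copy(),
                              self.kinds.copy(), self.bonds.copy(),
                              self.molecule_id.copy(), self.box.copy(),
                              rg, self.images.copy())


@dataclass
class Frame:
    time: float
    step: int
    box: np.ndarray
    positions: np.ndarray
    unwrapped: np.ndarray
    kinds: np.ndarray
    molecule_id: np.ndarray


@dataclass
class Trajectory:
    """Time-ordered frames with box history and run metadata."""

    frames: list[Frame] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def box_areas(self) -> np.ndarray:
        return np.array([f.box[0] * f.box[1] for f in self.frames])

    def append_state(self, system: ParticleSystem, time: float, step: int):
        self.frames.append(Frame(
            time=time, step=step, box=system.box.copy(),
            positions=system.positions.copy(),
            unwrapped=system.unwrapped,
            kinds=system.kinds.copy(),
            molecule_id=system.molecule_id.copy()))


# ---------------------------------------------------------------------------
# extended-XYZ I/O (columns: kind, x, y, z, molecule_id; 6 decimals in sigma)
# ---------------------------------------------------------------------------

def write_xyz_frame(fh, kinds, positions, molecule_id, box, time, step):
    fh.write(f"{len(positions)}\n")
    fh.write(
        f'step={step} time={time:.6f} '
        f'box="{box[0]:.6f} {box[1]:.6f} {box[2]:.6f}" '
        f'Properties=species:S:1:pos:R:3:mol:I:1\n')
    for k, p, m in zip(kinds, positions, molecule_id):
        name = _KIND_NAMES[BeadKind(int(k))]
        fh.write(f"{name} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {int(m)}\n")


def write_trajectory_xyz(traj: Trajectory, path: str | Path) -> None:
    with open(path, "w") as fh:
        for fr in traj.frames:
            write_xyz_frame(fh, fr.kinds, fr.positions, fr.molecule_id,
                            fr.box, fr.time, fr.step)


def write_system_xyz(system: ParticleSystem, path: str | Path,
                     time: float = 0.0, step: int = 0) -> None:
    with open(path, "w") as fh:
        write_xyz_frame(fh, system.kinds, system.positions,
                        system.molecule_id, system.box, time, step)


def _parse_comment(line: str, lineno: int) -> dict:
    meta = {}
    rest = line.strip()
    while rest:
        if "=" not in rest:
            break
        key, rest = rest.split("=", 1)
        key = key.strip()
        if rest.startswith('"'):
            end = rest.index('"', 1)
            val, rest = rest[1:end], rest[end + 1:]
        else:
            parts = rest.split(None, 1)
            val = parts[0]
            rest = parts[1] if len(parts) > 1 else ""
        meta[key] = val
        rest = rest.strip()
    if "box" not in meta:
        raise FormatError(f"line {lineno}: comment line lacks box=...")
    return meta


def read_trajectory_xyz(path: str | Path) -> Trajectory:
    """Read an extended-XYZ trajectory written by this package."""
    traj = Trajectory()
    lines = Path(path).read_text().splitlines()
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise FormatError(f"line {i + 1}: expected atom count") from None
        if i + 1 >= len(lines):
            raise FormatError(f"frame {frame_no}: missing comment line")
        meta = _parse_comment(lines[i + 1], i + 2)
        box = np.array([float(x) for x in meta["box"].split()])
        time = float(meta.get("time", 0.0))
        step = int(meta.get("step", 0))
        kinds = np.empty(n, dtype=np.int64)
        mol = np.empty(n, dtype=np.int64)
        pos = np.empty((n, 3))
        for a in range(n):
            ln = i + 2 + a
            if ln >= len(lines):
                raise FormatError(f"frame {frame_no} truncated at line {ln}")
            parts = lines[ln].split()
            if len(parts) != 5:
                raise FormatError(
                    f"line {ln + 1}: expected 5 columns, got {len(parts)}")
            try:
                kinds[a] = _KIND_FROM_NAME[parts[0]]
            except KeyError:
                raise FormatError(
                    f"line {ln + 1}: unknown bead kind {parts[0]!r}") from None
            pos[a] = [float(parts[1]), float(parts[2]), float(parts[3])]
            mol[a] = int(parts[4])
        traj.frames.append(Frame(time=time, step=step, box=box,
                                 positions=pos, unwrapped=pos.copy(),
                                 kinds=kinds, molecule_id=mol))
        i += 2 + n
        frame_no += 1
    return traj


def read_system_xyz(path: str | Path, sidecar: str | Path | None = None
                    ) -> ParticleSystem:
    """Load the first frame of an XYZ file as a system.

    A JSON sidecar (written by :func:`write_system_bundle`) restores
    bonds, velocities and the rigid group.
    """
    traj = read_trajectory_xyz(path)
    if not traj.frames:
        raise FormatError(f"{path}: no frames")
    fr = traj.frames[0]
    n = len(fr.positions)
    vel = np.zeros((n, 3))
    bonds = np.zeros((0, 3), dtype=np.int64)
    rigid = None
    if sidecar is not None:
        meta = json.loads(Path(sidecar).read_text())
        bonds = np.asarray(meta["bonds"], dtype=np.int64).reshape(-1, 3)
        vel = np.asarray(meta["velocities"], dtype=float).reshape(n, 3)
        if meta.get("rigid_group"):
            rg = meta["rigid_group"]
            rigid = RigidGroup(np.asarray(rg["indices"], dtype=np.int64),
                               np.asarray(rg["reference"], dtype=float),
                               np.asarray(rg["center"], dtype=float))
    return ParticleSystem(fr.positions, vel, fr.kinds, bonds,
                          fr.molecule_id, fr.box, rigid)


def write_system_bundle(system: ParticleSystem, xyz_path: str | Path,
                        sidecar_path: str | Path) -> None:
    """Write a system as XYZ plus a JSON sidecar with topology metadata."""
    write_system_xyz(system, xyz_path)
    meta = {
        "box": system.box.tolist(),
        "bonds": system.bonds.tolist(),
        "velocities": np.round(system.velocities, 9).tolist(),
        "rigid_group": None,
    }
    if system.rigid_group is not None:
        meta["rigid_group"] = {
            "indices": system.rigid_group.indices.tolist(),
            "reference": system.rigid_group.reference.tolist(),
            "center": system.rigid_group.center.tolist(),
        }
    Path(sidecar_path).write_text(json.dumps(meta))
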