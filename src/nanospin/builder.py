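"""Initial-condition builders: planar bilayer, rigid spiky robot, cargo.

Everything is generated in-package and deterministic given a seed.  The
robot morphology follows the measured particle geometry: spikes with
apex (tip) angles of 5-20 degrees distributed roughly uniformly over the
core sphere; spike lengths are configurable and default to a membrane-
commensurate 10-20 sigma (a literal several-hundred-nanometre robot would
dwarf the simulated membrane patch).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .forcefield import BeadKind
from .params import ProtocolParams
from .system import ParticleSystem, RigidGroup


class BuildError(ValueError):
    pass


BUILDER_KEYS = {
    "nx", "ny", "area_per_lipid", "core_radius", "n_spikes",
    "spike_length_min", "spike_length_max", "apex_angle_min",
    "apex_angle_max", "bead_spacing", "robot_clearance",
}


@dataclass
class SpikyRobotGeometry:
    """Rigid robot morphology: spherical core shell plus tapered spikes."""

    core_radius: float = 5.0
    n_spikes: int = 12
    spike_length_range: tuple[float, float] = (10.0, 20.0)
    apex_angle_range: tuple[float, float] = (5.0, 20.0)  # degrees
    bead_spacing: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bead_spacing > 1.0 + 1e-12:
            raise BuildError("bead_spacing must be <= 1 sigma for a "
                             "contiguous surface")
        if self.core_radius < self.bead_spacing:
            raise BuildError("core_radius must be at least bead_spacing")
        lo, hi = self.spike_length_range
        if not (0 < lo <= hi):
            raise BuildError("invalid spike_length_range")
        alo, ahi = self.apex_angle_range
        if not (0 < alo <= ahi):
            raise BuildError("invalid apex_angle_range")

    @property
    def max_extent(self) -> float:
        return self.core_radius + self.spike_length_range[1]


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def maxwell_boltzmann_velocities(n: int, temperature: float,
                                 rng: np.random.Generator) -> np.ndarray:
    """Zero-net-momentum Maxwell-Boltzmann draw at unit mass."""
    v = rng.normal(0.0, math.sqrt(temperature), size=(n, 3))
    if n > 0:
        v -= v.mean(axis=0, keepdims=True)
    return v


def build_bilayer(nx: int, ny: int, area_per_lipid: float, box_z: float,
                  seed: int, temperature: float = 1.1,
                  jitter: float = 0.05,
                  undulation_spectrum: tuple[float, float] | None = None
                  ) -> ParticleSystem:
    """Planar two-leaflet bilayer of ``nx*ny`` lipids per leaflet.

    Lipids sit on a square lattice with spacing ``sqrt(area_per_lipid)``,
    tails inward, midplane at ``z = box_z/2``.  Velocities are
    Maxwell-Boltzmann at *temperature* with zero net momentum.

    ``undulation_spectrum = (kappa0, sigma0)`` pre-seeds the membrane
    height with a thermal draw from the tension + bending spectrum
    ``kBT/(A (sigma0 q^2 + kappa0 q^4))``.  The slowest height modes
    relax over hundreds of tau from a flat start; seeding them near
    their equilibrium amplitude shortens equilibration without touching
    any measured statistics (it is an initial condition, the guess only
    affects the equilibration time).
    """
    if nx < 4 or ny < 4:
        raise BuildError("need at least 4x4 lipids per leaflet")
    if not 1.0 <= area_per_lipid <= 2.0:
        raise BuildError("area_per_lipid outside the sensible [1, 2] range")
    rng = np.random.default_rng(np.random.PCG64(seed))
    a = math.sqrt(area_per_lipid)
    Lx, Ly = nx * a, ny * a
    zmid = box_z / 2.0
    hfield = np.zeros((nx, ny))
    if undulation_spectrum is not None:
        kappa0, sigma0 = undulation_spectrum
        A = Lx * Ly
        kxs = np.fft.fftfreq(nx) * nx * 2 * math.pi / Lx
        kys = np.fft.fftfreq(ny) * ny * 2 * math.pi / Ly
        QX, QY = np.meshgrid(kxs, kys, indexing="ij")
        q2 = QX**2 + QY**2
        var = np.zeros_like(q2)
        nz = q2 > 1e-12
        var[nz] = temperature / (A * (sigma0 * q2[nz]
                                      + kappa0 * q2[nz] ** 2))
        white = rng.standard_normal((nx, ny))
        hfield = np.fft.ifft2(np.fft.fft2(white)
                              * np.sqrt(var)).real * math.sqrt(nx * ny)
    n_lipids = 2 * nx * ny
    n = 3 * n_lipids
    pos = np.empty((n, 3))
    kinds = np.empty(n, dtype=np.int64)
    mol = np.empty(n, dtype=np.int64)
    bonds = []
    # bead z-offsets from midplane, top leaflet: head out at +2.5, tails in
    spacing = 0.97  # near the FENE+WCA bond minimum
    offs_top = np.array([0.5 + 2 * spacing, 0.5 + spacing, 0.5])
    b = 0
    m = 0
    for leaflet, sign in ((0, +1.0), (1, -1.0)):
        # half-cell offset between leaflets avoids tail registry
        shift = 0.5 * a if leaflet else 0.0
        for ix in range(nx):
            for iy in range(ny):
                x = (ix + 0.5) * a + shift
                y = (iy + 0.5) * a + shift
                jx, jy = rng.uniform(-jitter, jitter, size=2)
                h = hfield[ix, iy]
                for k, (kind, dz) in enumerate(
                        zip((BeadKind.HEAD, BeadKind.TAIL1, BeadKind.TAIL2),
                            offs_top)):
                    pos[b + k] = (x + jx, y + jy, zmid + h + sign * dz)
                    kinds[b + k] = int(kind)
                    mol[b + k] = m
                bonds.append((b, b + 1, 0))
                bonds.append((b + 1, b + 2, 0))
                bonds.append((b, b + 2, 1))
                b += 3
                m += 1
    vel = maxwell_boltzmann_velocities(n, temperature, rng)
    sysm = ParticleSystem(pos, vel, kinds, np.array(bonds, dtype=np.int64),
                         mol, np.array([Lx, Ly, box_z]))
    sysm.wrap()
    _check_min_distance(sysm, 0.8)
    return sysm


def _check_min_distance(system: ParticleSystem, dmin: float) -> None:
    """Builder overlap guard: same-kind-agnostic minimum distance among
    beads of different molecules (cheap grid check)."""
    from scipy.spatial import cKDTree

    pos = system.positions
    tree = cKDTree(pos, boxsize=system.box)
    pairs = tree.query_pairs(dmin, output_type="ndarray")
    if len(pairs):
        same_mol = (system.molecule_id[pairs[:, 0]]
                    == system.molecule_id[pairs[:, 1]])
        both_lipid = (system.molecule_id[pairs[:, 0]] >= 0)
        bad = pairs[~(same_mol & both_lipid)]
        if len(bad):
            i, j = bad[0]
            raise BuildError(
                f"overlapping placement: beads {i} and {j} closer "
                f"than {dmin} sigma")


def build_spiky_robot(geometry: SpikyRobotGeometry) -> np.ndarray:
    """Bead positions of the rigid robot, relative to its center.

    The core is a spherical shell of beads at ``core_radius``; each spike
    is a sequence of rings along an outward axis whose radius tapers
    linearly to the tip according to the sampled apex angle.
    Deterministic given ``geometry.seed``.

    Returns ``(positions, kinds)``.
    """
    g = geometry
    rng = np.random.default_rng(np.random.PCG64(g.seed))
    pts = []
    kinds = []
    # core shell with ~bead_spacing^2 area per bead
    n_core = max(1, int(round(4.0 * math.pi * g.core_radius**2
                              / g.bead_spacing**2)))
    core = _fibonacci_sphere(n_core) * g.core_radius
    pts.extend(core)
    kinds.extend([int(BeadKind.ROBOT_CORE)] * len(core))

    if g.n_spikes > 0:
        dirs = _fibonacci_sphere(g.n_spikes)
        # random global rotation so spike directions vary with seed
        from .system import rotation_matrix

        ax = rng.normal(size=3)
        ax /= np.linalg.norm(ax)
        R = rotation_matrix(ax, rng.uniform(0, 2 * math.pi))
        dirs = dirs @ R.T
        lengths = rng.uniform(*g.spike_length_range, size=g.n_spikes)
        apexes = np.deg2rad(rng.uniform(*g.apex_angle_range, size=g.n_spikes))
        for d, L, alpha in zip(dirs, lengths, apexes):
            n_seg = max(2, int(math.ceil(L / g.bead_spacing)))
            tanh = math.tan(alpha / 2.0)
            u = _perpendicular(d)
            w = np.cross(d, u)
            for si in range(n_seg + 1):
                s = L * si / n_seg
                center = d * (g.core_radius + s)
                rho = (L - s) * tanh
                n_ring = max(1, int(round(2 * math.pi * rho / g.bead_spacing)))
                if rho < 0.25 * g.bead_spacing:
                    n_ring = 1
                if n_ring == 1:
                    pts.append(center)
                    kinds.append(int(BeadKind.ROBOT_SPIKE))
                else:
                    for q in range(n_ring):
                        th = 2 * math.pi * q / n_ring
                        pts.append(center + rho * (math.cos(th) * u
                                                   + math.sin(th) * w))
                        kinds.append(int(BeadKind.ROBOT_SPIKE))
    return np.asarray(pts), np.asarray(kinds, dtype=np.int64)


def _perpendicular(d: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(d, ref)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    u = np.cross(d, ref)
    return u / np.linalg.norm(u)


def add_cargo(system: ParticleSystem, n: int, diameter: float,
              z_range: tuple[float, float], seed: int,
              temperature: float = 1.1, max_tries: int = 2000
              ) -> ParticleSystem:
    """Add *n* cargo beads uniformly in the slab ``z_range`` (cis side),
    no two closer than *diameter* and none within *diameter* of existing
    beads."""
    if n == 0:
        return system
    zlo, zhi = z_range
    if zhi <= zlo:
        raise BuildError("empty cargo z-range")
    rng = np.random.default_rng(np.random.PCG64(seed))
    from scipy.spatial import cKDTree

    existing = system.positions
    tree = cKDTree(existing, boxsize=system.box) if len(existing) else None
    placed: list[np.ndarray] = []
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > max_tries * n:
            raise BuildError(
                f"could not place {n} cargo beads after {tries} tries; "
                "region too small")
        p = np.array([rng.uniform(0, system.box[0]),
                      rng.uniform(0, system.box[1]),
                      rng.uniform(zlo, zhi)])
        if tree is not None and tree.query_ball_point(
                p % system.box, diameter).__len__() > 0:
            continue
        ok = True
        for q in placed:
            d = p - q
            d -= system.box * np.round(d / system.box)
            if np.dot(d, d) < diameter * diameter:
                ok = False
                break
        if ok:
            placed.append(p)
    npos = np.vstack([existing, placed])
    nvel = np.vstack([system.velocities,
                      maxwell_boltzmann_velocities(n, temperature, rng)])
    nkinds = np.concatenate([system.kinds,
                             np.full(n, int(BeadKind.CARGO), dtype=np.int64)])
    nmol = np.concatenate([system.molecule_id, np.full(n, -1, dtype=np.int64)])
    out = ParticleSystem(npos, nvel, nkinds, system.bonds, nmol,
                         system.box.copy(), system.rigid_group)
    out.wrap()
    return out


def _evict_overlapping_lipids(system: ParticleSystem, robot_pos: np.ndarray,
                              r_evict: float) -> ParticleSystem:
    """Drop whole lipids having any bead within *r_evict* of a robot bead
    (minimum-image); bonds and molecule ids are re-indexed."""
    from scipy.spatial import cKDTree

    tree = cKDTree(robot_pos % system.box, boxsize=system.box)
    close = tree.query_ball_point(system.positions, r_evict)
    bad_beads = np.array([len(c) > 0 for c in close])
    bad_mols = np.unique(system.molecule_id[bad_beads
                                            & (system.molecule_id >= 0)])
    if len(bad_mols) == 0:
        return system
    keep = ~np.isin(system.molecule_id, bad_mols)
    new_index = np.cumsum(keep) - 1
    bonds = system.bonds[keep[system.bonds[:, 0]]
                         & keep[system.bonds[:, 1]]].copy()
    bonds[:, 0] = new_index[bonds[:, 0]]
    bonds[:, 1] = new_index[bonds[:, 1]]
    return ParticleSystem(system.positions[keep], system.velocities[keep],
                          system.kinds[keep], bonds,
                          system.molecule_id[keep], system.box.copy(),
                          system.rigid_group)


def upper_head_plane(system: ParticleSystem) -> float:
    """Mean z of the upper-leaflet head beads."""
    from .forcefield import HEAD_KINDS

    heads = np.isin(system.kinds, [int(k) for k in HEAD_KINDS])
    z = system.positions[heads][:, 2]
    zmid = float(np.median(system.positions[system.lipid_mask()][:, 2]))
    upper = z[z > zmid]
    if len(upper) == 0:
        raise BuildError("no upper-leaflet heads found")
    return float(upper.mean())


def assemble_scene(protocol: ProtocolParams,
                   geometry: SpikyRobotGeometry | None = None,
                   nx: int = 20, ny: int = 20,
                   area_per_lipid: float = 1.2,
                   robot_clearance: float = 1.0,
                   cargo_gap: float = 2.0) -> ParticleSystem:
    """Bilayer + (optional) robot + cargo, the full simulation scene.

    The robot is centered laterally, its lowest spike tip
    ``robot_clearance`` sigma above the upper head plane; a
    ``protocol.receptor_fraction`` of upper-leaflet heads becomes
    receptors.  Cargo goes on the cis (robot) side above the membrane.
    """
    sysm = build_bilayer(nx, ny, area_per_lipid, protocol.box_z,
                        protocol.seed, protocol.temperature)
    head_plane = upper_head_plane(sysm)

    if protocol.robot_enabled:
        if geometry is None:
            geometry = SpikyRobotGeometry(seed=protocol.seed)
        if 2 * geometry.max_extent > min(sysm.box[0], sysm.box[1]):
            raise BuildError(
                f"robot extent {geometry.max_extent:.1f} sigma does not fit "
                f"the {sysm.box[0]:.1f}-sigma box")
        rpos, rkinds = build_spiky_robot(geometry)
        zlow = rpos[:, 2].min()
        center = np.array([sysm.box[0] / 2.0, sysm.box[1] / 2.0,
                           head_plane + robot_clearance - zlow])
        # an embedded start (negative clearance: the post-attachment
        # state) displaces the lipids the robot volume excludes; remove
        # molecules that would sit inside the steric core, the remainder
        # relaxes against the surface during minimization
        sysm = _evict_overlapping_lipids(sysm, center[None, :] + rpos,
                                        r_evict=1.6)
        n0 = sysm.n_beads
        npos = np.vstack([sysm.positions, center[None, :] + rpos])
        nvel = np.vstack([sysm.velocities, np.zeros_like(rpos)])
        nkinds = np.concatenate([sysm.kinds, rkinds])
        nmol = np.concatenate([sysm.molecule_id,
                               np.full(len(rpos), -1, dtype=np.int64)])
        rigid = RigidGroup(indices=np.arange(n0, n0 + len(rpos)),
                           reference=rpos.copy(), center=center)
        sysm = ParticleSystem(npos, nvel, nkinds, sysm.bonds, nmol,
                             sysm.box.copy(), rigid)
        sysm.wrap()

    # receptors on the upper leaflet
    if protocol.receptor_fraction > 0:
        rng = np.random.default_rng(np.random.PCG64(protocol.seed + 7))
        zmid = protocol.box_z / 2.0
        upper_heads = np.where((sysm.kinds == int(BeadKind.HEAD))
                               & (sysm.positions[:, 2] > zmid))[0]
        n_rec = int(round(protocol.receptor_fraction * len(upper_heads)))
        chosen = rng.choice(upper_heads, size=n_rec, replace=False)
        sysm.kinds[chosen] = int(BeadKind.RECEPTOR_HEAD)

    if protocol.cargo_count > 0:
        ztop = sysm.positions[:, 2].max() if protocol.robot_enabled else \
            head_plane
        zlo = head_plane + cargo_gap
        zhi = min(float(sysm.box[2]) - 1.0, max(zlo + 4.0, ztop + 8.0))
        sysm = add_cargo(sysm, protocol.cargo_count, protocol.cargo_diameter,
                        (zlo, zhi), protocol.seed + 13, protocol.temperature)
    sysm.validate()
    return sysm


def scene_from_config(cfg) -> ParticleSystem:
    """Build the scene described by a :class:`RunConfig`."""
    b = dict(cfg.builder)
    geom = None
    if cfg.protocol.robot_enabled:
        geom = SpikyRobotGeometry(
            core_radius=b.get("core_radius", 5.0),
            n_spikes=b.get("n_spikes", 12),
            spike_length_range=(b.get("spike_length_min", 10.0),
                                b.get("spike_length_max", 20.0)),
            apex_angle_range=(b.get("apex_angle_min", 5.0),
                              b.get("apex_angle_max", 20.0)),
            bead_spacing=b.get("bead_spacing", 1.0),
            seed=cfg.protocol.seed)
    return assemble_scene(
        cfg.protocol, geom,
        nx=b.get("nx", 20), ny=b.get("ny", 20),
        area_per_lipid=b.get("area_per_lipid", 1.2),
        robot_clearance=b.get("robot_clearance", 1.0))
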