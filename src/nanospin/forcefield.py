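"""Pair and bonded interactions of the three-bead lipid / nanoparticle model.

Interactions, all in reduced units:

* ``u_rep`` — Weeks-Chandler-Andersen core setting bead size.  The default
  variant carries the +eps shift making the energy vanish continuously at
  the cutoff ``2^(1/6) b``; the unshifted variant (selectable) reproduces
  the bare truncated 12-6 form, which is discontinuous by ``-eps_rep`` at
  the cutoff.
* ``u_cos`` — tail-tail cosine-squared attraction modelling the hydrophobic
  effect of the missing solvent: a flat ``-eps`` plateau for ``r < rc``
  tapering smoothly to zero over a width ``wc``.
* ``u_fene`` — finitely extensible bond between consecutive lipid beads;
  diverges at ``r_inf`` so chains cannot cross.
* ``u_bend`` — harmonic head-to-second-tail spring with 4 sigma rest
  length; since two bonds can never stretch to 4 sigma it is always taut
  and straightens the lipid.
* ``u_np`` — truncated (and shifted, by default) 12-6 attraction between
  nanoparticle beads and lipid beads, modelling an adhesive coating.

Scalar functions here are the readable reference; the cell-list production
path lives in :mod:`nanospin._kernels` and is tested against this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .params import ForceFieldParams


class BeadKind(IntEnum):
    HEAD = 0
    TAIL1 = 1
    TAIL2 = 2
    CARGO = 3
    ROBOT_CORE = 4
    ROBOT_SPIKE = 5
    RECEPTOR_HEAD = 6


N_KINDS = len(BeadKind)

#: membrane (lipid) kinds; RECEPTOR_HEAD behaves as HEAD for Eqs. of the
#: lipid model and additionally feels the adhesion toward spike beads
LIPID_KINDS = (BeadKind.HEAD, BeadKind.TAIL1, BeadKind.TAIL2, BeadKind.RECEPTOR_HEAD)
TAIL_KINDS = (BeadKind.TAIL1, BeadKind.TAIL2)
HEAD_KINDS = (BeadKind.HEAD, BeadKind.RECEPTOR_HEAD)
ROBOT_KINDS = (BeadKind.ROBOT_CORE, BeadKind.ROBOT_SPIKE)


class PotentialKind(IntEnum):
    NONE = 0
    WCA = 1
    WCA_COS = 2
    NP_LJ = 3


class ForceFieldError(ValueError):
    pass


class BondOverstretchError(RuntimeError):
    """A FENE bond reached its divergence length (timestep too large)."""

    def __init__(self, i: int, j: int, r: float, r_inf: float, step: int = -1):
        self.i, self.j, self.r, self.step = i, j, r, step
        at = f" at step {step}" if step >= 0 else ""
        super().__init__(
            f"FENE bond {i}-{j} overstretched{at}: r = {r:.4f} >= r_inf = {r_inf}"
        )


# ---------------------------------------------------------------------------
# scalar potentials (energy) and their radial forces  f = -dU/dr
# ---------------------------------------------------------------------------

def u_rep(r: float, b: float, params: ForceFieldParams) -> float:
    """WCA repulsion with length scale *b*, cut at ``2^(1/6) b``."""
    if r <= 0:
        raise ForceFieldError("u_rep requires r > 0")
    rcut = 2.0 ** (1.0 / 6.0) * b
    if r > rcut:
        return 0.0
    sr6 = (b / r) ** 6
    u = 4.0 * params.eps_rep * (sr6 * sr6 - sr6)
    if params.rep_shifted:
        u += params.eps_rep
    return u


def f_rep(r: float, b: float, params: ForceFieldParams) -> float:
    if r <= 0:
        raise ForceFieldError("f_rep requires r > 0")
    rcut = 2.0 ** (1.0 / 6.0) * b
    if r > rcut:
        return 0.0
    sr6 = (b / r) ** 6
    return 4.0 * params.eps_rep * (12.0 * sr6 * sr6 - 6.0 * sr6) / r


def u_cos(r: float, params: ForceFieldParams, eps: float = 1.0) -> float:
    """Tail-tail cosine-squared attraction (depth *eps*)."""
    if r <= 0:
        raise ForceFieldError("u_cos requires r > 0")
    rc, wc = params.rc, params.wc
    if r < rc:
        return -eps
    if r > rc + wc:
        return 0.0
    c = math.cos(math.pi * (r - rc) / (2.0 * wc))
    return -eps * c * c


def f_cos(r: float, params: ForceFieldParams, eps: float = 1.0) -> float:
    rc, wc = params.rc, params.wc
    if r < rc or r > rc + wc:
        return 0.0
    arg = math.pi * (r - rc) / (2.0 * wc)
    # -dU/dr of -eps cos^2(arg)
    return -eps * math.pi / (2.0 * wc) * math.sin(2.0 * arg)


def u_fene(r: float, params: ForceFieldParams) -> float:
    """FENE bond energy; domain [0, r_inf)."""
    if r < 0:
        raise ForceFieldError("u_fene requires r >= 0")
    if r >= params.r_inf:
        raise BondOverstretchError(-1, -1, r, params.r_inf)
    x = r / params.r_inf
    return -0.5 * params.k_fene * params.r_inf**2 * math.log(1.0 - x * x)


def f_fene(r: float, params: ForceFieldParams) -> float:
    if r >= params.r_inf:
        raise BondOverstretchError(-1, -1, r, params.r_inf)
    x2 = (r / params.r_inf) ** 2
    return -params.k_fene * r / (1.0 - x2)


def u_bend(r: float, params: ForceFieldParams) -> float:
    """Harmonic head-to-tail2 straightening spring."""
    if r < 0:
        raise ForceFieldError("u_bend requires r >= 0")
    return 0.5 * params.k_bend * (r - params.r0_bend) ** 2


def f_bend(r: float, params: ForceFieldParams) -> float:
    return -params.k_bend * (r - params.r0_bend)


def u_np(
    r: float,
    params: ForceFieldParams,
    eps: float | None = None,
    shifted: bool = True,
) -> float:
    """Nanoparticle-membrane 12-6 attraction, truncated at ``rcut_np``."""
    if r <= 0:
        raise ForceFieldError("u_np requires r > 0")
    if eps is None:
        eps = params.eps_np
    if r > params.rcut_np:
        return 0.0
    b = params.b_np

    def lj(rr: float) -> float:
        sr6 = (b / rr) ** 6
        return 4.0 * eps * (sr6 * sr6 - sr6)

    u = lj(r)
    if shifted:
        u -= lj(params.rcut_np)
    return u


def f_np(r: float, params: ForceFieldParams, eps: float | None = None) -> float:
    if r <= 0:
        raise ForceFieldError("f_np requires r > 0")
    if eps is None:
        eps = params.eps_np
    if r > params.rcut_np:
        return 0.0
    sr6 = (params.b_np / r) ** 6
    return 4.0 * eps * (12.0 * sr6 * sr6 - 6.0 * sr6) / r


_POTENTIALS = {
    "rep": (u_rep, f_rep),
    "cos": (u_cos, f_cos),
    "fene": (u_fene, f_fene),
    "bend": (u_bend, f_bend),
    "np": (u_np, f_np),
}


def pair_force(potential: str, r: float, params: ForceFieldParams, **kw) -> float:
    """Radial force magnitude ``-dU/dr`` for the named potential."""
    try:
        _, f = _POTENTIALS[potential]
    except KeyError:
        raise ForceFieldError(
            f"unknown potential {potential!r}; known: {sorted(_POTENTIALS)}"
        ) from None
    if potential == "rep":
        return f(r, kw.pop("b"), params, **kw)
    return f(r, params, **kw)


def pair_energy(potential: str, r: float, params: ForceFieldParams, **kw) -> float:
    try:
        u, _ = _POTENTIALS[potential]
    except KeyError:
        raise ForceFieldError(
            f"unknown potential {potential!r}; known: {sorted(_POTENTIALS)}"
        ) from None
    if potential == "rep":
        return u(r, kw.pop("b"), params, **kw)
    return u(r, params, **kw)


# ---------------------------------------------------------------------------
# kind-pair rule table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairRule:
    kind_a: BeadKind
    kind_b: BeadKind
    potential: PotentialKind
    b_effective: float
    epsilon_effective: float
    cutoff: float


def build_pair_table(params: ForceFieldParams):
    """Dense symmetric (N_KINDS x N_KINDS) tables of pair interactions.

    Returns ``(pot, b, eps, cutoff)`` integer/float arrays indexed by the
    two bead kinds.
    """
    K = N_KINDS
    pot = np.zeros((K, K), dtype=np.int64)
    b = np.zeros((K, K))
    eps = np.zeros((K, K))
    cut = np.zeros((K, K))
    sixth = 2.0 ** (1.0 / 6.0)

    def set_rule(ka, kb, p, bb, ee, cc):
        pot[ka, kb] = pot[kb, ka] = int(p)
        b[ka, kb] = b[kb, ka] = bb
        eps[ka, kb] = eps[kb, ka] = ee
        cut[ka, kb] = cut[kb, ka] = cc

    heads = HEAD_KINDS
    tails = TAIL_KINDS
    # lipid-lipid WCA core: b = 0.95 if either partner is a head, 1.0 tail-tail
    for ka in heads:
        for kb in heads:
            set_rule(ka, kb, PotentialKind.WCA, params.b_head_head,
                     params.eps_rep, sixth * params.b_head_head)
        for kb in tails:
            set_rule(ka, kb, PotentialKind.WCA, params.b_head_tail,
                     params.eps_rep, sixth * params.b_head_tail)
    for ka in tails:
        for kb in tails:
            set_rule(ka, kb, PotentialKind.WCA_COS, params.b_tail_tail,
                     params.eps_rep, params.rc + params.wc)
    # nanoparticle (cargo + robot) against any lipid bead: adhesive LJ
    for np_kind in (BeadKind.CARGO, *ROBOT_KINDS):
        for lk in LIPID_KINDS:
            set_rule(np_kind, lk, PotentialKind.NP_LJ, params.b_np,
                     params.eps_np, params.rcut_np)
    # ligand-receptor: deeper attraction between receptor heads and spikes
    set_rule(BeadKind.RECEPTOR_HEAD, BeadKind.ROBOT_SPIKE, PotentialKind.NP_LJ,
             params.b_np, params.eps_receptor, params.rcut_np)
    # cargo-cargo: purely repulsive at the cargo diameter (no aggregation)
    set_rule(BeadKind.CARGO, BeadKind.CARGO, PotentialKind.WCA,
             params.b_cargo_cargo, params.eps_rep,
             sixth * params.b_cargo_cargo)
    # cargo-robot: repulsive at the mean of cargo (2 sigma) and robot (1 sigma)
    b_cr = 0.5 * (params.b_cargo_cargo + 1.0)
    for rk in ROBOT_KINDS:
        set_rule(BeadKind.CARGO, rk, PotentialKind.WCA, b_cr,
                 params.eps_rep, sixth * b_cr)
    # robot-robot: rigid body, no internal interactions
    for ka in ROBOT_KINDS:
        for kb in ROBOT_KINDS:
            set_rule(ka, kb, PotentialKind.NONE, 0.0, 0.0, 0.0)
    return pot, b, eps, cut


def pair_rules(params: ForceFieldParams) -> list[PairRule]:
    """Upper-triangle list of :class:`PairRule` (auditable view)."""
    pot, b, eps, cut = build_pair_table(params)
    rules = []
    for ka in BeadKind:
        for kb in BeadKind:
            if kb < ka:
                continue
            rules.append(PairRule(ka, kb, PotentialKind(pot[ka, kb]),
                                  float(b[ka, kb]), float(eps[ka, kb]),
                                  float(cut[ka, kb])))
    return rules


def pair_rules_to_csv(params: ForceFieldParams, path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["kind_a", "kind_b", "potential", "b", "epsilon", "cutoff"])
        for r in pair_rules(params):
            w.writerow([r.kind_a.name, r.kind_b.name, r.potential.name,
                        f"{r.b_effective:.6f}", f"{r.epsilon_effective:.6f}",
                        f"{r.cutoff:.6f}"])


def _pair_uf(r, p, bb, ee, cc, params) -> tuple[float, float]:
    """Energy/force from prebuilt table entries (p, b, eps, cutoff)."""
    if p == PotentialKind.NONE or r > cc:
        return 0.0, 0.0
    if p == PotentialKind.WCA:
        sr6 = (bb / r) ** 6
        u = 4.0 * ee * (sr6 * sr6 - sr6)
        if params.rep_shifted:
            u += ee
        f = 4.0 * ee * (12.0 * sr6 * sr6 - 6.0 * sr6) / r
        return u, f
    if p == PotentialKind.WCA_COS:
        u = f = 0.0
        rcut_w = 2.0 ** (1.0 / 6.0) * bb
        if r <= rcut_w:
            sr6 = (bb / r) ** 6
            u = 4.0 * params.eps_rep * (sr6 * sr6 - sr6)
            if params.rep_shifted:
                u += params.eps_rep
            f = 4.0 * params.eps_rep * (12.0 * sr6 * sr6 - 6.0 * sr6) / r
        u += u_cos(r, params)
        f += f_cos(r, params)
        return u, f
    # NP_LJ
    return u_np(r, params, eps=ee), f_np(r, params, eps=ee)


def pair_energy_force_by_kind(
    r: float, ka: int, kb: int, params: ForceFieldParams
) -> tuple[float, float]:
    """Energy and radial force for a pair of the given kinds at distance r."""
    pot, b, eps, cut = build_pair_table(params)
    return _pair_uf(r, int(pot[ka, kb]), float(b[ka, kb]), float(eps[ka, kb]),
                    float(cut[ka, kb]), params)


# ---------------------------------------------------------------------------
# brute-force reference evaluator (test oracle; O(N^2))
# ---------------------------------------------------------------------------

def reference_energy_forces(system, params: ForceFieldParams):
    """All-pairs double-loop energy/forces, the oracle for the fast path.

    Parameters
    ----------
    system : ParticleSystem
    params : ForceFieldParams

    Returns
    -------
    (energy, forces) with minimum-image periodic distances.
    """
    pos = np.asarray(system.positions, dtype=float)
    box = np.asarray(system.box, dtype=float)
    kinds = np.asarray(system.kinds)
    pot, btab, epstab, cuttab = build_pair_table(params)
    n = len(pos)
    forces = np.zeros((n, 3))
    energy = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            d = pos[i] - pos[j]
            d -= box * np.round(d / box)
            r = float(np.linalg.norm(d))
            ka, kb = int(kinds[i]), int(kinds[j])
            u, f = _pair_uf(r, int(pot[ka, kb]), float(btab[ka, kb]),
                            float(epstab[ka, kb]), float(cuttab[ka, kb]),
                            params)
            energy += u
            if r > 0 and f != 0.0:
                fv = f * d / r
                forces[i] += fv
                forces[j] -= fv
    for i, j, bond_type in system.bonds:
        d = pos[i] - pos[j]
        d -= box * np.round(d / box)
        r = float(np.linalg.norm(d))
        if bond_type == 0:  # FENE
            if r >= params.r_inf:
                raise BondOverstretchError(i, j, r, params.r_inf)
            energy += u_fene(r, params)
            f = f_fene(r, params)
        else:  # head-tail2 straightening spring
            energy += u_bend(r, params)
            f = f_bend(r, params)
        if r > 0:
            fv = f * d / r
            forces[i] += fv
            forces[j] -= fv
    return energy, forces
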