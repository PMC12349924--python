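"""Numba-compiled inner loops: neighbor search, pair/bond forces, virial.

Strategy
--------
Membrane beads (the overwhelming majority) interact at short range
(<= rc + wc) and get a linked-cell search with cells of about half the
list range (finer cells mean fewer spurious distance checks for a slab
geometry).  "Special" beads (cargo and robot) are few but reach out to
the nanoparticle cutoff (~6.7 sigma); their pairs come from a direct
loop against all beads.  The builder emits three *typed* Verlet lists --
WCA, WCA+cosine (tail-tail), nanoparticle 12-6 -- with per-pair constants
resolved once per rebuild, so the per-step force loops are branch-free.
Lists are rebuilt by the caller when any bead has moved more than half
the skin.

All periodic minimum-image arithmetic is written out inline: numba's
function inlining leaves measurable per-call overhead in these loops.
"""

from __future__ import annotations

import numpy as np
from numba import njit

RT6_2 = 2.0 ** (1.0 / 6.0)

# potential codes in the dense kind tables
POT_NONE = 0
POT_WCA = 1
POT_WCA_COS = 2
POT_NP = 3


@njit(cache=True, fastmath=True)
def build_pairs(pos, kinds, box, mem_mask, special_idx,
                pot_table, b_table, eps_table, cut_table,
                skin, max_pairs):
    """Build the three typed pair lists.

    Returns ``(wi, wj, wb2, weps, wcut2, nw, ci, cj, nc, pi_, pj, peps,
    npn)``; any negative count signals that *max_pairs* was too small.
    """
    n = pos.shape[0]
    lx = box[0]
    ly = box[1]
    lz = box[2]
    wi = np.empty(max_pairs, dtype=np.int32)
    wj = np.empty(max_pairs, dtype=np.int32)
    wb2 = np.empty(max_pairs, dtype=np.float64)
    weps = np.empty(max_pairs, dtype=np.float64)
    wcut2 = np.empty(max_pairs, dtype=np.float64)
    ci = np.empty(max_pairs, dtype=np.int32)
    cj = np.empty(max_pairs, dtype=np.int32)
    pi_ = np.empty(max_pairs, dtype=np.int32)
    pj = np.empty(max_pairs, dtype=np.int32)
    peps = np.empty(max_pairs, dtype=np.float64)
    nw = 0
    nc = 0
    npn = 0

    # membrane-membrane list range = largest lipid-lipid cutoff + skin
    cut_mem = 0.0
    for a in range(pot_table.shape[0]):
        for b in range(pot_table.shape[1]):
            la = a == 0 or a == 1 or a == 2 or a == 6
            lb = b == 0 or b == 1 or b == 2 or b == 6
            if la and lb and cut_table[a, b] > cut_mem:
                cut_mem = cut_table[a, b]
    rlist = cut_mem + skin

    # --- cell list over membrane beads, cells ~ rlist/2 -----------------
    target = 0.5 * rlist
    ncx = max(1, int(lx / target))
    ncy = max(1, int(ly / target))
    ncz = max(1, int(lz / target))
    # cell reach covering rlist; +-(nc//2) with dedup spans the whole
    # axis, so the min() is safe on small grids
    rx = min(int(np.ceil(rlist / (lx / ncx))), ncx // 2)
    ry = min(int(np.ceil(rlist / (ly / ncy))), ncy // 2)
    rz = min(int(np.ceil(rlist / (lz / ncz))), ncz // 2)

    ncells = ncx * ncy * ncz
    head = np.full(ncells, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        if not mem_mask[i]:
            continue
        cx = int(pos[i, 0] / lx * ncx) % ncx
        cy = int(pos[i, 1] / ly * ncy) % ncy
        cz = int(pos[i, 2] / lz * ncz) % ncz
        c = (cz * ncy + cy) * ncx + cx
        nxt[i] = head[c]
        head[c] = i

    # Half-stencil cell-pair iteration: every unordered cell pair is
    # visited once, so candidate bead pairs are checked only once.  Grids
    # too small to make wrapped offsets unambiguous fall back to a full
    # stencil with duplicate-cell removal and a j > i guard (tiny systems
    # only, where the cost is irrelevant).
    small_grid = (ncx < 2 * (2 * rx + 1)) or (ncy < 2 * (2 * ry + 1)) \
        or (ncz < 2 * (2 * rz + 1))
    nmax = (2 * rx + 1) * (2 * ry + 1) * (2 * rz + 1)
    neigh = np.empty(nmax, dtype=np.int64)
    for cz in range(ncz):
        for cy in range(ncy):
            for cx in range(ncx):
                c = (cz * ncy + cy) * ncx + cx
                i0 = head[c]
                if i0 < 0:
                    continue
                # same-cell pairs via chain order (each pair once)
                i = i0
                while i >= 0:
                    ki = kinds[i]
                    xi = pos[i, 0]
                    yi = pos[i, 1]
                    zi = pos[i, 2]
                    j = nxt[i]
                    while j >= 0:
                        kj = kinds[j]
                        rl = cut_table[ki, kj] + skin
                        dx = xi - pos[j, 0]
                        if dx > 0.5 * lx:
                            dx -= lx
                        elif dx < -0.5 * lx:
                            dx += lx
                        dy = yi - pos[j, 1]
                        if dy > 0.5 * ly:
                            dy -= ly
                        elif dy < -0.5 * ly:
                            dy += ly
                        dz = zi - pos[j, 2]
                        if dz > 0.5 * lz:
                            dz -= lz
                        elif dz < -0.5 * lz:
                            dz += lz
                        if dx * dx + dy * dy + dz * dz < rl * rl:
                            p = pot_table[ki, kj]
                            if p == POT_WCA_COS:
                                if nc >= max_pairs:
                                    return (wi, wj, wb2, weps, wcut2, -1,
                                            ci, cj, -1, pi_, pj, peps, -1)
                                ci[nc] = i
                                cj[nc] = j
                                nc += 1
                            elif p == POT_WCA:
                                if nw >= max_pairs:
                                    return (wi, wj, wb2, weps, wcut2, -1,
                                            ci, cj, -1, pi_, pj, peps, -1)
                                bb = b_table[ki, kj]
                                wi[nw] = i
                                wj[nw] = j
                                wb2[nw] = bb * bb
                                weps[nw] = eps_table[ki, kj]
                                cc = cut_table[ki, kj]
                                wcut2[nw] = cc * cc
                                nw += 1
                        j = nxt[j]
                    i = nxt[i]
                # cross-cell pairs
                nn = 0
                for oz in range(-rz, rz + 1):
                    for oy in range(-ry, ry + 1):
                        for ox in range(-rx, rx + 1):
                            if not small_grid:
                                # half stencil: skip self and mirrors
                                if oz < 0 or (oz == 0 and (oy < 0 or (
                                        oy == 0 and ox <= 0))):
                                    continue
                            c2 = ((((cz + oz) % ncz) * ncy
                                   + (cy + oy) % ncy) * ncx
                                  + (cx + ox) % ncx)
                            if c2 == c or head[c2] < 0:
                                continue
                            if small_grid:
                                dup = False
                                for q in range(nn):
                                    if neigh[q] == c2:
                                        dup = True
                                        break
                                if dup:
                                    continue
                                neigh[nn] = c2
                                nn += 1
                            i = i0
                            while i >= 0:
                                ki = kinds[i]
                                xi = pos[i, 0]
                                yi = pos[i, 1]
                                zi = pos[i, 2]
                                j = head[c2]
                                while j >= 0:
                                    if small_grid and j <= i:
                                        j = nxt[j]
                                        continue
                                    kj = kinds[j]
                                    rl = cut_table[ki, kj] + skin
                                    dx = xi - pos[j, 0]
                                    if dx > 0.5 * lx:
                                        dx -= lx
                                    elif dx < -0.5 * lx:
                                        dx += lx
                                    dy = yi - pos[j, 1]
                                    if dy > 0.5 * ly:
                                        dy -= ly
                                    elif dy < -0.5 * ly:
                                        dy += ly
                                    dz = zi - pos[j, 2]
                                    if dz > 0.5 * lz:
                                        dz -= lz
                                    elif dz < -0.5 * lz:
                                        dz += lz
                                    if dx * dx + dy * dy + dz * dz < rl * rl:
                                        p = pot_table[ki, kj]
                                        if p == POT_WCA_COS:
                                            if nc >= max_pairs:
                                                return (wi, wj, wb2, weps,
                                                        wcut2, -1, ci, cj,
                                                        -1, pi_, pj, peps,
                                                        -1)
                                            ci[nc] = i
                                            cj[nc] = j
                                            nc += 1
                                        elif p == POT_WCA:
                                            if nw >= max_pairs:
                                                return (wi, wj, wb2, weps,
                                                        wcut2, -1, ci, cj,
                                                        -1, pi_, pj, peps,
                                                        -1)
                                            bb = b_table[ki, kj]
                                            wi[nw] = i
                                            wj[nw] = j
                                            wb2[nw] = bb * bb
                                            weps[nw] = eps_table[ki, kj]
                                            cc = cut_table[ki, kj]
                                            wcut2[nw] = cc * cc
                                            nw += 1
                                    j = nxt[j]
                                i = nxt[i]

    # --- special beads: direct loop ------------------------------------
    ns = special_idx.shape[0]
    for a in range(ns):
        i = special_idx[a]
        ki = kinds[i]
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        for j in range(n):
            if j == i:
                continue
            if not mem_mask[j] and j < i:
                continue  # special-special counted once
            kj = kinds[j]
            p = pot_table[ki, kj]
            if p == POT_NONE:
                continue
            cut = cut_table[ki, kj]
            rl = cut + skin
            rl2 = rl * rl
            dx = xi - pos[j, 0]
            if dx > 0.5 * lx:
                dx -= lx
            elif dx < -0.5 * lx:
                dx += lx
            if dx * dx > rl2:
                continue
            dy = yi - pos[j, 1]
            if dy > 0.5 * ly:
                dy -= ly
            elif dy < -0.5 * ly:
                dy += ly
            dz = zi - pos[j, 2]
            if dz > 0.5 * lz:
                dz -= lz
            elif dz < -0.5 * lz:
                dz += lz
            if dx * dx + dy * dy + dz * dz >= rl2:
                continue
            if p == POT_NP:
                if npn >= max_pairs:
                    return (wi, wj, wb2, weps, wcut2, -1, ci, cj, -1,
                            pi_, pj, peps, -1)
                pi_[npn] = i
                pj[npn] = j
                peps[npn] = eps_table[ki, kj]
                npn += 1
            elif p == POT_WCA:
                if nw >= max_pairs:
                    return (wi, wj, wb2, weps, wcut2, -1, ci, cj, -1,
                            pi_, pj, peps, -1)
                bb = b_table[ki, kj]
                wi[nw] = i
                wj[nw] = j
                wb2[nw] = bb * bb
                weps[nw] = eps_table[ki, kj]
                wcut2[nw] = cut * cut
                nw += 1
    return wi, wj, wb2, weps, wcut2, nw, ci, cj, nc, pi_, pj, peps, npn


@njit(cache=True, fastmath=True)
def typed_forces(pos, box,
                 wi, wj, wb2, weps, wcut2, nw,
                 ci, cj, nc,
                 pi_, pj, peps, npn,
                 rep_shift, b_tail, eps_rep, rc, wc,
                 b_np, rcut_np, np_shift,
                 forces):
    """Pair forces from the typed lists; returns (E, Wxx, Wyy, Wzz)."""
    energy = 0.0
    wxx = 0.0
    wyy = 0.0
    wzz = 0.0
    lx = box[0]
    ly = box[1]
    lz = box[2]

    # --- plain WCA ------------------------------------------------------
    for p in range(nw):
        i = wi[p]
        j = wj[p]
        dx = pos[i, 0] - pos[j, 0]
        if dx > 0.5 * lx:
            dx -= lx
        elif dx < -0.5 * lx:
            dx += lx
        dy = pos[i, 1] - pos[j, 1]
        if dy > 0.5 * ly:
            dy -= ly
        elif dy < -0.5 * ly:
            dy += ly
        dz = pos[i, 2] - pos[j, 2]
        if dz > 0.5 * lz:
            dz -= lz
        elif dz < -0.5 * lz:
            dz += lz
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= wcut2[p]:
            continue
        ee = weps[p]
        rinv2 = 1.0 / r2
        a2 = wb2[p] * rinv2
        sr6 = a2 * a2 * a2
        sr12 = sr6 * sr6
        u = 4.0 * ee * (sr12 - sr6)
        if rep_shift:
            u += ee
        fr = ee * (48.0 * sr12 - 24.0 * sr6) * rinv2
        energy += u
        fx = fr * dx
        fy = fr * dy
        fz = fr * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        wxx += fx * dx
        wyy += fy * dy
        wzz += fz * dz

    # --- tail-tail: WCA core + cosine attraction (depth = 1 epsilon) ----
    b2 = b_tail * b_tail
    wca_cut2 = RT6_2 * RT6_2 * b2
    rc2 = rc * rc
    outer = rc + wc
    outer2 = outer * outer
    halfpi_wc = np.pi / (2.0 * wc)
    for p in range(nc):
        i = ci[p]
        j = cj[p]
        dx = pos[i, 0] - pos[j, 0]
        if dx > 0.5 * lx:
            dx -= lx
        elif dx < -0.5 * lx:
            dx += lx
        dy = pos[i, 1] - pos[j, 1]
        if dy > 0.5 * ly:
            dy -= ly
        elif dy < -0.5 * ly:
            dy += ly
        dz = pos[i, 2] - pos[j, 2]
        if dz > 0.5 * lz:
            dz -= lz
        elif dz < -0.5 * lz:
            dz += lz
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= outer2:
            continue
        u = 0.0
        fr = 0.0
        rinv2 = 1.0 / r2
        if r2 < wca_cut2:
            a2 = b2 * rinv2
            sr6 = a2 * a2 * a2
            sr12 = sr6 * sr6
            u = 4.0 * eps_rep * (sr12 - sr6)
            if rep_shift:
                u += eps_rep
            fr = eps_rep * (48.0 * sr12 - 24.0 * sr6) * rinv2
        if r2 < rc2:
            u += -1.0
        else:
            r = np.sqrt(r2)
            x = halfpi_wc * (r - rc)  # in [0, pi/2]
            x2 = x * x
            # Taylor cos to x^14: |err| < 1e-10 on [0, pi/2]
            c = 1.0 + x2 * (-0.5 + x2 * (1.0 / 24.0 + x2 * (
                -1.0 / 720.0 + x2 * (1.0 / 40320.0 + x2 * (
                    -1.0 / 3628800.0 + x2 * (1.0 / 479001600.0
                                             - x2 / 87178291200.0))))))
            # sin from its own series (sqrt(1-c^2) would amplify the
            # truncation error near the plateau edge where sin -> 0)
            s = x * (1.0 + x2 * (-1.0 / 6.0 + x2 * (1.0 / 120.0 + x2 * (
                -1.0 / 5040.0 + x2 * (1.0 / 362880.0 + x2 * (
                    -1.0 / 39916800.0 + x2 / 6227020800.0))))))
            u += -c * c
            fr += -halfpi_wc * 2.0 * s * c * r * rinv2
        energy += u
        fx = fr * dx
        fy = fr * dy
        fz = fr * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        wxx += fx * dx
        wyy += fy * dy
        wzz += fz * dz

    # --- nanoparticle 12-6 ----------------------------------------------
    bnp2 = b_np * b_np
    npcut2 = rcut_np * rcut_np
    sc2 = bnp2 / npcut2
    sc6 = sc2 * sc2 * sc2
    ushift_unit = 4.0 * (sc6 * sc6 - sc6) if np_shift else 0.0
    for p in range(npn):
        i = pi_[p]
        j = pj[p]
        dx = pos[i, 0] - pos[j, 0]
        if dx > 0.5 * lx:
            dx -= lx
        elif dx < -0.5 * lx:
            dx += lx
        dy = pos[i, 1] - pos[j, 1]
        if dy > 0.5 * ly:
            dy -= ly
        elif dy < -0.5 * ly:
            dy += ly
        dz = pos[i, 2] - pos[j, 2]
        if dz > 0.5 * lz:
            dz -= lz
        elif dz < -0.5 * lz:
            dz += lz
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= npcut2:
            continue
        ee = peps[p]
        rinv2 = 1.0 / r2
        a2 = bnp2 * rinv2
        sr6 = a2 * a2 * a2
        sr12 = sr6 * sr6
        u = 4.0 * ee * (sr12 - sr6) - ee * ushift_unit
        fr = ee * (48.0 * sr12 - 24.0 * sr6) * rinv2
        energy += u
        fx = fr * dx
        fy = fr * dy
        fz = fr * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        wxx += fx * dx
        wyy += fy * dy
        wzz += fz * dz
    return energy, wxx, wyy, wzz


@njit(cache=True, fastmath=True)
def bond_forces(pos, box, bonds, k_fene, r_inf, k_bend, r0_bend, forces):
    """FENE + straightening-spring forces.

    Returns (energy, wxx, wyy, wzz, bad_bond); bad_bond >= 0 is the row
    of an overstretched FENE bond (caller raises).
    """
    energy = 0.0
    wxx = 0.0
    wyy = 0.0
    wzz = 0.0
    lx = box[0]
    ly = box[1]
    lz = box[2]
    for m in range(bonds.shape[0]):
        i = bonds[m, 0]
        j = bonds[m, 1]
        bt = bonds[m, 2]
        dx = pos[i, 0] - pos[j, 0]
        if dx > 0.5 * lx:
            dx -= lx
        elif dx < -0.5 * lx:
            dx += lx
        dy = pos[i, 1] - pos[j, 1]
        if dy > 0.5 * ly:
            dy -= ly
        elif dy < -0.5 * ly:
            dy += ly
        dz = pos[i, 2] - pos[j, 2]
        if dz > 0.5 * lz:
            dz -= lz
        elif dz < -0.5 * lz:
            dz += lz
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        if bt == 0:
            if r >= r_inf:
                return energy, wxx, wyy, wzz, m
            x2 = r2 / (r_inf * r_inf)
            energy += -0.5 * k_fene * r_inf * r_inf * np.log(1.0 - x2)
            fr = -k_fene / (1.0 - x2)  # f/r
        else:
            energy += 0.5 * k_bend * (r - r0_bend) ** 2
            fr = -k_bend * (r - r0_bend) / r
        fx = fr * dx
        fy = fr * dy
        fz = fr * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        wxx += fx * dx
        wyy += fy * dy
        wzz += fz * dz
    return energy, wxx, wyy, wzz, -1


@njit(cache=True, fastmath=True)
def max_disp2(pos, ref, box):
    """Largest squared displacement since the last neighbor build."""
    worst = 0.0
    lx = box[0]
    ly = box[1]
    lz = box[2]
    for i in range(pos.shape[0]):
        dx = pos[i, 0] - ref[i, 0]
        if dx > 0.5 * lx:
            dx -= lx
        elif dx < -0.5 * lx:
            dx += lx
        dy = pos[i, 1] - ref[i, 1]
        if dy > 0.5 * ly:
            dy -= ly
        elif dy < -0.5 * ly:
            dy += ly
        dz = pos[i, 2] - ref[i, 2]
        if dz > 0.5 * lz:
            dz -= lz
        elif dz < -0.5 * lz:
            dz += lz
        d2 = dx * dx + dy * dy + dz * dz
        if d2 > worst:
            worst = d2
    return worst


@njit(cache=True, fastmath=True)
def baoab_pre(pos, vel, forces, images, box, dt, c1, c2, noise, thermo):
    """B (half kick), A (half drift), O, A, then periodic wrap."""
    n = pos.shape[0]
    half = 0.5 * dt
    for i in range(n):
        for d in range(3):
            v = vel[i, d] + half * forces[i, d]
            x = pos[i, d] + half * v
            if thermo:
                v = c1 * v + c2 * noise[i, d]
            x += half * v
            L = box[d]
            if x >= L:
                x -= L
                images[i, d] += 1
                if x >= L:
                    k = int(x // L)
                    x -= k * L
                    images[i, d] += k
            elif x < 0.0:
                x += L
                images[i, d] -= 1
                if x < 0.0:
                    k = int((-x) // L) + 1
                    x += k * L
                    images[i, d] -= k
            vel[i, d] = v
            pos[i, d] = x


@njit(cache=True, fastmath=True)
def kick(vel, forces, dt):
    n = vel.shape[0]
    half = 0.5 * dt
    for i in range(n):
        for d in range(3):
            vel[i, d] += half * forces[i, d]
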