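"""Numba kernels: pair lists, forces, and integration inner loops.

Everything here operates on packed plain arrays; the public modules own the
dataclasses and do the packing.  Force conventions: ``F[i]`` is the force on
bead ``i``; all pairwise terms are equal and opposite by construction.

Error codes returned by the integrators:
    0  success
    1  nonbonded overlap (r < 1e-6 sigma) — offending pair reported
    2  non-finite displacement — offending step reported
    3  pair-list buffer overflow
"""
from __future__ import annotations

import numpy as np
from numba import njit

WCA_CUT_FACTOR = 2.0 ** (1.0 / 6.0)

PAIR_REPULSION = 0
PAIR_ATTRACTION = 1


@njit(cache=True)
def build_pairs(pos, list_cutoff, excl, is_head, is_mem, pi, pj, ptype):
    """Exhaustive O(n^2) candidate-pair scan within ``list_cutoff``.

    Returns the number of pairs found, or -1 on buffer overflow.
    """
    n = pos.shape[0]
    cut2 = list_cutoff * list_cutoff
    count = 0
    cap = pi.shape[0]
    for i in range(n - 1):
        xi = pos[i, 0]
        yi = pos[i, 1]
        for j in range(i + 1, n):
            if excl[i, j]:
                continue
            dx = xi - pos[j, 0]
            dy = yi - pos[j, 1]
            r2 = dx * dx + dy * dy
            if r2 >= cut2:
                continue
            if count >= cap:
                return -1
            pi[count] = i
            pj[count] = j
            if (is_head[i] and is_mem[j]) or (is_mem[i] and is_head[j]):
                ptype[count] = PAIR_ATTRACTION
            else:
                ptype[count] = PAIR_REPULSION
            count += 1
    return count


@njit(cache=True)
def forces_energy(
    pos,
    bonds,
    bond_kappa,
    bond_r0,
    triples,
    tri_kappa,
    tri_phi0,
    area_idx,
    area_off,
    area_kappa,
    area_a0,
    pi,
    pj,
    ptype,
    n_pairs,
    u3,
    rcut_attr,
    eps_rep,
    sigma,
    forces,
):
    """Total force field and energy breakdown.

    Returns (e_stretch, e_bend, e_attr, e_rep, e_area, err_i, err_j);
    err_i >= 0 flags a nonbonded overlap between beads err_i and err_j.
    """
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0

    e_stretch = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        r = np.sqrt(dx * dx + dy * dy)
        k = bond_kappa[b]
        dr = r - bond_r0[b]
        e_stretch += 0.5 * k * dr * dr
        if r > 0.0:
            f = -k * dr / r
            fx = f * dx
            fy = f * dy
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[j, 0] -= fx
            forces[j, 1] -= fy

    e_bend = 0.0
    for t in range(triples.shape[0]):
        i = triples[t, 0]
        j = triples[t, 1]
        k2 = triples[t, 2]
        ax = pos[j, 0] - pos[i, 0]
        ay = pos[j, 1] - pos[i, 1]
        bx = pos[k2, 0] - pos[j, 0]
        by = pos[k2, 1] - pos[j, 1]
        c = ax * by - ay * bx
        d = ax * bx + ay * by
        s2 = c * c + d * d
        if s2 < 1e-300:
            continue
        phi = np.arctan2(c, d)
        kb = tri_kappa[t]
        dphi = phi - tri_phi0[t]
        e_bend += kb * (1.0 - np.cos(dphi))
        dedphi = kb * np.sin(dphi)
        inv = 1.0 / s2
        # dphi/da and dphi/db (a = r_j - r_i, b = r_k - r_j)
        dpdax = (d * by - c * bx) * inv
        dpday = (-d * bx - c * by) * inv
        dpdbx = (-d * ay - c * ax) * inv
        dpdby = (d * ax - c * ay) * inv
        # F_i = +dE/dphi * dphi/da ; F_k = -dE/dphi * dphi/db ; F_j = -(F_i+F_k)
        fix = dedphi * dpdax
        fiy = dedphi * dpday
        fkx = -dedphi * dpdbx
        fky = -dedphi * dpdby
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[k2, 0] += fkx
        forces[k2, 1] += fky
        forces[j, 0] -= fix + fkx
        forces[j, 1] -= fiy + fky

    # nonbonded
    sig2 = sigma * sigma
    rcut2_attr = rcut_attr * rcut_attr
    rcut2_rep = (WCA_CUT_FACTOR * sigma) * (WCA_CUT_FACTOR * sigma)
    overlap2 = (1e-6 * sigma) * (1e-6 * sigma)
    # energy shift so the attraction vanishes continuously at its cutoff
    src2 = sig2 / rcut2_attr
    src6 = src2 * src2 * src2
    e_shift = 4.0 * u3 * (src6 * src6 - src6)
    e_attr = 0.0
    e_rep = 0.0
    for p in range(n_pairs):
        i = pi[p]
        j = pj[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        r2 = dx * dx + dy * dy
        if ptype[p] == PAIR_ATTRACTION:
            if r2 >= rcut2_attr:
                continue
            if r2 < overlap2:
                return (e_stretch, e_bend, e_attr, e_rep, 0.0, i, j)
            sr2 = sig2 / r2
            sr6 = sr2 * sr2 * sr2
            e_attr += 4.0 * u3 * (sr6 * sr6 - sr6) - e_shift
            f_over_r2 = 24.0 * u3 * (2.0 * sr6 * sr6 - sr6) / r2
        else:
            if r2 >= rcut2_rep:
                continue
            if r2 < overlap2:
                return (e_stretch, e_bend, e_attr, e_rep, 0.0, i, j)
            sr2 = sig2 / r2
            sr6 = sr2 * sr2 * sr2
            e_rep += 4.0 * eps_rep * (sr6 * sr6 - sr6) + eps_rep
            f_over_r2 = 24.0 * eps_rep * (2.0 * sr6 * sr6 - sr6) / r2
        fx = f_over_r2 * dx
        fy = f_over_r2 * dy
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[j, 0] -= fx
        forces[j, 1] -= fy

    # area constraints: E = 0.5 * kA * (A - A0)^2 / A0, shoelace area
    e_area = 0.0
    for g in range(area_off.shape[0] - 1):
        lo = area_off[g]
        hi = area_off[g + 1]
        m = hi - lo
        area = 0.0
        for a in range(m):
            i = area_idx[lo + a]
            j = area_idx[lo + (a + 1) % m]
            area += pos[i, 0] * pos[j, 1] - pos[j, 0] * pos[i, 1]
        area *= 0.5
        a0 = area_a0[g]
        ka = area_kappa[g]
        da = area - a0
        e_area += 0.5 * ka * da * da / a0
        deda = ka * da / a0
        for a in range(m):
            i = area_idx[lo + a]
            inext = area_idx[lo + (a + 1) % m]
            iprev = area_idx[lo + (a - 1) % m]
            # dA/dx_i = 0.5 (y_next - y_prev); dA/dy_i = 0.5 (x_prev - x_next)
            forces[i, 0] -= deda * 0.5 * (pos[inext, 1] - pos[iprev, 1])
            forces[i, 1] -= deda * 0.5 * (pos[iprev, 0] - pos[inext, 0])

    return (e_stretch, e_bend, e_attr, e_rep, e_area, -1, -1)


@njit(cache=True)
def integrate_overdamped_chunk(
    pos,
    ref_pos,
    pi,
    pj,
    ptype,
    n_pairs,
    bonds,
    bond_kappa,
    bond_r0,
    triples,
    tri_kappa,
    tri_phi0,
    area_idx,
    area_off,
    area_kappa,
    area_a0,
    excl,
    is_head,
    is_mem,
    noise,
    dt_over_gamma,
    max_disp,
    skin,
    list_cutoff,
    u3,
    rcut_attr,
    eps_rep,
    sigma,
    forces,
):
    """Euler-Maruyama chunk: pos <- pos + F dt/gamma + noise[s].

    ``noise`` is pre-scaled by sqrt(2 kT dt / gamma).  The deterministic
    displacement is capped at ``max_disp`` per bead per step, which keeps the
    steep Lennard-Jones core integrable at strong adhesion (the cap only
    engages at |F| > max_disp * gamma / dt, far above typical forces).
    Mutates pos, ref_pos and the pair buffers.  Returns
    (err_code, err_step, err_i, err_j, n_pairs).
    """
    n = pos.shape[0]
    n_steps = noise.shape[0]
    half_skin2 = (0.5 * skin) * (0.5 * skin)
    for s in range(n_steps):
        # Verlet-list validity: rebuild when any bead moved more than skin/2
        maxd2 = 0.0
        for i in range(n):
            dx = pos[i, 0] - ref_pos[i, 0]
            dy = pos[i, 1] - ref_pos[i, 1]
            d2 = dx * dx + dy * dy
            if d2 > maxd2:
                maxd2 = d2
        if maxd2 > half_skin2:
            n_pairs = build_pairs(pos, list_cutoff, excl, is_head, is_mem, pi, pj, ptype)
            if n_pairs < 0:
                return (3, s, -1, -1, 0)
            for i in range(n):
                ref_pos[i, 0] = pos[i, 0]
                ref_pos[i, 1] = pos[i, 1]

        res = forces_energy(
            pos, bonds, bond_kappa, bond_r0, triples, tri_kappa, tri_phi0,
            area_idx, area_off, area_kappa, area_a0,
            pi, pj, ptype, n_pairs, u3, rcut_attr, eps_rep, sigma, forces,
        )
        if res[5] >= 0:
            return (1, s, res[5], res[6], n_pairs)

        ok = True
        for i in range(n):
            ddx = forces[i, 0] * dt_over_gamma
            ddy = forces[i, 1] * dt_over_gamma
            d2 = ddx * ddx + ddy * ddy
            if d2 > max_disp * max_disp:
                scale = max_disp / np.sqrt(d2)
                ddx *= scale
                ddy *= scale
            pos[i, 0] += ddx + noise[s, i, 0]
            pos[i, 1] += ddy + noise[s, i, 1]
            if not (np.isfinite(pos[i, 0]) and np.isfinite(pos[i, 1])):
                ok = False
        if not ok:
            return (2, s, -1, -1, n_pairs)
    return (0, n_steps, -1, -1, n_pairs)


@njit(cache=True)
def integrate_nve_chunk(
    pos,
    vel,
    ref_pos,
    pi,
    pj,
    ptype,
    n_pairs,
    bonds,
    bond_kappa,
    bond_r0,
    triples,
    tri_kappa,
    tri_phi0,
    area_idx,
    area_off,
    area_kappa,
    area_a0,
    excl,
    is_head,
    is_mem,
    n_steps,
    dt,
    skin,
    list_cutoff,
    u3,
    rcut_attr,
    eps_rep,
    sigma,
    forces,
):
    """Velocity-Verlet chunk with unit bead mass (validation mode).

    ``forces`` must hold F(t) for the entry configuration and holds F(t_end)
    on return.  Returns (err_code, err_step, err_i, err_j, n_pairs).
    """
    n = pos.shape[0]
    half_skin2 = (0.5 * skin) * (0.5 * skin)
    for s in range(n_steps):
        for i in range(n):
            vel[i, 0] += 0.5 * dt * forces[i, 0]
            vel[i, 1] += 0.5 * dt * forces[i, 1]
            pos[i, 0] += dt * vel[i, 0]
            pos[i, 1] += dt * vel[i, 1]
            if not (np.isfinite(pos[i, 0]) and np.isfinite(pos[i, 1])):
                return (2, s, -1, -1, n_pairs)

        maxd2 = 0.0
        for i in range(n):
            dx = pos[i, 0] - ref_pos[i, 0]
            dy = pos[i, 1] - ref_pos[i, 1]
            d2 = dx * dx + dy * dy
            if d2 > maxd2:
                maxd2 = d2
        if maxd2 > half_skin2:
            n_pairs = build_pairs(pos, list_cutoff, excl, is_head, is_mem, pi, pj, ptype)
            if n_pairs < 0:
                return (3, s, -1, -1, 0)
            for i in range(n):
                ref_pos[i, 0] = pos[i, 0]
                ref_pos[i, 1] = pos[i, 1]

        res = forces_energy(
            pos, bonds, bond_kappa, bond_r0, triples, tri_kappa, tri_phi0,
            area_idx, area_off, area_kappa, area_a0,
            pi, pj, ptype, n_pairs, u3, rcut_attr, eps_rep, sigma, forces,
        )
        if res[5] >= 0:
            return (1, s, res[5], res[6], n_pairs)

        for i in range(n):
            vel[i, 0] += 0.5 * dt * forces[i, 0]
            vel[i, 1] += 0.5 * dt * forces[i, 1]
    return (0, n_steps, -1, -1, n_pairs)
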