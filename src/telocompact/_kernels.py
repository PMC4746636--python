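"""Numba force/energy kernel.

One compiled routine evaluates every force term of the model (neighbor-list
non-bonded pairs, DNA bonds and bends, optional harmonic tethers) and
accumulates forces in place, returning the total potential energy.  The pair
list it receives has exclusions (intra-body pairs, DNA bonded neighbors)
already removed.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def compute_forces(
    pos,  # (N, 3) float64, unwrapped
    pi,  # (P,) int32 pair list
    pj,  # (P,) int32
    kinds,  # (N,) int8
    eps_table,  # (K, K) float64
    charges,  # (N,) float64
    sigma,
    delta,
    r_cut_lj,
    kappa,
    coulomb_scale,
    r_cut_yukawa,
    box,  # <= 0 means open boundaries
    bond_i,  # (B,) int32
    bond_j,
    bond_r0,
    k_bond,
    ang_mid,  # (A,) int32 middle bead of each bending triple (mid-1, mid, mid+1)
    k_bend,
    teth_idx,  # (T,) int32
    teth_anchor,  # (T, 3)
    teth_k,  # (T,)
    forces,  # (N, 3) output, zeroed here
):
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    energy = 0.0
    lj_cut = r_cut_lj + delta
    lj_cut2 = lj_cut * lj_cut
    yk_cut2 = r_cut_yukawa * r_cut_yukawa
    max_cut2 = lj_cut2 if lj_cut2 > yk_cut2 else yk_cut2
    sc6 = (sigma / r_cut_lj) ** 6
    shift = 4.0 * (sc6 * sc6 - sc6)

    for p in range(pi.shape[0]):
        a = pi[p]
        b = pj[p]
        dx = pos[a, 0] - pos[b, 0]
        dy = pos[a, 1] - pos[b, 1]
        dz = pos[a, 2] - pos[b, 2]
        if box > 0.0:
            dx -= box * np.round(dx / box)
            dy -= box * np.round(dy / box)
            dz -= box * np.round(dz / box)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= max_cut2:
            continue
        qq = charges[a] * charges[b]
        if r2 >= lj_cut2 and qq == 0.0:
            continue
        r = np.sqrt(r2)
        fr = 0.0  # radial force / r  (positive = repulsive)
        if r2 < lj_cut2:
            eps = eps_table[kinds[a], kinds[b]]
            x = r - delta
            if x < 0.05:
                x = 0.05  # clamped core; the step-size guard aborts real overlaps
            sr2 = (sigma / x) ** 2
            sr6 = sr2 * sr2 * sr2
            energy += 4.0 * eps * (sr6 * sr6 - sr6) - eps * shift
            fr += 4.0 * eps * (12.0 * sr6 * sr6 - 6.0 * sr6) / (x * r)
        if qq != 0.0 and r2 < yk_cut2:
            e_yk = coulomb_scale * qq * np.exp(-kappa * r) / r
            energy += e_yk
            fr += e_yk * (1.0 / r + kappa) / r
        if fr != 0.0:
            fx = fr * dx
            fy = fr * dy
            fz = fr * dz
            forces[a, 0] += fx
            forces[a, 1] += fy
            forces[a, 2] += fz
            forces[b, 0] -= fx
            forces[b, 1] -= fy
            forces[b, 2] -= fz

    for p in range(bond_i.shape[0]):
        a = bond_i[p]
        b = bond_j[p]
        dx = pos[a, 0] - pos[b, 0]
        dy = pos[a, 1] - pos[b, 1]
        dz = pos[a, 2] - pos[b, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        energy += 0.5 * k_bond * (r - bond_r0) ** 2
        if r > 1e-12:
            f = -k_bond * (r - bond_r0) / r
            forces[a, 0] += f * dx
            forces[a, 1] += f * dy
            forces[a, 2] += f * dz
            forces[b, 0] -= f * dx
            forces[b, 1] -= f * dy
            forces[b, 2] -= f * dz

    if k_bend > 0.0:
        for p in range(ang_mid.shape[0]):
            m = ang_mid[p]
            a = m - 1
            c = m + 1
            v1x = pos[m, 0] - pos[a, 0]
            v1y = pos[m, 1] - pos[a, 1]
            v1z = pos[m, 2] - pos[a, 2]
            v2x = pos[c, 0] - pos[m, 0]
            v2y = pos[c, 1] - pos[m, 1]
            v2z = pos[c, 2] - pos[m, 2]
            l1 = np.sqrt(v1x * v1x + v1y * v1y + v1z * v1z)
            l2 = np.sqrt(v2x * v2x + v2y * v2y + v2z * v2z)
            n1x, n1y, n1z = v1x / l1, v1y / l1, v1z / l1
            n2x, n2y, n2z = v2x / l2, v2y / l2, v2z / l2
            u = n1x * n2x + n1y * n2y + n1z * n2z
            if u > 1.0:
                u = 1.0
            elif u < -1.0:
                u = -1.0
            theta = np.arccos(u)
            energy += 0.5 * k_bend * theta * theta
            s = np.sqrt(1.0 - u * u)
            if s < 1e-9:
                continue  # collinear: gradient magnitude ~ k*theta -> 0
            coef = k_bend * theta / s
            # dtheta/dra = (n2 - u n1)/(l1 s); dtheta/drc = -(n1 - u n2)/(l2 s)
            gax = coef * (n2x - u * n1x) / l1
            gay = coef * (n2y - u * n1y) / l1
            gaz = coef * (n2z - u * n1z) / l1
            gcx = -coef * (n1x - u * n2x) / l2
            gcy = -coef * (n1y - u * n2y) / l2
            gcz = -coef * (n1z - u * n2z) / l2
            # force = -dE/dr
            forces[a, 0] -= gax
            forces[a, 1] -= gay
            forces[a, 2] -= gaz
            forces[c, 0] -= gcx
            forces[c, 1] -= gcy
            forces[c, 2] -= gcz
            forces[m, 0] += gax + gcx
            forces[m, 1] += gay + gcy
            forces[m, 2] += gaz + gcz

    for p in range(teth_idx.shape[0]):
        a = teth_idx[p]
        dx = pos[a, 0] - teth_anchor[p, 0]
        dy = pos[a, 1] - teth_anchor[p, 1]
        dz = pos[a, 2] - teth_anchor[p, 2]
        energy += 0.5 * teth_k[p] * (dx * dx + dy * dy + dz * dz)
        forces[a, 0] -= teth_k[p] * dx
        forces[a, 1] -= teth_k[p] * dy
        forces[a, 2] -= teth_k[p] * dz

    return energy


@njit(cache=True, fastmath=True)
def step_block(
    pos,  # (N, 3) all particles, updated in place
    dna_pos,  # (n_dna, 3) view-independent array, updated in place
    centers,  # (P, 3)
    quats,  # (P, 4) scalar-first
    site_offsets,  # (S, 3) body frame (shared by all bodies)
    n_dna,
    pi,
    pj,
    kinds,
    eps_table,
    charges,
    sigma,
    delta,
    r_cut_lj,
    kappa,
    coulomb_scale,
    r_cut_yukawa,
    box,
    bond_i,
    bond_j,
    bond_r0,
    k_bond,
    ang_mid,
    k_bend,
    teth_idx,
    teth_anchor,
    teth_k,
    forces,
    noise,  # (n_inner, ndof) standard normals (may be empty when noise off)
    prev_noise,  # (ndof,) carry for the Leimkuhler-Matthews average
    D_dt,
    Dr_dt,
    sig_t,
    sig_r,
    max_step,
    use_noise,
):
    """Advance ``n_inner = noise.shape[0]`` BD steps on a fixed pair list.

    Returns the largest deterministic per-step displacement (the caller
    aborts when it exceeds ``max_step``).  The Leimkuhler-Matthews noise
    carry in ``prev_noise`` is updated in place.
    """
    n_prot = centers.shape[0]
    n_sites = site_offsets.shape[0]
    per = 1 + n_sites
    n_inner = noise.shape[0]
    nd3 = 3 * n_dna
    worst = 0.0
    for it in range(n_inner):
        # site positions from rigid-body frames
        for b in range(n_prot):
            w, x, y, z = quats[b, 0], quats[b, 1], quats[b, 2], quats[b, 3]
            r00 = 1 - 2 * (y * y + z * z)
            r01 = 2 * (x * y - w * z)
            r02 = 2 * (x * z + w * y)
            r10 = 2 * (x * y + w * z)
            r11 = 1 - 2 * (x * x + z * z)
            r12 = 2 * (y * z - w * x)
            r20 = 2 * (x * z - w * y)
            r21 = 2 * (y * z + w * x)
            r22 = 1 - 2 * (x * x + y * y)
            base = n_dna + b * per
            pos[base, 0] = centers[b, 0]
            pos[base, 1] = centers[b, 1]
            pos[base, 2] = centers[b, 2]
            for s in range(n_sites):
                ox, oy, oz = site_offsets[s, 0], site_offsets[s, 1], site_offsets[s, 2]
                pos[base + 1 + s, 0] = centers[b, 0] + r00 * ox + r01 * oy + r02 * oz
                pos[base + 1 + s, 1] = centers[b, 1] + r10 * ox + r11 * oy + r12 * oz
                pos[base + 1 + s, 2] = centers[b, 2] + r20 * ox + r21 * oy + r22 * oz
        for i in range(n_dna):
            pos[i, 0] = dna_pos[i, 0]
            pos[i, 1] = dna_pos[i, 1]
            pos[i, 2] = dna_pos[i, 2]

        compute_forces(
            pos, pi, pj, kinds, eps_table, charges, sigma, delta, r_cut_lj,
            kappa, coulomb_scale, r_cut_yukawa, box, bond_i, bond_j, bond_r0,
            k_bond, ang_mid, k_bend, teth_idx, teth_anchor, teth_k, forces,
        )

        for i in range(n_dna):
            for d in range(3):
                disp = D_dt * forces[i, d]
                if abs(disp) > worst:
                    worst = abs(disp)
                if use_noise:
                    cur = noise[it, 3 * i + d]
                    disp += sig_t * 0.5 * (prev_noise[3 * i + d] + cur)
                    prev_noise[3 * i + d] = cur
                dna_pos[i, d] += disp

        for b in range(n_prot):
            base = n_dna + b * per
            fx = forces[base, 0]
            fy = forces[base, 1]
            fz = forces[base, 2]
            tx = 0.0
            ty = 0.0
            tz = 0.0
            for s in range(1, per):
                sfx = forces[base + s, 0]
                sfy = forces[base + s, 1]
                sfz = forces[base + s, 2]
                ax = pos[base + s, 0] - centers[b, 0]
                ay = pos[base + s, 1] - centers[b, 1]
                az = pos[base + s, 2] - centers[b, 2]
                fx += sfx
                fy += sfy
                fz += sfz
                tx += ay * sfz - az * sfy
                ty += az * sfx - ax * sfz
                tz += ax * sfy - ay * sfx
            ox = nd3 + 6 * b
            cdx = D_dt * fx
            cdy = D_dt * fy
            cdz = D_dt * fz
            m = max(abs(cdx), max(abs(cdy), abs(cdz)))
            if m > worst:
                worst = m
            rx = Dr_dt * tx
            ry = Dr_dt * ty
            rz = Dr_dt * tz
            if use_noise:
                for d in range(3):
                    cur = noise[it, ox + d]
                    if d == 0:
                        cdx += sig_t * 0.5 * (prev_noise[ox + d] + cur)
                    elif d == 1:
                        cdy += sig_t * 0.5 * (prev_noise[ox + d] + cur)
                    else:
                        cdz += sig_t * 0.5 * (prev_noise[ox + d] + cur)
                    prev_noise[ox + d] = cur
                for d in range(3):
                    cur = noise[it, ox + 3 + d]
                    inc = sig_r * 0.5 * (prev_noise[ox + 3 + d] + cur)
                    if d == 0:
                        rx += inc
                    elif d == 1:
                        ry += inc
                    else:
                        rz += inc
                    prev_noise[ox + 3 + d] = cur
            centers[b, 0] += cdx
            centers[b, 1] += cdy
            centers[b, 2] += cdz
            # quaternion increment for world-frame rotation vector (rx,ry,rz)
            ang = np.sqrt(rx * rx + ry * ry + rz * rz)
            half = 0.5 * ang
            if ang > 1e-12:
                scale = np.sin(half) / ang
            else:
                scale = 0.5
            dw = np.cos(half)
            dx_ = scale * rx
            dy_ = scale * ry
            dz_ = scale * rz
            aw, ax_, ay_, az_ = quats[b, 0], quats[b, 1], quats[b, 2], quats[b, 3]
            nw = dw * aw - dx_ * ax_ - dy_ * ay_ - dz_ * az_
            nx = dw * ax_ + dx_ * aw + dy_ * az_ - dz_ * ay_
            ny = dw * ay_ - dx_ * az_ + dy_ * aw + dz_ * ax_
            nz = dw * az_ + dx_ * ay_ - dy_ * ax_ + dz_ * aw
            norm = np.sqrt(nw * nw + nx * nx + ny * ny + nz * nz)
            quats[b, 0] = nw / norm
            quats[b, 1] = nx / norm
            quats[b, 2] = ny / norm
            quats[b, 3] = nz / norm

        if worst > max_step:
            return worst
    return worst
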