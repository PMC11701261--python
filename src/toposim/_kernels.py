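"""Numba kernels for the Langevin polymer dynamics.

Single-threaded, deterministic under an explicit seed.  The integrator is
the Langevin "middle" (BAOAB) splitting: half kick, half drift, exact
Ornstein-Uhlenbeck velocity update, half drift, new forces, half kick.
With friction gamma = 0 it reduces exactly to velocity-Verlet, which is the
NVE validation mode.  Nonbonded interactions run over a Verlet pair list
with a displacement-triggered rebuild; the backbone FENE bond carries its
own WCA core (bonded 1-2 pairs are excluded from the pair list), all other
pairs take WCA, the normalized truncated-shifted LJ attraction, or the
soft push-off potential depending on the stage.
"""

from __future__ import annotations

import numpy as np
from numba import njit

WCA_CUT = 2.0 ** (1.0 / 6.0)


@njit(cache=True, inline="always")
def _mi(d, L, periodic):
    if periodic and L > 0.0:
        d -= L * np.rint(d / L)
    return d


@njit(cache=True)
def build_pairs(pos, box, periodic, cutoff, n_chain):
    """All pairs within cutoff (minimum image), excluding bonded chain
    neighbors (i, i+1) below n_chain, whose WCA lives inside the FENE bond."""
    n = pos.shape[0]
    c2 = cutoff * cutoff
    count = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            if j == i + 1 and j < n_chain:
                continue
            dx = _mi(pos[i, 0] - pos[j, 0], box[0], periodic)
            dy = _mi(pos[i, 1] - pos[j, 1], box[1], periodic)
            dz = _mi(pos[i, 2] - pos[j, 2], box[2], periodic)
            if dx * dx + dy * dy + dz * dz < c2:
                count += 1
    pairs = np.empty((count, 2), dtype=np.int64)
    k = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            if j == i + 1 and j < n_chain:
                continue
            dx = _mi(pos[i, 0] - pos[j, 0], box[0], periodic)
            dy = _mi(pos[i, 1] - pos[j, 1], box[1], periodic)
            dz = _mi(pos[i, 2] - pos[j, 2], box[2], periodic)
            if dx * dx + dy * dy + dz * dz < c2:
                pairs[k, 0] = i
                pairs[k, 1] = j
                k += 1
    return pairs


@njit(cache=True)
def compute_forces(
    pos, f, box, periodic,
    fene_bonds, fene_k, fene_r0,
    harm_bonds, harm_k, harm_r0,
    n_chain, kappa,
    pairs, types, eps_mat, ljnorm, rc, soft_a,
    wall_k,
):
    """Fill f with forces; return index of an overstretched FENE bond, or -1."""
    n = pos.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0

    # FENE backbone (with its WCA core)
    r0sq = fene_r0 * fene_r0
    for b in range(fene_bonds.shape[0]):
        i = fene_bonds[b, 0]
        j = fene_bonds[b, 1]
        dx = _mi(pos[i, 0] - pos[j, 0], box[0], periodic)
        dy = _mi(pos[i, 1] - pos[j, 1], box[1], periodic)
        dz = _mi(pos[i, 2] - pos[j, 2], box[2], periodic)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= r0sq:
            return b
        r = np.sqrt(r2)
        fr = -fene_k * r / (1.0 - r2 / r0sq)  # FENE pull
        if r < WCA_CUT and r > 0.0:
            inv6 = 1.0 / (r2 * r2 * r2)
            fr += 24.0 * (2.0 * inv6 * inv6 - inv6) / r
        if r > 0.0:
            s = fr / r
            f[i, 0] += s * dx
            f[i, 1] += s * dy
            f[i, 2] += s * dz
            f[j, 0] -= s * dx
            f[j, 1] -= s * dy
            f[j, 2] -= s * dz

    # harmonic bonds (crumple, extruder, soft-stage backbone)
    for b in range(harm_bonds.shape[0]):
        i = harm_bonds[b, 0]
        j = harm_bonds[b, 1]
        dx = _mi(pos[i, 0] - pos[j, 0], box[0], periodic)
        dy = _mi(pos[i, 1] - pos[j, 1], box[1], periodic)
        dz = _mi(pos[i, 2] - pos[j, 2], box[2], periodic)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r > 0.0:
            s = -2.0 * harm_k[b] * (r - harm_r0[b]) / r
            f[i, 0] += s * dx
            f[i, 1] += s * dy
            f[i, 2] += s * dz
            f[j, 0] -= s * dx
            f[j, 1] -= s * dy
            f[j, 2] -= s * dz

    # Kratky-Porod bending on consecutive chain triplets
    if kappa > 0.0:
        for i in range(n_chain - 2):
            b1x = _mi(pos[i + 1, 0] - pos[i, 0], box[0], periodic)
            b1y = _mi(pos[i + 1, 1] - pos[i, 1], box[1], periodic)
            b1z = _mi(pos[i + 1, 2] - pos[i, 2], box[2], periodic)
            b2x = _mi(pos[i + 2, 0] - pos[i + 1, 0], box[0], periodic)
            b2y = _mi(pos[i + 2, 1] - pos[i + 1, 1], box[1], periodic)
            b2z = _mi(pos[i + 2, 2] - pos[i + 1, 2], box[2], periodic)
            l1 = np.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
            l2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
            if l1 == 0.0 or l2 == 0.0:
                continue
            d1x, d1y, d1z = b1x / l1, b1y / l1, b1z / l1
            d2x, d2y, d2z = b2x / l2, b2y / l2, b2z / l2
            c = d1x * d2x + d1y * d2y + d1z * d2z
            # U = kappa (1 - cos th), cos th = d1.d2 ; F = kappa * grad(cos th)
            g1x = (d2x - c * d1x) / l1
            g1y = (d2y - c * d1y) / l1
            g1z = (d2z - c * d1z) / l1
            g2x = (d1x - c * d2x) / l2
            g2y = (d1y - c * d2y) / l2
            g2z = (d1z - c * d2z) / l2
            f[i, 0] -= kappa * g1x
            f[i, 1] -= kappa * g1y
            f[i, 2] -= kappa * g1z
            f[i + 2, 0] += kappa * g2x
            f[i + 2, 1] += kappa * g2y
            f[i + 2, 2] += kappa * g2z
            f[i + 1, 0] += kappa * (g1x - g2x)
            f[i + 1, 1] += kappa * (g1y - g2y)
            f[i + 1, 2] += kappa * (g1z - g2z)

    # nonbonded pairs
    rc2 = rc * rc
    for p in range(pairs.shape[0]):
        i = pairs[p, 0]
        j = pairs[p, 1]
        dx = _mi(pos[i, 0] - pos[j, 0], box[0], periodic)
        dy = _mi(pos[i, 1] - pos[j, 1], box[1], periodic)
        dz = _mi(pos[i, 2] - pos[j, 2], box[2], periodic)
        r2 = dx * dx + dy * dy + dz * dz
        if soft_a > 0.0:
            if r2 < WCA_CUT * WCA_CUT:
                r = np.sqrt(r2)
                fr = soft_a * np.pi / WCA_CUT * np.sin(np.pi * r / WCA_CUT)
                if r > 1e-12:
                    s = fr / r
                    f[i, 0] += s * dx
                    f[i, 1] += s * dy
                    f[i, 2] += s * dz
                    f[j, 0] -= s * dx
                    f[j, 1] -= s * dy
                    f[j, 2] -= s * dz
            continue
        eps = eps_mat[types[i], types[j]]
        if eps == 0.0:
            if r2 < WCA_CUT * WCA_CUT and r2 > 0.0:
                inv6 = 1.0 / (r2 * r2 * r2)
                s = 24.0 * (2.0 * inv6 * inv6 - inv6) / r2
                f[i, 0] += s * dx
                f[i, 1] += s * dy
                f[i, 2] += s * dz
                f[j, 0] -= s * dx
                f[j, 1] -= s * dy
                f[j, 2] -= s * dz
        else:
            if r2 < rc2 and r2 > 0.0:
                inv6 = 1.0 / (r2 * r2 * r2)
                s = 4.0 * eps * ljnorm * (12.0 * inv6 * inv6 - 6.0 * inv6) / r2
                f[i, 0] += s * dx
                f[i, 1] += s * dy
                f[i, 2] += s * dz
                f[j, 0] -= s * dx
                f[j, 1] -= s * dy
                f[j, 2] -= s * dz

    # confining walls (non-periodic stages): harmonic restoring force
    if wall_k > 0.0 and not periodic:
        for i in range(n):
            for a in range(3):
                if pos[i, a] < 0.0:
                    f[i, a] += -wall_k * pos[i, a]
                elif pos[i, a] > box[a]:
                    f[i, a] += -wall_k * (pos[i, a] - box[a])
    return -1


@njit(cache=True)
def compute_potential(
    pos, box, periodic,
    fene_bonds, fene_k, fene_r0,
    harm_bonds, harm_k, harm_r0,
    n_chain, kappa,
    pairs, types, eps_mat, ljnorm, rc, soft_a,
    wall_k,
):
    """Total potential energy matching compute_forces term by term."""
    u = 0.0
    r0sq = fene_r0 * fene_r0
    for b in range(fene_bonds.shape[0]):
        i = fene_bonds[b, 0]
        j = fene_bonds[b, 1]
        dx = _mi(pos[i, 0] - pos[j, 0], box[0], periodic)
        dy = _mi(pos[i, 1] - pos[j, 1], box[1], periodic)
        dz = _mi(pos[i, 2] - pos[j, 2], box[2], periodic)
        r2 = dx * dx + dy * dy + dz * dz
        u += -0.5 * fene_k * r0sq * np.log(1.0 - r2 / r0sq)
        if r2 < WCA_CUT * WCA_CUT:
            inv6 = 1.0 / (r2 * r2 * r2)
            u += 4.0 * (inv6 * inv6 - inv6 + 0.25)
    for b in range(harm_bonds.shape[0]):
        i = harm_bonds[b, 0]
        j = harm_bonds[b, 1]
        dx = _mi(pos[i, 0] - pos[j, 0], box[0], periodic)
        dy = _mi(pos[i, 1] - pos[j, 1], box[1], periodic)
        dz = _mi(pos[i, 2] - pos[j, 2], box[2], periodic)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        u += harm_k[b] * (r - harm_r0[b]) ** 2
    if kappa > 0.0:
        for i in range(n_chain - 2):
            b1x = _mi(pos[i + 1, 0] - pos[i, 0], box[0], periodic)
            b1y = _mi(pos[i + 1, 1] - pos[i, 1], box[1], periodic)
            b1z = _mi(pos[i + 1, 2] - pos[i, 2], box[2], periodic)
            b2x = _mi(pos[i + 2, 0] - pos[i + 1, 0], box[0], periodic)
            b2y = _mi(pos[i + 2, 1] - pos[i + 1, 1], box[1], periodic)
            b2z = _mi(pos[i + 2, 2] - pos[i + 1, 2], box[2], periodic)
            l1 = np.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
            l2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
            if l1 == 0.0 or l2 == 0.0:
                continue
            c = (b1x * b2x + b1y * b2y + b1z * b2z) / (l1 * l2)
            u += kappa * (1.0 - c)
    rc2 = rc * rc
    shift = -(rc ** -12) + rc ** -6
    for p in range(pairs.shape[0]):
        i = pairs[p, 0]
        j = pairs[p, 1]
        dx = _mi(pos[i, 0] - pos[j, 0], box[0], periodic)
        dy = _mi(pos[i, 1] - pos[j, 1], box[1], periodic)
        dz = _mi(pos[i, 2] - pos[j, 2], box[2], periodic)
        r2 = dx * dx + dy * dy + dz * dz
        if soft_a > 0.0:
            if r2 < WCA_CUT * WCA_CUT:
                u += soft_a * (1.0 + np.cos(np.pi * np.sqrt(r2) / WCA_CUT))
            continue
        eps = eps_mat[types[i], types[j]]
        if eps == 0.0:
            if r2 < WCA_CUT * WCA_CUT:
                inv6 = 1.0 / (r2 * r2 * r2)
                u += 4.0 * (inv6 * inv6 - inv6 + 0.25)
        else:
            if r2 < rc2:
                inv6 = 1.0 / (r2 * r2 * r2)
                u += 4.0 * eps * ljnorm * (inv6 * inv6 - inv6 + shift)
    if wall_k > 0.0 and not periodic:
        n = pos.shape[0]
        for i in range(n):
            for a in range(3):
                if pos[i, a] < 0.0:
                    u += 0.5 * wall_k * pos[i, a] ** 2
                elif pos[i, a] > box[a]:
                    u += 0.5 * wall_k * (pos[i, a] - box[a]) ** 2
    return u


@njit(cache=True)
def run_chunk(
    pos, vel, n_steps, dt, gamma, kT, box, periodic,
    fene_bonds, fene_k, fene_r0,
    harm_bonds, harm_k, harm_r0,
    n_chain, kappa,
    types, eps_mat, ljnorm, rc,
    soft_a0, soft_a1,
    wall_k, use_nonbonded, skin,
    noise,
):
    """Integrate n_steps of BAOAB Langevin dynamics in place.

    `noise` must hold (n_steps, n, 3) standard normals when gamma > 0 (the
    caller generates them with a seeded numpy Generator, which is both
    faster than drawing inside the kernel and keeps all randomness under
    one seed).  Returns (-1, -1) on success, else (step, fene_bond_index)
    at the first FENE overstretch.  soft_a ramps linearly soft_a0 ->
    soft_a1 across the chunk (0 disables the soft potential).
    """
    n = pos.shape[0]
    f = np.zeros((n, 3))
    list_cut = rc + skin
    if use_nonbonded:
        pairs = build_pairs(pos, box, periodic, list_cut, n_chain)
    else:
        pairs = np.empty((0, 2), dtype=np.int64)
    pos_ref = pos.copy()

    c1 = np.exp(-gamma * dt) if gamma > 0.0 else 1.0
    c2 = np.sqrt((1.0 - c1 * c1) * kT) if gamma > 0.0 else 0.0

    soft_a = soft_a0
    bad = compute_forces(
        pos, f, box, periodic, fene_bonds, fene_k, fene_r0,
        harm_bonds, harm_k, harm_r0, n_chain, kappa,
        pairs, types, eps_mat, ljnorm, rc, soft_a, wall_k,
    )
    if bad >= 0:
        return 0, bad

    half = 0.5 * dt
    for step in range(n_steps):
        if n_steps > 1:
            soft_a = soft_a0 + (soft_a1 - soft_a0) * step / (n_steps - 1.0)
        for i in range(n):
            vel[i, 0] += half * f[i, 0]
            vel[i, 1] += half * f[i, 1]
            vel[i, 2] += half * f[i, 2]
            pos[i, 0] += half * vel[i, 0]
            pos[i, 1] += half * vel[i, 1]
            pos[i, 2] += half * vel[i, 2]
        if gamma > 0.0:
            for i in range(n):
                vel[i, 0] = c1 * vel[i, 0] + c2 * noise[step, i, 0]
                vel[i, 1] = c1 * vel[i, 1] + c2 * noise[step, i, 1]
                vel[i, 2] = c1 * vel[i, 2] + c2 * noise[step, i, 2]
        for i in range(n):
            pos[i, 0] += half * vel[i, 0]
            pos[i, 1] += half * vel[i, 1]
            pos[i, 2] += half * vel[i, 2]

        if use_nonbonded:
            max_d2 = 0.0
            for i in range(n):
                dx = pos[i, 0] - pos_ref[i, 0]
                dy = pos[i, 1] - pos_ref[i, 1]
                dz = pos[i, 2] - pos_ref[i, 2]
                d2 = dx * dx + dy * dy + dz * dz
                if d2 > max_d2:
                    max_d2 = d2
            if max_d2 > 0.25 * skin * skin:
                pairs = build_pairs(pos, box, periodic, list_cut, n_chain)
                pos_ref = pos.copy()

        bad = compute_forces(
            pos, f, box, periodic, fene_bonds, fene_k, fene_r0,
            harm_bonds, harm_k, harm_r0, n_chain, kappa,
            pairs, types, eps_mat, ljnorm, rc, soft_a, wall_k,
        )
        if bad >= 0:
            return step, bad
        for i in range(n):
            vel[i, 0] += half * f[i, 0]
            vel[i, 1] += half * f[i, 1]
            vel[i, 2] += half * f[i, 2]
    return -1, -1
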