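"""Numba kernels for the Langevin engine.

These mirror :mod:`knotloop.forcefield` exactly (same formulas, same
cutoffs) but run as compiled loops with a Verlet neighbour list for the
WCA term.  The BAOAB splitting is used for the Langevin update; with
``gamma = 0`` and zero noise it reduces to velocity Verlet.

Status codes returned by :func:`run_chunk`:

* ``STATUS_RUNNING``      — chunk exhausted, no terminating event
* ``STATUS_CIRCULARIZED`` — terminal sticky pair adhered this chunk
* ``STATUS_FENE_DIV``     — a FENE bond reached R0 (timestep too large)
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_RUNNING = 0
STATUS_CIRCULARIZED = 1
STATUS_FENE_DIV = 2

#: extra radius of the neighbour list beyond the WCA cutoff
NLIST_SKIN = 0.4


@njit(cache=True)
def _build_nlist(pos, rlist2, pairs_i, pairs_j):
    """All-pairs O(N^2) rebuild of the WCA neighbour list."""
    n = pos.shape[0]
    cap = pairs_i.shape[0]
    cnt = 0
    for i in range(n - 1):
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        for j in range(i + 1, n):
            dx = xi - pos[j, 0]
            dy = yi - pos[j, 1]
            dz = zi - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rlist2:
                if cnt >= cap:
                    return -1
                pairs_i[cnt] = i
                pairs_j[cnt] = j
                cnt += 1
    return cnt


@njit(cache=True)
def _forces(
    pos,
    f,
    pairs_i,
    pairs_j,
    npairs,
    sigma,
    epsilon,
    kappa_fene,
    r0_fene,
    u0,
    lam,
    kappa_bend,
    term_i,
    term_j,
    int_i,
    int_j,
    bonded,
):
    """Fill ``f`` with -grad H.  Returns a status code."""
    n = pos.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0

    sigma2 = sigma * sigma
    rc2 = 2.0 ** (1.0 / 3.0) * sigma2  # (2^(1/6) sigma)^2
    r02 = r0_fene * r0_fene

    # WCA over the neighbour list (includes bonded neighbours)
    for k in range(npairs):
        i = pairs_i[k]
        j = pairs_j[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rc2:
            s6 = (sigma2 / r2) ** 3
            g = 24.0 * epsilon * (2.0 * s6 * s6 - s6) / r2
            f[i, 0] += g * dx
            f[i, 1] += g * dy
            f[i, 2] += g * dz
            f[j, 0] -= g * dx
            f[j, 1] -= g * dy
            f[j, 2] -= g * dz

    # FENE springs: consecutive beads plus formed adhesion bonds
    for b in range(n - 1 + 2):
        if b < n - 1:
            i = b
            j = b + 1
        elif b == n - 1:
            if bonded[0] == 0 or term_i < 0:
                continue
            i = term_i
            j = term_j
        else:
            if bonded[1] == 0 or int_i < 0:
                continue
            i = int_i
            j = int_j
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        d2 = dx * dx + dy * dy + dz * dz
        if d2 >= r02:
            return STATUS_FENE_DIV
        g = -kappa_fene / (sigma2 * (1.0 - d2 / r02))
        f[i, 0] += g * dx
        f[i, 1] += g * dy
        f[i, 2] += g * dz
        f[j, 0] -= g * dx
        f[j, 1] -= g * dy
        f[j, 2] -= g * dz

    # sticky Gaussian wells (always active between designated pairs)
    rmin = 2.0 ** (1.0 / 6.0) * sigma
    router = rmin + 5.0 * sigma
    for p in range(2):
        if p == 0:
            i = term_i
            j = term_j
        else:
            i = int_i
            j = int_j
        if i < 0:
            continue
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if rmin <= r <= router:
            z = (r - rmin) / lam
            dgdr = u0 * (r - rmin) / (lam * lam) * np.exp(-0.5 * z * z)
            g = -dgdr / r
            f[i, 0] += g * dx
            f[i, 1] += g * dy
            f[i, 2] += g * dz
            f[j, 0] -= g * dx
            f[j, 1] -= g * dy
            f[j, 2] -= g * dz

    # bending (harmonic in the triplet angle, straight = minimum)
    if kappa_bend > 0.0:
        for k in range(1, n - 1):
            ax = pos[k - 1, 0] - pos[k, 0]
            ay = pos[k - 1, 1] - pos[k, 1]
            az = pos[k - 1, 2] - pos[k, 2]
            bx = pos[k + 1, 0] - pos[k, 0]
            by = pos[k + 1, 1] - pos[k, 1]
            bz = pos[k + 1, 2] - pos[k, 2]
            n1 = np.sqrt(ax * ax + ay * ay + az * az)
            n2 = np.sqrt(bx * bx + by * by + bz * bz)
            c = (ax * bx + ay * by + az * bz) / (n1 * n2)
            if c > 1.0:
                c = 1.0
            elif c < -1.0:
                c = -1.0
            theta = np.arccos(c)
            s2 = 1.0 - c * c
            if s2 > 1e-16:
                coef = kappa_bend * (theta - np.pi) / np.sqrt(s2)
            else:
                coef = -kappa_bend
            inv12 = 1.0 / (n1 * n2)
            ca = c / (n1 * n1)
            cb = c / (n2 * n2)
            f1x = coef * (bx * inv12 - ca * ax)
            f1y = coef * (by * inv12 - ca * ay)
            f1z = coef * (bz * inv12 - ca * az)
            f2x = coef * (ax * inv12 - cb * bx)
            f2y = coef * (ay * inv12 - cb * by)
            f2z = coef * (az * inv12 - cb * bz)
            f[k - 1, 0] += f1x
            f[k - 1, 1] += f1y
            f[k - 1, 2] += f1z
            f[k + 1, 0] += f2x
            f[k + 1, 1] += f2y
            f[k + 1, 2] += f2z
            f[k, 0] -= f1x + f2x
            f[k, 1] -= f1y + f2y
            f[k, 2] -= f1z + f2z

    return STATUS_RUNNING


@njit(cache=True)
def _pair_dist2(pos, i, j):
    dx = pos[i, 0] - pos[j, 0]
    dy = pos[i, 1] - pos[j, 1]
    dz = pos[i, 2] - pos[j, 2]
    return dx * dx + dy * dy + dz * dz


@njit(cache=True)
def run_chunk(
    pos,
    vel,
    noise,
    dt,
    gamma,
    kbt,
    mass,
    sigma,
    epsilon,
    kappa_fene,
    r0_fene,
    u0,
    lam,
    kappa_bend,
    term_i,
    term_j,
    int_i,
    int_j,
    bonded,
    capture2,
    pairs_i,
    pairs_j,
    pos_ref,
):
    """Integrate up to ``noise.shape[0]`` BAOAB steps in place.

    ``bonded`` is a mutable int8[2] array ``[termini, internal]``; adhesion
    is checked every step and a set flag is never cleared.  Returns
    ``(status, steps_done, ke_sum)`` where ``ke_sum`` accumulates the total
    kinetic energy summed over steps (for equipartition diagnostics).
    """
    n = pos.shape[0]
    n_steps = noise.shape[0]
    f = np.empty((n, 3))

    rlist = 2.0 ** (1.0 / 6.0) * sigma + NLIST_SKIN
    rlist2 = rlist * rlist
    half_skin2 = (0.5 * NLIST_SKIN) ** 2

    if gamma > 0.0:
        c1 = np.exp(-gamma * dt)
        c2 = np.sqrt(kbt / mass * (1.0 - c1 * c1))
    else:
        c1 = 1.0
        c2 = 0.0

    npairs = _build_nlist(pos, rlist2, pairs_i, pairs_j)
    if npairs < 0:
        return STATUS_FENE_DIV, 0, 0.0
    for i in range(n):
        pos_ref[i, 0] = pos[i, 0]
        pos_ref[i, 1] = pos[i, 1]
        pos_ref[i, 2] = pos[i, 2]

    status = _forces(
        pos, f, pairs_i, pairs_j, npairs,
        sigma, epsilon, kappa_fene, r0_fene, u0, lam, kappa_bend,
        term_i, term_j, int_i, int_j, bonded,
    )
    if status != STATUS_RUNNING:
        return status, 0, 0.0

    half_dt = 0.5 * dt
    inv_m = 1.0 / mass
    ke_sum = 0.0

    for step in range(n_steps):
        # B
        for i in range(n):
            vel[i, 0] += half_dt * f[i, 0] * inv_m
            vel[i, 1] += half_dt * f[i, 1] * inv_m
            vel[i, 2] += half_dt * f[i, 2] * inv_m
        # A
        for i in range(n):
            pos[i, 0] += half_dt * vel[i, 0]
            pos[i, 1] += half_dt * vel[i, 1]
            pos[i, 2] += half_dt * vel[i, 2]
        # O
        if gamma > 0.0:
            for i in range(n):
                vel[i, 0] = c1 * vel[i, 0] + c2 * noise[step, i, 0]
                vel[i, 1] = c1 * vel[i, 1] + c2 * noise[step, i, 1]
                vel[i, 2] = c1 * vel[i, 2] + c2 * noise[step, i, 2]
        # A
        for i in range(n):
            pos[i, 0] += half_dt * vel[i, 0]
            pos[i, 1] += half_dt * vel[i, 1]
            pos[i, 2] += half_dt * vel[i, 2]

        # neighbour-list validity
        max_disp2 = 0.0
        for i in range(n):
            dx = pos[i, 0] - pos_ref[i, 0]
            dy = pos[i, 1] - pos_ref[i, 1]
            dz = pos[i, 2] - pos_ref[i, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > max_disp2:
                max_disp2 = d2
        if max_disp2 > half_skin2:
            npairs = _build_nlist(pos, rlist2, pairs_i, pairs_j)
            if npairs < 0:
                return STATUS_FENE_DIV, step + 1, ke_sum
            for i in range(n):
                pos_ref[i, 0] = pos[i, 0]
                pos_ref[i, 1] = pos[i, 1]
                pos_ref[i, 2] = pos[i, 2]

        # B with fresh forces
        status = _forces(
            pos, f, pairs_i, pairs_j, npairs,
            sigma, epsilon, kappa_fene, r0_fene, u0, lam, kappa_bend,
            term_i, term_j, int_i, int_j, bonded,
        )
        if status != STATUS_RUNNING:
            return status, step + 1, ke_sum
        for i in range(n):
            vel[i, 0] += half_dt * f[i, 0] * inv_m
            vel[i, 1] += half_dt * f[i, 1] * inv_m
            vel[i, 2] += half_dt * f[i, 2] * inv_m

        ke = 0.0
        for i in range(n):
            ke += (
                vel[i, 0] * vel[i, 0]
                + vel[i, 1] * vel[i, 1]
                + vel[i, 2] * vel[i, 2]
            )
        ke_sum += 0.5 * mass * ke

        # permanent adhesion: internal pair first, then the terminating
        # terminal pair
        if int_i >= 0 and bonded[1] == 0:
            if _pair_dist2(pos, int_i, int_j) <= capture2:
                bonded[1] = 1
        if term_i >= 0 and bonded[0] == 0:
            if _pair_dist2(pos, term_i, term_j) <= capture2:
                bonded[0] = 1
                return STATUS_CIRCULARIZED, step + 1, ke_sum

    return STATUS_RUNNING, n_steps, ke_sum
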