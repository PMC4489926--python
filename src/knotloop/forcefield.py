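"""Potential-energy terms of the sticky bead-spring chain and their forces.

The Hamiltonian is the sum of four terms::

    H = U_WCA + U_FENE + U_stick + U_bend

* ``U_WCA``  — purely repulsive Weeks-Chandler-Andersen excluded volume
  acting between every distinct bead pair (bonded neighbours included),
  truncated at ``2^(1/6)*sigma`` and shifted so it vanishes there.
* ``U_FENE`` — finitely extensible nonlinear elastic springs between
  consecutive beads (and between an adhered sticky pair once it has bonded),
  diverging at the maximum extension ``R0``.
* ``U_stick`` — a deep, short-ranged attractive Gaussian well between the
  two designated adhesive pairs only: the termini and the internal pair.
  It is centred on the WCA minimum and truncated ``5*sigma`` further out.
* ``U_bend`` — harmonic penalty on the angle of each consecutive bead
  triplet, minimal for straight triplets; absent for the flexible regime.

Functions here are straightforward numpy reference implementations; the
simulation engine uses numerically identical numba kernels
(:mod:`knotloop._kernels`) for speed.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np

from .params import ModelParams, WCA_CUTOFF_FACTOR
from .state import ChainState

__all__ = [
    "wca_pair_energy",
    "fene_bond_energy",
    "sticky_pair_energy",
    "bending_energy",
    "total_energy",
    "forces",
    "FeneDivergenceError",
]


class FeneDivergenceError(FloatingPointError):
    """A FENE bond reached or exceeded its maximum extension R0.

    During dynamics this signals a broken bond, i.e. a timestep too large
    for the stiffness of the potential.
    """


# ---------------------------------------------------------------------------
# scalar pair/triplet terms
# ---------------------------------------------------------------------------

def wca_pair_energy(r: float, params: ModelParams) -> float:
    """WCA (truncated-shifted Lennard-Jones) energy of one bead pair.

    ``4*eps*[(sigma/r)^12 - (sigma/r)^6 + 1/4]`` for ``r <= 2^(1/6)*sigma``,
    exactly zero beyond the cutoff.
    """
    if r <= 0:
        raise ValueError("pair distance must be positive")
    if r >= params.wca_cutoff:
        return 0.0
    s6 = (params.sigma / r) ** 6
    return 4.0 * params.epsilon * (s6 * s6 - s6 + 0.25)


def fene_bond_energy(d: float, params: ModelParams) -> float:
    """FENE spring energy ``-(k/2)(R0/sigma)^2 ln[1-(d/R0)^2]``.

    Monotone increasing in ``d`` and divergent as ``d -> R0``.
    """
    if d < 0:
        raise ValueError("bond length must be non-negative")
    if d >= params.r0_fene:
        raise FeneDivergenceError(
            f"FENE bond length {d:.6g} >= R0 = {params.r0_fene:.6g}"
        )
    x = d / params.r0_fene
    pref = 0.5 * params.kappa_fene * (params.r0_fene / params.sigma) ** 2
    return -pref * np.log1p(-x * x)


def sticky_pair_energy(r: float, params: ModelParams) -> float:
    """Adhesive Gaussian well between one designated sticky pair.

    ``-U0 * exp(-(r - 2^(1/6)*sigma)^2 / (2*lambda^2))`` on the shell
    ``2^(1/6)*sigma <= r <= (2^(1/6)+5)*sigma`` and zero outside it.  The
    well applies only between the terminal pair and between the internal
    pair — never across pairs.
    """
    if r <= 0:
        raise ValueError("pair distance must be positive")
    rmin = params.wca_cutoff
    if r < rmin or r > params.sticky_outer_cutoff:
        return 0.0
    z = (r - rmin) / params.lambda_sticky
    return -params.u0_sticky * np.exp(-0.5 * z * z)


def bending_energy(theta: float, params: ModelParams) -> float:
    """Harmonic bending energy ``(kappa_bend/2)(theta - pi)^2`` of one triplet.

    ``theta`` is the angle at the central bead; straight triplets
    (``theta = pi``) cost nothing, and the flexible regime
    (``kappa_bend = 0``) costs nothing everywhere.
    """
    return 0.5 * params.kappa_bend * (theta - np.pi) ** 2


# ---------------------------------------------------------------------------
# whole-chain energy and forces
# ---------------------------------------------------------------------------

def _bond_list(state: ChainState, params: ModelParams) -> list:
    """Consecutive FENE bonds plus any adhesion bonds currently formed."""
    bonds = [(i, i + 1) for i in range(params.n_beads - 1)]
    if state.bonded_termini and params.sticky_terminal_pair is not None:
        bonds.append(tuple(params.sticky_terminal_pair))
    if state.bonded_internal and params.sticky_internal_pair is not None:
        bonds.append(tuple(params.sticky_internal_pair))
    return bonds


def _sticky_pairs(params: ModelParams) -> list:
    pairs = []
    if params.sticky_terminal_pair is not None:
        pairs.append(tuple(params.sticky_terminal_pair))
    if params.sticky_internal_pair is not None:
        pairs.append(tuple(params.sticky_internal_pair))
    return pairs


def total_energy(state: ChainState, params: ModelParams) -> float:
    """Total potential energy of a chain state.

    The WCA sum runs over unordered distinct pairs counted once (the
    conventional reading of the symmetric double sum with prefactor 1/2).
    """
    pos = np.asarray(state.positions, dtype=float)
    n = params.n_beads

    # pairwise distances, upper triangle
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((diff * diff).sum(axis=-1))
    iu, ju = np.triu_indices(n, k=1)
    r = dist[iu, ju]

    # WCA over all unordered pairs
    rc = params.wca_cutoff
    inside = r < rc
    s6 = (params.sigma / r[inside]) ** 6
    e_wca = float(np.sum(4.0 * params.epsilon * (s6 * s6 - s6 + 0.25)))

    # FENE over chain bonds + formed adhesion bonds
    e_fene = 0.0
    for i, j in _bond_list(state, params):
        e_fene += fene_bond_energy(dist[i, j], params)

    # sticky Gaussian between the designated pairs only
    e_stick = 0.0
    for i, j in _sticky_pairs(params):
        e_stick += sticky_pair_energy(dist[i, j], params)

    # bending over interior triplets
    e_bend = 0.0
    if params.kappa_bend > 0:
        b = pos[1:] - pos[:-1]
        bn = b / np.linalg.norm(b, axis=1, keepdims=True)
        cos_t = np.clip((bn[:-1] * bn[1:]).sum(axis=1), -1.0, 1.0)
        # angle at the central bead: pi when the triplet is straight
        theta = np.pi - np.arccos(cos_t)
        e_bend = float(np.sum(0.5 * params.kappa_bend * (theta - np.pi) ** 2))

    return e_wca + e_fene + e_stick + e_bend


def forces(state: ChainState, params: ModelParams) -> np.ndarray:
    """Analytic forces ``F = -grad H`` on every bead, shape (N, 3).

    Each term's force is continuous at its cutoff: the WCA force vanishes at
    ``2^(1/6)*sigma``, the Gaussian adhesion force vanishes at both edges of
    its shell, and the bending force has a finite straight-triplet limit.
    """
    pos = np.asarray(state.positions, dtype=float)
    n = params.n_beads
    f = np.zeros_like(pos)

    # WCA: dV/dr = -24 eps/r * (2 (sigma/r)^12 - (sigma/r)^6)
    diff = pos[:, None, :] - pos[None, :, :]
    dist2 = (diff * diff).sum(axis=-1)
    np.fill_diagonal(dist2, np.inf)
    rc2 = params.wca_cutoff**2
    ii, jj = np.nonzero(np.triu(dist2 < rc2, k=1))
    for i, j in zip(ii, jj):
        r2 = dist2[i, j]
        s6 = (params.sigma**2 / r2) ** 3
        fr_over_r = 24.0 * params.epsilon * (2.0 * s6 * s6 - s6) / r2
        fv = fr_over_r * diff[i, j]
        f[i] += fv
        f[j] -= fv

    # FENE: dU/dd = kappa * d / (sigma^2 (1-(d/R0)^2))
    for i, j in _bond_list(state, params):
        d2 = dist2[i, j]
        d = np.sqrt(d2)
        if d >= params.r0_fene:
            raise FeneDivergenceError(
                f"FENE bond ({i},{j}) length {d:.6g} >= R0"
            )
        denom = 1.0 - (d / params.r0_fene) ** 2
        fr_over_r = -params.kappa_fene / (params.sigma**2 * denom)
        fv = fr_over_r * diff[i, j]
        f[i] += fv
        f[j] -= fv

    # sticky Gaussian: dG/dr = U0 (r - rmin)/lambda^2 exp(...)
    rmin = params.wca_cutoff
    for i, j in _sticky_pairs(params):
        r = np.sqrt(dist2[i, j])
        if rmin <= r <= params.sticky_outer_cutoff:
            z = (r - rmin) / params.lambda_sticky
            dgdr = (
                params.u0_sticky
                * (r - rmin)
                / params.lambda_sticky**2
                * np.exp(-0.5 * z * z)
            )
            fv = -dgdr * diff[i, j] / r
            f[i] += fv
            f[j] -= fv

    # bending
    if params.kappa_bend > 0:
        f += _bending_forces(pos, params.kappa_bend)

    return f


def _bending_forces(pos: np.ndarray, kappa: float) -> np.ndarray:
    """Forces of the harmonic-angle term, with a stable straight-triplet limit.

    With ``theta`` the angle at the central bead, ``dU/dtheta = kappa*(theta-pi)``
    vanishes at ``theta = pi`` while ``dtheta/dr`` carries a ``1/sin(theta)``
    factor; their product approaches the finite limit ``kappa`` and is
    evaluated via a guarded ratio near straightness.
    """
    n = len(pos)
    f = np.zeros_like(pos)
    for k in range(1, n - 1):
        r1 = pos[k - 1] - pos[k]
        r2 = pos[k + 1] - pos[k]
        n1 = np.linalg.norm(r1)
        n2 = np.linalg.norm(r2)
        c = float(np.dot(r1, r2) / (n1 * n2))
        c = min(1.0, max(-1.0, c))
        # theta is the angle between the two arms at the central bead;
        # a straight triplet has c = -1, theta = pi.
        theta = np.arccos(c)
        s = np.sqrt(max(1.0 - c * c, 0.0))
        # F_i = kappa*(theta - pi)/sin(theta) * dc/dr_i ; the prefactor has
        # the finite straight-triplet limit -kappa.
        if s > 1e-8:
            coef = kappa * (theta - np.pi) / s
        else:
            coef = -kappa
        d_c_d1 = r2 / (n1 * n2) - c * r1 / (n1 * n1)
        d_c_d2 = r1 / (n1 * n2) - c * r2 / (n2 * n2)
        f1 = coef * d_c_d1
        f2 = coef * d_c_d2
        f[k - 1] += f1
        f[k + 1] += f2
        f[k] -= f1 + f2
    return f
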