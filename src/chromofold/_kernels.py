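"""Numba-compiled inner loops for the Monte Carlo folding stage.

The Metropolis sweep moves one bead at a time, so it cannot be vectorised;
this module carries a scalar re-implementation of the bead-pair energies
(kept in lock-step with :mod:`chromofold.forcefield`, enforced by a
cross-check test) and a whole-sweep kernel. RNG state is numba's own
Mersenne-Twister, seeded per call, so sweeps are reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_BIG = 1e30  # stands in for +inf (a move that would break a FENE bond)


@njit(cache=True)
def _wca_e(r2: float, eps: float, sigma: float) -> float:
    """WCA energy from the squared separation; zero beyond 2^(1/6) sigma."""
    if r2 > 2.0 ** (1.0 / 3.0) * sigma * sigma:
        return 0.0
    sr6 = (sigma * sigma / r2) ** 3
    return 4.0 * eps * (sr6 * sr6 - sr6 + 0.25)


@njit(cache=True)
def _bond_e(r: float, kappa: float, eps_star: float, sigma: float, R0: float) -> float:
    """FENE + WCA bond energy; _BIG if the bond would exceed R0."""
    if r >= R0 or r <= 0.0:
        return _BIG
    x = (r / R0) ** 2
    return -0.5 * kappa * R0 * R0 * np.log(1.0 - x) + _wca_e(r * r, eps_star, sigma)


@njit(cache=True)
def _bead_energy(
    pos: np.ndarray,
    b: int,
    x: np.ndarray,
    kappa: float,
    eps_star: float,
    sigma: float,
    R0: float,
    eps: float,
    K_r: float,
    r0_r: float,
    restr_ptr: np.ndarray,
    restr_idx: np.ndarray,
) -> float:
    """Energy of every pair term involving bead ``b`` placed at ``x``."""
    n = pos.shape[0]
    e = 0.0
    for nb in (b - 1, b + 1):
        if 0 <= nb < n:
            dx = x[0] - pos[nb, 0]
            dy = x[1] - pos[nb, 1]
            dz = x[2] - pos[nb, 2]
            e += _bond_e(np.sqrt(dx * dx + dy * dy + dz * dz), kappa, eps_star, sigma, R0)
            if e >= _BIG:
                return _BIG
    cut2 = 2.0 ** (1.0 / 3.0) * sigma * sigma
    for j in range(n):
        if j >= b - 1 and j <= b + 1:
            continue
        dx = x[0] - pos[j, 0]
        dy = x[1] - pos[j, 1]
        dz = x[2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < cut2:
            e += _wca_e(r2, eps, sigma)
    for k in range(restr_ptr[b], restr_ptr[b + 1]):
        j = restr_idx[k]
        dx = x[0] - pos[j, 0]
        dy = x[1] - pos[j, 1]
        dz = x[2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        e += K_r * (r - r0_r) * (r - r0_r)
    return e


@njit(cache=True)
def mc_sweep(
    pos: np.ndarray,
    move_sigma: float,
    beta: float,
    greedy: bool,
    kappa: float,
    eps_star: float,
    sigma: float,
    R0: float,
    eps: float,
    K_r: float,
    r0_r: float,
    restr_ptr: np.ndarray,
    restr_idx: np.ndarray,
    seed: int,
) -> int:
    """One Metropolis sweep: N random single-bead Gaussian trial moves.

    ``restr_ptr``/``restr_idx`` are a CSR adjacency of the currently active
    restraints (each pair listed under both beads). ``greedy`` accepts only
    downhill moves (the zero-temperature polish). Returns the number of
    accepted moves; mutates ``pos`` in place.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    accepted = 0
    x = np.empty(3)
    for _ in range(n):
        b = np.random.randint(0, n)
        x[0] = pos[b, 0] + move_sigma * np.random.standard_normal()
        x[1] = pos[b, 1] + move_sigma * np.random.standard_normal()
        x[2] = pos[b, 2] + move_sigma * np.random.standard_normal()
        e_old = _bead_energy(
            pos, b, pos[b], kappa, eps_star, sigma, R0, eps, K_r, r0_r, restr_ptr, restr_idx
        )
        e_new = _bead_energy(
            pos, b, x, kappa, eps_star, sigma, R0, eps, K_r, r0_r, restr_ptr, restr_idx
        )
        if e_new >= _BIG:
            continue  # would break the chain: always rejected
        de = e_new - e_old
        if de <= 0.0:
            ok = True
        elif greedy:
            ok = False
        else:
            ok = np.random.random() < np.exp(-beta * de)
        if ok:
            pos[b, 0] = x[0]
            pos[b, 1] = x[1]
            pos[b, 2] = x[2]
            accepted += 1
    return accepted
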