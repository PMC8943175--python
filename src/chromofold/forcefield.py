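"""Bead-spring force field in reduced (Lennard-Jones) units.

The chromosome is a linear chain of beads. Three interactions act on it:

* **Bonded** (consecutive beads): a FENE spring,
  ``U = -1/2 kappa R0^2 ln(1 - (r/R0)^2)``, plus the purely repulsive
  Weeks-Chandler-Andersen (WCA) core, i.e. the Lennard-Jones potential
  truncated and shifted at its minimum ``2^(1/6) sigma``. With the default
  parameters (``kappa = 30 eps*/sigma^2``, ``R0 = 20 sigma``) the combined
  bond has its minimum at 0.99 sigma while remaining extensible to 20 sigma.
* **Nonbonded** (all other pairs within the cutoff): the WCA core only —
  excluded volume without attraction.
* **Restraint** (selected Hi-C contact pairs): a harmonic well
  ``U = K (r - r0)^2`` with ``K = 1 eps/sigma^2`` and rest length
  ``r0 = 2.2 sigma``, pulling contacting loci together in 3D.

Everything is dimensionless: sigma is the unit of length, eps the unit of
energy, and with unit mass the time unit is ``tau = sigma * sqrt(m/eps)``.
All functions accept scalar or ndarray separations and are consistent with
their analytic radial derivatives (``force = -dU/dr``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .errors import ConfigError, PotentialDomainError

__all__ = [
    "ForceFieldParams",
    "bonded_energy",
    "bonded_force",
    "nonbonded_energy",
    "nonbonded_force",
    "restraint_energy",
    "restraint_force",
    "equilibrium_bond_length",
    "system_energy_forces",
]

#: Reduced-unit position of the Lennard-Jones minimum; the WCA cutoff.
WCA_CUTOFF_FACTOR: float = 2.0 ** (1.0 / 6.0)


@dataclass(frozen=True)
class ForceFieldParams:
    """Force-field constants in reduced units.

    Lengths (``R0``, ``r0``) are multiples of ``sigma``; spring constants
    are in ``eps*/sigma^2`` (``kappa``) and ``eps/sigma^2`` (``K``).
    """

    sigma: float = 1.0
    epsilon: float = 1.0
    epsilon_star: float = 1.0
    kappa: float = 30.0
    R0: float = 20.0
    K: float = 1.0
    r0: float = 2.2

    def __post_init__(self) -> None:
        for name in ("sigma", "epsilon", "epsilon_star", "kappa", "R0", "K", "r0"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ConfigError(f"force-field parameter {name}={v} must be finite and >= 0")
        for name in ("sigma", "kappa", "R0", "K", "r0"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"force-field parameter {name} must be strictly positive")
        if self.R0 * self.sigma <= self.lj_cutoff:
            raise ConfigError(
                f"maximum bond extension R0={self.R0} sigma must exceed the "
                f"WCA cutoff 2^(1/6) sigma"
            )

    @property
    def lj_cutoff(self) -> float:
        """Nonbonded cutoff ``2^(1/6) sigma`` in absolute length units."""
        return WCA_CUTOFF_FACTOR * self.sigma


def _as_array(r) -> tuple[np.ndarray, bool]:
    arr = np.asarray(r, dtype=float)
    return arr, arr.ndim == 0


def _wca(r: np.ndarray, eps: float, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """WCA energy and radial derivative dU/dr, zero beyond 2^(1/6) sigma."""
    inside = r <= WCA_CUTOFF_FACTOR * sigma
    e = np.zeros_like(r)
    dudr = np.zeros_like(r)
    if np.any(inside):
        ri = r[inside]
        sr6 = (sigma / ri) ** 6
        sr12 = sr6 * sr6
        e[inside] = 4.0 * eps * (sr12 - sr6 + 0.25)
        dudr[inside] = 4.0 * eps * (-12.0 * sr12 + 6.0 * sr6) / ri
    return e, dudr


def _fene(r: np.ndarray, p: ForceFieldParams) -> tuple[np.ndarray, np.ndarray]:
    """FENE energy and dU/dr; caller guarantees 0 < r < R0*sigma.

    The spring constant is expressed in units of the system energy (one
    reduced unit, equal to the bonded core strength eps* at the defaults),
    scaled by ``epsilon`` so the whole force field shares one energy unit;
    ``epsilon_star`` only scales the bonded repulsive core.
    """
    R0 = p.R0 * p.sigma
    k = p.kappa * p.epsilon / p.sigma**2
    x = (r / R0) ** 2
    e = -0.5 * k * R0**2 * np.log1p(-x)
    dudr = k * r / (1.0 - x)
    return e, dudr


def _check_bond_domain(r: np.ndarray, p: ForceFieldParams, label: str = "bond") -> None:
    R0 = p.R0 * p.sigma
    bad_low = r <= 0
    bad_high = r >= R0
    if np.any(bad_low | bad_high):
        bad = np.atleast_1d(r)[np.atleast_1d(bad_low | bad_high)]
        raise PotentialDomainError(
            f"{label} separation r={bad[0]:g} sigma outside the FENE domain "
            f"(0, R0={R0:g}); the chain would be broken"
        )


def bonded_energy(r, p: ForceFieldParams = ForceFieldParams()):
    """Energy of a chain bond: FENE spring plus WCA repulsive core (in eps).

    Diverges logarithmically as r -> R0; raises
    :class:`PotentialDomainError` outside (0, R0).
    """
    arr, scalar = _as_array(r)
    _check_bond_domain(arr, p)
    e_f, _ = _fene(arr, p)
    e_w, _ = _wca(arr, p.epsilon_star, p.sigma)
    out = e_f + e_w
    return float(out) if scalar else out


def bonded_force(r, p: ForceFieldParams = ForceFieldParams()):
    """Signed radial bond force ``-dU/dr`` in eps/sigma (negative pulls inward).

    Zero at the equilibrium bond length (0.99 sigma with defaults).
    """
    arr, scalar = _as_array(r)
    _check_bond_domain(arr, p)
    _, d_f = _fene(arr, p)
    _, d_w = _wca(arr, p.epsilon_star, p.sigma)
    out = -(d_f + d_w)
    return float(out) if scalar else out


def nonbonded_energy(r, p: ForceFieldParams = ForceFieldParams()):
    """WCA excluded-volume energy between non-bonded beads (in eps).

    ``4 eps [(sigma/r)^12 - (sigma/r)^6 + 1/4]`` for r <= 2^(1/6) sigma,
    exactly zero beyond; energy and force are continuous at the cutoff.
    """
    arr, scalar = _as_array(r)
    if np.any(arr <= 0):
        raise PotentialDomainError("nonbonded separation must be > 0")
    e, _ = _wca(arr, p.epsilon, p.sigma)
    return float(e) if scalar else e


def nonbonded_force(r, p: ForceFieldParams = ForceFieldParams()):
    """Signed radial WCA force ``-dU/dr`` in eps/sigma; >= 0 (purely repulsive)."""
    arr, scalar = _as_array(r)
    if np.any(arr <= 0):
        raise PotentialDomainError("nonbonded separation must be > 0")
    _, d = _wca(arr, p.epsilon, p.sigma)
    out = -d
    return float(out) if scalar else out


def restraint_energy(r, p: ForceFieldParams = ForceFieldParams()):
    """Harmonic Hi-C restraint energy ``K (r - r0)^2`` (in eps), symmetric about r0."""
    arr, scalar = _as_array(r)
    K = p.K * p.epsilon / p.sigma**2
    out = K * (arr - p.r0 * p.sigma) ** 2
    return float(out) if scalar else out


def restraint_force(r, p: ForceFieldParams = ForceFieldParams()):
    """Signed radial restraint force ``-2K (r - r0)`` in eps/sigma."""
    arr, scalar = _as_array(r)
    K = p.K * p.epsilon / p.sigma**2
    out = -2.0 * K * (arr - p.r0 * p.sigma)
    return float(out) if scalar else out


def equilibrium_bond_length(p: ForceFieldParams = ForceFieldParams(), xtol: float = 1e-9) -> float:
    """Locate the minimum of the bonded potential by bracketed root-finding.

    Searches for the zero of :func:`bonded_force` in
    ``(0.5 sigma, 2^(1/6) sigma)`` — beyond the cutoff the bond is pure
    FENE and strictly attractive, so any minimum lies inside the WCA core.
    With the default parameters the result is 0.99 sigma (two decimals).

    Raises :class:`PotentialDomainError` if the force does not change sign
    in the bracket (e.g. the WCA core disabled, leaving a monotone FENE
    spring whose energy infimum sits at r -> 0).
    """
    lo, hi = 0.5 * p.sigma, p.lj_cutoff * (1.0 - 1e-12)
    f_lo, f_hi = bonded_force(lo, p), bonded_force(hi, p)
    if f_lo * f_hi > 0:
        raise PotentialDomainError(
            "bonded force has no zero in (0.5 sigma, 2^(1/6) sigma): the bonded "
            "potential is monotone there (is the repulsive core disabled?)"
        )
    return float(brentq(lambda r: bonded_force(r, p), lo, hi, xtol=xtol * p.sigma))


def _pair_accumulate(
    forces: np.ndarray,
    pos: np.ndarray,
    i: np.ndarray,
    j: np.ndarray,
    dudr: np.ndarray,
    r: np.ndarray,
) -> None:
    """Scatter pair forces -dU/dr * rhat onto beads i and j (Newton's third law)."""
    rhat = (pos[i] - pos[j]) / r[:, None]
    f = -dudr[:, None] * rhat
    np.add.at(forces, i, f)
    np.add.at(forces, j, -f)


def system_energy_forces(chain, restraints=None, p: ForceFieldParams = ForceFieldParams()):
    """Total energy (eps) and per-bead force vectors (eps/sigma) of a conformation.

    ``chain`` may be a :class:`~chromofold.chain_init.BeadChain` or a bare
    (N, 3) coordinate array. Nonbonded WCA pairs are found with a k-d tree
    at the cutoff and exclude directly bonded neighbours (the bonded term
    already carries that repulsion); restrained pairs feel both the
    harmonic well and, if close enough, the WCA core.
    """
    pos = np.asarray(getattr(chain, "positions", chain), dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 3:
        raise ConfigError("chain positions must be an (N, 3) array")
    n = pos.shape[0]
    forces = np.zeros_like(pos)
    energy = 0.0

    if n >= 2:
        bond_vec = pos[:-1] - pos[1:]
        r = np.linalg.norm(bond_vec, axis=1)
        bad = (r <= 0) | (r >= p.R0 * p.sigma)
        if np.any(bad):
            k = int(np.argmax(bad))
            raise PotentialDomainError(
                f"bond {k}-{k + 1} has length {r[k]:g} sigma, outside (0, R0={p.R0 * p.sigma:g})"
            )
        e_f, d_f = _fene(r, p)
        e_w, d_w = _wca(r, p.epsilon_star, p.sigma)
        energy += float(np.sum(e_f + e_w))
        i = np.arange(n - 1)
        _pair_accumulate(forces, pos, i, i + 1, d_f + d_w, r)

        tree = cKDTree(pos)
        pairs = tree.query_pairs(p.lj_cutoff, output_type="ndarray")
        if pairs.size:
            nonadj = np.abs(pairs[:, 0] - pairs[:, 1]) > 1
            pairs = pairs[nonadj]
        if pairs.size:
            i, j = pairs[:, 0], pairs[:, 1]
            r = np.linalg.norm(pos[i] - pos[j], axis=1)
            e_w, d_w = _wca(r, p.epsilon, p.sigma)
            energy += float(np.sum(e_w))
            _pair_accumulate(forces, pos, i, j, d_w, r)

    if restraints is not None and len(restraints) > 0:
        i, j = restraints.pairs[:, 0], restraints.pairs[:, 1]
        r = np.linalg.norm(pos[i] - pos[j], axis=1)
        K = restraints.K * p.epsilon / p.sigma**2
        r0 = restraints.r0 * p.sigma
        energy += float(np.sum(K * (r - r0) ** 2))
        _pair_accumulate(forces, pos, i, j, 2.0 * K * (r - r0), r)

    return energy, forces
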