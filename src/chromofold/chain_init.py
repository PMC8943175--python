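"""Initial chain conformations by self-avoiding random walk (SARW).

The chromosome model starts from a linear polymer grown one bead at a time:
each new bead is placed at a fixed bond length from the previous one, in a
uniformly random direction, and is rejected if it comes closer than an
excluded radius to any earlier bead. When a bead cannot be placed after a
bounded number of trials the walk backtracks, removing the previous bead.
Collision checks use a hashed spatial grid so growth is O(N) in the typical
(dilute) regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ChromofoldError, ConfigError

__all__ = ["BeadChain", "sarw_chain"]


@dataclass
class BeadChain:
    """A linear bead chain: (N, 3) coordinates in sigma plus its geometry.

    Invariants: consecutive beads are exactly ``bond_length`` apart (to
    1e-9) at construction, and no two beads are closer than
    ``excluded_radius``. Both are properties of the *initial* walk — the
    folding stages later move beads under the force field.
    """

    positions: np.ndarray
    bond_length: float = 0.99
    excluded_radius: float = 0.9

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ConfigError("positions must be an (N, 3) array")
        if self.n_beads < 1:
            raise ConfigError("a chain needs at least one bead")

    @property
    def n_beads(self) -> int:
        return int(self.positions.shape[0])

    def bond_lengths(self) -> np.ndarray:
        """Distances between consecutive beads, length N-1."""
        return np.linalg.norm(np.diff(self.positions, axis=0), axis=1)

    def min_pair_distance(self) -> float:
        """Smallest pairwise bead distance (inf for a single bead)."""
        if self.n_beads < 2:
            return float("inf")
        tree = cKDTree(self.positions)
        d, _ = tree.query(self.positions, k=2)
        return float(d[:, 1].min())

    def copy(self) -> "BeadChain":
        return BeadChain(self.positions.copy(), self.bond_length, self.excluded_radius)


class _Grid:
    """Hashed cell grid for neighbour lookups at a fixed interaction radius."""

    def __init__(self, cell: float) -> None:
        self.cell = cell
        self.cells: dict[tuple[int, int, int], list[int]] = {}

    def key(self, x: np.ndarray) -> tuple[int, int, int]:
        return tuple(np.floor(x / self.cell).astype(int))

    def add(self, idx: int, x: np.ndarray) -> None:
        self.cells.setdefault(self.key(x), []).append(idx)

    def remove(self, idx: int, x: np.ndarray) -> None:
        self.cells[self.key(x)].remove(idx)

    def neighbours(self, x: np.ndarray) -> list[int]:
        kx, ky, kz = self.key(x)
        out: list[int] = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    out.extend(self.cells.get((kx + dx, ky + dy, kz + dz), ()))
        return out


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:  # pragma: no cover - probability ~0
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def sarw_chain(
    n_beads: int,
    bond_length: float = 0.99,
    excluded_radius: float = 0.9,
    seed: int | None = None,
    max_trials_per_bead: int = 60,
    max_backtracks: int | None = None,
) -> BeadChain:
    """Grow a self-avoiding random walk of ``n_beads`` beads.

    The first bead sits at the origin; each subsequent bead is placed
    ``bond_length`` away from its predecessor in a uniformly random
    direction, retried up to ``max_trials_per_bead`` times on collision
    (any earlier bead within ``excluded_radius``), then the walk backtracks
    one bead. The total backtrack budget defaults to ``100 * n_beads``;
    exhausting it raises :class:`ChromofoldError` with a hint to raise the
    bond-length / excluded-radius ratio. Deterministic for a fixed seed.
    """
    if n_beads < 1:
        raise ConfigError("n_beads must be >= 1")
    if excluded_radius > bond_length:
        raise ConfigError(
            f"excluded_radius ({excluded_radius}) must not exceed bond_length "
            f"({bond_length}): consecutive beads would always collide"
        )
    if max_backtracks is None:
        max_backtracks = 100 * n_beads

    rng = np.random.default_rng(seed)
    pos = np.zeros((n_beads, 3))
    grid = _Grid(cell=max(excluded_radius, 1e-9))
    grid.add(0, pos[0])

    k = 1
    backtracks = 0
    while k < n_beads:
        placed = False
        for _ in range(max_trials_per_bead):
            cand = pos[k - 1] + bond_length * _random_unit(rng)
            nbrs = grid.neighbours(cand)
            if nbrs:
                d = np.linalg.norm(pos[nbrs] - cand, axis=1)
                # the bonded predecessor sits exactly at bond_length >= excluded_radius
                if np.any(d < excluded_radius - 1e-12):
                    continue
            pos[k] = cand
            grid.add(k, cand)
            placed = True
            break
        if placed:
            k += 1
            continue
        backtracks += 1
        if backtracks > max_backtracks or k <= 1:
            raise ChromofoldError(
                f"SARW backtrack budget exhausted at bead {k} after "
                f"{backtracks} backtracks; increase bond_length relative to "
                f"excluded_radius or the trial/backtrack budgets"
            )
        k -= 1
        grid.remove(k, pos[k])

    return BeadChain(pos, bond_length=bond_length, excluded_radius=excluded_radius)
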