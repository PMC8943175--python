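"""Hi-C restrained folding: restraint selection, Monte Carlo satisfaction,
Langevin (Brownian-dynamics) equilibration.

The workflow mirrors restraint-based chromosome modelling: start from a
self-avoiding random walk, convert contact-matrix entries into harmonic
pair restraints, *force the restrained pairs to connect* with a Metropolis
Monte Carlo stage (restraints switched on progressively from short to long
genomic range, with a stiffened, shortened well during the search and a
zero-temperature polish at the end), and finally relax the connected
structure with underdamped Langevin dynamics at reduced temperature T = 1,
friction 1/tau, timestep 0.01 tau.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from . import _kernels
from .chain_init import BeadChain, sarw_chain
from .errors import ConfigError, ConvergenceError
from .forcefield import ForceFieldParams, _fene, _wca
from .genomics_io import HiCMatrix

__all__ = [
    "RestraintSet",
    "RestraintRamp",
    "MCConfig",
    "SimConfig",
    "Trajectory",
    "FoldedStructure",
    "select_restraints",
    "restraint_distances",
    "mc_fold",
    "langevin_equilibrate",
    "kinetic_temperature",
    "fold_chromosome",
]

log = logging.getLogger(__name__)


@dataclass
class RestraintSet:
    """Harmonic Hi-C restraints between non-adjacent bead pairs.

    ``K`` (eps/sigma^2) and ``r0`` (sigma) parametrise the well
    ``K (r - r0)^2``; a pair counts as *connected* once its separation is
    at most ``activation_radius`` (defaults to r0).
    """

    pairs: np.ndarray  # (M, 2) with i + 1 < j
    K: float = 1.0
    r0: float = 2.2
    activation_radius: float | None = None

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)
        if self.activation_radius is None:
            self.activation_radius = self.r0
        if self.pairs.size:
            i, j = self.pairs[:, 0], self.pairs[:, 1]
            if np.any(i < 0):
                raise ConfigError("restraint indices must be nonnegative")
            if np.any(j - i < 2):
                raise ConfigError("restraints must join non-adjacent beads (i + 1 < j)")
            if len(np.unique(self.pairs, axis=0)) != len(self.pairs):
                raise ConfigError("duplicate restraint pairs")

    def __len__(self) -> int:
        return int(self.pairs.shape[0])

    def genomic_separations(self) -> np.ndarray:
        if not len(self):
            return np.zeros(0, dtype=np.int64)
        return self.pairs[:, 1] - self.pairs[:, 0]


@dataclass(frozen=True)
class RestraintRamp:
    """Schedule for switching restraints on during the MC search.

    Restraints are sorted by genomic separation and activated in
    ``n_stages`` cumulative batches (short-range loops first, avoiding
    topological frustration). While searching, each well is stiffened by
    ``k_boost`` and its rest length shortened by ``r0_factor`` so that the
    connected state is reached with margin below the activation radius; the
    physical (K, r0) are restored for the dynamics stage.

    ``polish`` finishes the satisfaction: gradient (L-BFGS) minimisation of
    the full energy with *one-sided* restraints — zero inside the shortened
    rest length, harmonic beyond — whose stiffness climbs the
    ``stiffness_ladder`` (multiples of the boosted K), with
    ``shake_sweeps`` thermal Metropolis sweeps between rungs to escape
    blocking arrangements. One-sided wells matter here: restrained
    reference distances span a range, so pinning them all to a single rest
    length is frustrated no matter the stiffness, while an upper bound has
    the satisfied set as its zero-energy set.
    """

    n_stages: int = 4
    k_boost: float = 10.0
    r0_factor: float = 0.9
    polish: bool = True
    stiffness_ladder: tuple = (1.0, 5.0, 20.0, 100.0, 500.0)
    shake_sweeps: int = 50


@dataclass
class MCConfig:
    max_sweeps: int = 4000
    move_sigma: float = 0.5
    temperature: float = 1.0
    restraint_ramp: RestraintRamp = field(default_factory=RestraintRamp)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_sweeps <= 0 or self.move_sigma <= 0 or self.temperature < 0:
            raise ConfigError("MCConfig fields must be positive (temperature >= 0)")


@dataclass
class SimConfig:
    """Langevin dynamics settings in reduced units (T in eps/k_B, time in tau)."""

    n_steps: int = 10000
    temperature: float = 1.0
    damping: float = 1.0
    timestep: float = 0.01
    mass: float = 1.0
    seed: int = 0
    neighbor_skin: float = 0.4
    snapshot_stride: int | None = None

    def __post_init__(self) -> None:
        if min(self.temperature, self.damping, self.timestep, self.mass) < 0:
            raise ConfigError("SimConfig fields must be nonnegative")
        if self.timestep <= 0:
            raise ConfigError("timestep must be positive")
        if self.n_steps < 0:
            raise ConfigError("n_steps must be >= 0")


@dataclass
class Trajectory:
    """Snapshots from a dynamics run plus the final phase-space state."""

    frames: list
    positions: np.ndarray
    velocities: np.ndarray
    stride: int
    kinetic_temperatures: np.ndarray


@dataclass
class FoldedStructure:
    """Final coordinates of a folded chromosome plus its genomic binning,
    the restraints used, and the satisfaction report."""

    positions: np.ndarray
    chrom: str
    bin_size: int
    bins: np.ndarray
    restraints: RestraintSet
    report: dict
    seeds: dict

    @property
    def n_beads(self) -> int:
        return int(self.positions.shape[0])

    def distance_matrix(self) -> np.ndarray:
        from scipy.spatial.distance import pdist, squareform

        return squareform(pdist(self.positions))


def select_restraints(
    hic: HiCMatrix,
    rule: str = "all_nonzero",
    K: float = 1.0,
    r0: float = 2.2,
    activation_radius: float | None = None,
) -> RestraintSet:
    """Turn contact-matrix entries into harmonic restraints.

    Rules: ``all_nonzero`` keeps every off-diagonal contact with a positive
    count; ``top_quantile:q`` keeps the top fraction ``q`` of nonzero
    contacts ranked by (count desc, i asc, j asc); ``count_threshold:c``
    keeps counts >= c. Diagonal and adjacent (|i - j| <= 1) entries are
    always excluded — chain bonds already connect neighbours.
    """
    counts = hic.counts
    iu = np.triu_indices(hic.n_bins, k=2)
    vals = counts[iu]
    nz = vals > 0
    i, j, vals = iu[0][nz], iu[1][nz], vals[nz]

    if rule == "all_nonzero":
        keep = np.ones(len(vals), dtype=bool)
    elif rule.startswith("top_quantile"):
        q = _rule_param(rule, "top_quantile", float)
        if not 0 < q <= 1:
            raise ConfigError(f"top_quantile fraction must be in (0, 1], got {q}")
        n_keep = int(np.ceil(q * len(vals)))
        order = np.lexsort((j, i, -vals))  # count desc, then i asc, j asc
        keep = np.zeros(len(vals), dtype=bool)
        keep[order[:n_keep]] = True
    elif rule.startswith("count_threshold"):
        c = _rule_param(rule, "count_threshold", float)
        keep = vals >= c
    else:
        raise ConfigError(f"unknown restraint-selection rule {rule!r}")

    pairs = np.column_stack([i[keep], j[keep]])
    return RestraintSet(pairs=pairs, K=K, r0=r0, activation_radius=activation_radius)


def _rule_param(rule: str, name: str, cast):
    body = rule[len(name):].strip(":() ")
    if not body:
        raise ConfigError(f"rule {name} needs a parameter, e.g. '{name}:0.5'")
    return cast(body)


def restraint_distances(positions: np.ndarray, restraints: RestraintSet) -> np.ndarray:
    """Current 3D separations of the restrained pairs."""
    if not len(restraints):
        return np.zeros(0)
    i, j = restraints.pairs[:, 0], restraints.pairs[:, 1]
    return np.linalg.norm(positions[i] - positions[j], axis=1)


def _restraint_csr(pairs: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """CSR adjacency (each pair listed under both beads) for the MC kernel."""
    deg = np.zeros(n + 1, dtype=np.int64)
    for a, b in pairs:
        deg[a + 1] += 1
        deg[b + 1] += 1
    ptr = np.cumsum(deg)
    idx = np.zeros(ptr[-1], dtype=np.int64)
    fill = ptr[:-1].copy()
    for a, b in pairs:
        idx[fill[a]] = b
        fill[a] += 1
        idx[fill[b]] = a
        fill[b] += 1
    return ptr, idx


def _polish_flat_bottom(
    pos: np.ndarray,
    pairs: np.ndarray,
    K: float,
    r_upper: float,
    ff: ForceFieldParams,
    maxiter: int = 4000,
) -> np.ndarray:
    """L-BFGS minimisation of chain + WCA energy plus one-sided restraints
    (zero below ``r_upper``, ``K (r - r_upper)^2`` beyond). Deterministic."""
    from scipy.optimize import minimize

    I, J = pairs[:, 0], pairs[:, 1]

    def fg(x: np.ndarray):
        p = x.reshape(-1, 3)
        nb = _NeighborList(p, ff.lj_cutoff, 0.4 * ff.sigma)
        e, f = _forces(p, nb, None, ff)
        dvec = p[I] - p[J]
        r = np.linalg.norm(dvec, axis=1)
        exc = np.maximum(r - r_upper, 0.0)
        e += float(np.sum(K * exc**2))
        fr = -(2.0 * K * exc / np.maximum(r, 1e-12))[:, None] * dvec
        np.add.at(f, I, fr)
        np.add.at(f, J, -fr)
        return e, -f.ravel()

    res = minimize(fg, pos.ravel(), jac=True, method="L-BFGS-B", options={"maxiter": maxiter})
    return res.x.reshape(-1, 3)


def mc_fold(
    chain: BeadChain,
    restraints: RestraintSet,
    cfg: MCConfig = MCConfig(),
    ff: ForceFieldParams = ForceFieldParams(),
) -> BeadChain:
    """Force the restrained pairs into contact: Metropolis search + polish.

    The search phase runs single-bead Gaussian trial moves accepted on the
    full pairwise energy at ``cfg.temperature``, with restraints stiffened
    and shortened per ``cfg.restraint_ramp`` and activated in stages of
    increasing genomic separation. The move scale adapts to hold the
    acceptance rate in a productive band as the chain compacts. Moves that
    would stretch a chain bond to R0 are always rejected, so connectivity
    is preserved at every accepted state.

    Because a thermal ensemble never holds *every* pair under the
    activation radius at once, the polish phase then minimises the energy
    with one-sided restraints of climbing stiffness (see
    :class:`RestraintRamp`) until all pairs are simultaneously within
    ``activation_radius``; failing that, :class:`ConvergenceError` reports
    the unsatisfied count and the worst distance. Deterministic for a
    fixed ``cfg.seed``.
    """
    out = chain.copy()
    m = len(restraints)
    if m == 0:
        return out
    if np.any(restraints.pairs[:, 1] >= out.n_beads):
        raise ConfigError("restraint indices exceed the chain length")

    pos = out.positions
    n = out.n_beads
    ramp = cfg.restraint_ramp
    K_mc = restraints.K * ramp.k_boost * ff.epsilon / ff.sigma**2
    r0_mc = restraints.r0 * ramp.r0_factor * ff.sigma
    act = restraints.activation_radius * ff.sigma
    beta = np.inf if cfg.temperature == 0 else 1.0 / cfg.temperature
    greedy = np.isinf(beta)

    order = np.argsort(restraints.genomic_separations(), kind="stable")
    pairs_sorted = np.ascontiguousarray(restraints.pairs[order])

    rng = np.random.default_rng(cfg.seed)
    sweeps_used = 0
    move_sigma = cfg.move_sigma
    kernel_args = (
        ff.kappa * ff.epsilon / ff.sigma**2,
        ff.epsilon_star,
        ff.sigma,
        ff.R0 * ff.sigma,
        ff.epsilon,
    )

    def _sweeps(active: np.ndarray, budget: int, stop_when_satisfied: bool) -> None:
        nonlocal sweeps_used, move_sigma
        ptr, idx = _restraint_csr(active, n)
        rs_act = RestraintSet(active, K=restraints.K, r0=restraints.r0)
        for _ in range(budget):
            seed = int(rng.integers(0, 2**31 - 1))
            acc = _kernels.mc_sweep(
                pos, move_sigma, 0.0 if greedy else beta, greedy,
                *kernel_args, K_mc, r0_mc, ptr, idx, seed,
            )
            sweeps_used += 1
            rate = acc / n
            if rate < 0.25:
                move_sigma = max(move_sigma * 0.85, 0.02 * ff.sigma)
            elif rate > 0.5:
                move_sigma = min(move_sigma * 1.2, cfg.move_sigma)
            if stop_when_satisfied and np.all(restraint_distances(pos, rs_act) <= act):
                return

    per_stage = max(1, cfg.max_sweeps // (2 * ramp.n_stages))
    for s in range(ramp.n_stages):
        size = int(np.ceil(m * (s + 1) / ramp.n_stages))
        _sweeps(pairs_sorted[:size], min(per_stage, cfg.max_sweeps - sweeps_used), True)

    if ramp.polish:
        for mult in ramp.stiffness_ladder:
            pos_new = _polish_flat_bottom(pos, pairs_sorted, K_mc * mult, r0_mc, ff)
            pos[:] = pos_new
            if np.all(restraint_distances(pos, restraints) <= act):
                break
            if sweeps_used < cfg.max_sweeps:
                _sweeps(
                    pairs_sorted,
                    min(ramp.shake_sweeps, cfg.max_sweeps - sweeps_used),
                    False,
                )

    d = restraint_distances(pos, restraints)
    if not np.all(d <= act):
        n_bad = int(np.sum(d > act))
        raise ConvergenceError(
            f"mc_fold: {n_bad} of {m} restrained pairs still beyond the activation "
            f"radius {act:g} sigma after {sweeps_used} sweeps (worst distance "
            f"{d.max():g} sigma); increase max_sweeps or relax the restraint rule"
        )
    log.info("mc_fold: %d restraints connected in %d sweeps", m, sweeps_used)
    return out


class _NeighborList:
    """k-d-tree Verlet list with a skin, rebuilt on displacement threshold."""

    def __init__(self, pos: np.ndarray, cutoff: float, skin: float) -> None:
        self.cutoff = cutoff
        self.skin = skin
        self.rebuild(pos)

    def rebuild(self, pos: np.ndarray) -> None:
        tree = cKDTree(pos)
        pairs = tree.query_pairs(self.cutoff + self.skin, output_type="ndarray")
        if pairs.size:
            pairs = pairs[np.abs(pairs[:, 0] - pairs[:, 1]) > 1]
        self.pairs = pairs.reshape(-1, 2)
        self.ref = pos.copy()

    def update(self, pos: np.ndarray) -> None:
        disp2 = np.max(np.sum((pos - self.ref) ** 2, axis=1)) if pos.size else 0.0
        if disp2 > (0.5 * self.skin) ** 2:
            self.rebuild(pos)


def _forces(
    pos: np.ndarray,
    nb: _NeighborList,
    restraints: RestraintSet | None,
    p: ForceFieldParams,
) -> tuple[float, np.ndarray]:
    """Energy and forces with a persistent neighbour list (dynamics hot path)."""
    n = pos.shape[0]
    forces = np.zeros_like(pos)
    energy = 0.0

    if n >= 2:
        dvec = pos[:-1] - pos[1:]
        r = np.linalg.norm(dvec, axis=1)
        if np.any(r >= p.R0 * p.sigma) or np.any(r <= 0):
            k = int(np.argmax((r >= p.R0 * p.sigma) | (r <= 0)))
            raise ConvergenceError(
                f"bond {k}-{k + 1} reached length {r[k]:g} sigma during dynamics"
            )
        e_f, d_f = _fene(r, p)
        e_w, d_w = _wca(r, p.epsilon_star, p.sigma)
        energy += float(np.sum(e_f + e_w))
        f = -((d_f + d_w) / r)[:, None] * dvec
        forces[:-1] += f
        forces[1:] -= f

    if nb.pairs.size:
        i, j = nb.pairs[:, 0], nb.pairs[:, 1]
        dvec = pos[i] - pos[j]
        r = np.linalg.norm(dvec, axis=1)
        mask = r < p.lj_cutoff
        if np.any(mask):
            i, j, dvec, r = i[mask], j[mask], dvec[mask], r[mask]
            e_w, d_w = _wca(r, p.epsilon, p.sigma)
            energy += float(np.sum(e_w))
            f = -(d_w / r)[:, None] * dvec
            np.add.at(forces, i, f)
            np.add.at(forces, j, -f)

    if restraints is not None and len(restraints):
        i, j = restraints.pairs[:, 0], restraints.pairs[:, 1]
        dvec = pos[i] - pos[j]
        r = np.linalg.norm(dvec, axis=1)
        K = restraints.K * p.epsilon / p.sigma**2
        r0 = restraints.r0 * p.sigma
        energy += float(np.sum(K * (r - r0) ** 2))
        f = -(2.0 * K * (r - r0) / r)[:, None] * dvec
        np.add.at(forces, i, f)
        np.add.at(forces, j, -f)

    return energy, forces


def minimize_energy(
    chain: BeadChain,
    restraints: RestraintSet | None = None,
    ff: ForceFieldParams = ForceFieldParams(),
    maxiter: int = 500,
) -> BeadChain:
    """Bounded L-BFGS relaxation under the physical potentials.

    Used between restraint satisfaction and dynamics: the polish can leave
    deep excluded-volume overlaps or near-limit FENE bonds whose forces
    would destabilise a 0.01-tau timestep, and a short minimisation brings
    the structure to a benign starting point. Deterministic.
    """
    from scipy.optimize import minimize

    def fg(x: np.ndarray):
        p = x.reshape(-1, 3)
        nb = _NeighborList(p, ff.lj_cutoff, 0.4 * ff.sigma)
        e, f = _forces(p, nb, restraints, ff)
        return e, -f.ravel()

    res = minimize(
        fg, chain.positions.ravel(), jac=True, method="L-BFGS-B",
        options={"maxiter": maxiter},
    )
    out = chain.copy()
    out.positions = res.x.reshape(-1, 3)
    return out


def kinetic_temperature(velocities: np.ndarray, mass: float = 1.0) -> float:
    """Instantaneous kinetic temperature ``m sum |v|^2 / (3 N)`` (k_B = 1)."""
    v = np.asarray(velocities, dtype=float).reshape(-1, 3)
    return float(mass * np.sum(v * v) / (3.0 * v.shape[0]))


def langevin_equilibrate(
    chain: BeadChain,
    restraints: RestraintSet | None = None,
    cfg: SimConfig = SimConfig(),
    ff: ForceFieldParams = ForceFieldParams(),
    initial_velocities: np.ndarray | None = None,
) -> Trajectory:
    """Underdamped Langevin dynamics via the BAOAB velocity-Verlet splitting.

    Half kicks and half drifts bracket an exact Ornstein-Uhlenbeck update
    ``v <- exp(-gamma dt) v + sqrt((1 - exp(-2 gamma dt)) T / m) xi``, which
    satisfies fluctuation-dissipation at ``cfg.temperature`` for any
    timestep and degenerates to plain velocity Verlet when ``damping = 0``
    (used by the energy-conservation sanity check). Velocities start from
    Maxwell-Boltzmann at the target temperature unless supplied.
    Deterministic for a fixed seed.
    """
    if cfg.timestep > 0.01 * ff.sigma + 1e-12:
        warnings.warn(
            f"timestep {cfg.timestep} tau exceeds the recommended stability "
            f"limit 0.01 tau",
            stacklevel=2,
        )
    if restraints is not None and len(restraints):
        d = restraint_distances(chain.positions, restraints)
        # flag clearly disconnected pairs (the activation radius plus the
        # 2-sigma thermal allowance), i.e. a skipped satisfaction stage
        loose = restraints.activation_radius * ff.sigma + 2.0 * ff.sigma
        if np.any(d > loose):
            warnings.warn(
                f"{int(np.sum(d > loose))} restrained pairs enter dynamics far "
                "beyond the activation radius; run mc_fold first",
                stacklevel=2,
            )

    pos = chain.positions.copy()
    n = pos.shape[0]
    rng = np.random.default_rng(cfg.seed)
    m_, dt, T, gamma = cfg.mass, cfg.timestep, cfg.temperature, cfg.damping
    if initial_velocities is not None:
        vel = np.array(initial_velocities, dtype=float)
    elif T > 0:
        vel = rng.normal(0.0, np.sqrt(T / m_), size=(n, 3))
    else:
        vel = np.zeros((n, 3))

    c1 = float(np.exp(-gamma * dt))
    c2 = float(np.sqrt(max(0.0, (1.0 - c1 * c1)) * T / m_))

    nb = _NeighborList(pos, ff.lj_cutoff, cfg.neighbor_skin * ff.sigma)
    _, F = _forces(pos, nb, restraints, ff)
    stride = cfg.snapshot_stride or max(1, cfg.n_steps // 10)
    frames = [pos.copy()]
    kts = np.empty(cfg.n_steps)

    for step in range(cfg.n_steps):
        vel += (0.5 * dt / m_) * F
        pos += 0.5 * dt * vel
        if c2 > 0.0 or c1 != 1.0:
            vel = c1 * vel + c2 * rng.standard_normal((n, 3))
        pos += 0.5 * dt * vel
        nb.update(pos)
        _, F = _forces(pos, nb, restraints, ff)
        vel += (0.5 * dt / m_) * F
        kts[step] = kinetic_temperature(vel, m_)
        if (step + 1) % stride == 0:
            frames.append(pos.copy())
        if (step + 1) % 200 == 0 or step + 1 == cfg.n_steps:
            if not np.all(np.isfinite(pos)) or np.max(np.abs(pos)) > 1e6:
                raise ConvergenceError(
                    f"dynamics diverged at step {step + 1}: non-finite or "
                    f">1e6 sigma coordinates (reduce the timestep)"
                )

    return Trajectory(
        frames=frames, positions=pos, velocities=vel, stride=stride, kinetic_temperatures=kts
    )


def fold_chromosome(
    hic: HiCMatrix,
    ff: ForceFieldParams = ForceFieldParams(),
    mc: MCConfig | None = None,
    sim: SimConfig | None = None,
    seed: int = 0,
    restraint_rule: str = "all_nonzero",
    chain: BeadChain | None = None,
) -> FoldedStructure:
    """Full folding pipeline: SARW -> restraints -> MC connect -> Langevin relax.

    One master seed deterministically derives independent streams for the
    initial walk, the Monte Carlo stage and the dynamics stage (logged in
    ``FoldedStructure.seeds``). The report records the restrained-pair
    satisfaction after MC (must be 1.0 — mc_fold raises otherwise) and the
    distance statistics after dynamics.
    """
    mc = mc or MCConfig()
    sim = sim or SimConfig()
    ss = np.random.SeedSequence(seed)
    s_sarw, s_mc, s_bd = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))

    if chain is None:
        chain = sarw_chain(hic.n_bins, bond_length=0.99 * ff.sigma, seed=s_sarw)
    elif chain.n_beads != hic.n_bins:
        raise ConfigError(
            f"chain has {chain.n_beads} beads but the matrix has {hic.n_bins} bins"
        )
    restraints = select_restraints(hic, rule=restraint_rule, K=ff.K, r0=ff.r0)
    log.info(
        "fold_chromosome: %d beads, %d restraints (rule %s)",
        hic.n_bins,
        len(restraints),
        restraint_rule,
    )

    folded = mc_fold(chain, restraints, replace(mc, seed=s_mc), ff)
    d_mc = restraint_distances(folded.positions, restraints)

    # relax before integrating: the stiff polish can leave strained overlaps
    # and long inter-domain bonds whose FENE forces would destabilise the
    # 0.01-tau timestep. The one-sided wall at the shortened rest length
    # keeps every pair connected while bonds contract to ~1 sigma.
    ramp = mc.restraint_ramp
    relaxed = folded.copy()
    relaxed.positions = _polish_flat_bottom(
        folded.positions,
        restraints.pairs,
        restraints.K * ramp.k_boost * ff.epsilon / ff.sigma**2,
        restraints.r0 * ramp.r0_factor * ff.sigma,
        ff,
    )
    traj = langevin_equilibrate(relaxed, restraints, replace(sim, seed=s_bd), ff)
    d_bd = restraint_distances(traj.positions, restraints)

    report = {
        "n_restraints": len(restraints),
        "satisfied_fraction_post_mc": float(np.mean(d_mc <= restraints.activation_radius))
        if len(restraints)
        else 1.0,
        "median_restrained_distance_post_mc": float(np.median(d_mc)) if len(restraints) else 0.0,
        "satisfied_fraction_post_bd": float(np.mean(d_bd <= restraints.activation_radius))
        if len(restraints)
        else 1.0,
        "median_restrained_distance_post_bd": float(np.median(d_bd)) if len(restraints) else 0.0,
        # averaged over the second half of the run, past the strain-release
        # transient that follows the compacted MC structure
        "mean_kinetic_temperature": float(
            np.mean(traj.kinetic_temperatures[sim.n_steps // 2:])
        )
        if sim.n_steps
        else 0.0,
    }
    return FoldedStructure(
        positions=traj.positions,
        chrom=hic.chrom,
        bin_size=hic.bin_size,
        bins=hic.bins,
        restraints=restraints,
        report=report,
        seeds={"master": seed, "sarw": s_sarw, "mc": s_mc, "bd": s_bd},
    )
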