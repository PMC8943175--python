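"""Synthetic fixtures for every pipeline stage: reference structures with
known spatial compartments, contact matrices derived from them, compartment-
enriched peak tracks, and two-channel spot images.

The generator emulates the statistical situation the 3D analysis probes: a
chromosome partitioned into alternating blocks that segregate into ``k``
spatial compartments (compact globules, well separated in space), a
contact map whose entries reflect short 3D distances in that reference
structure, and ChIP-seq-like peak tracks preferentially emitted in a
mark's home compartment. Because the reference structure is known, folding
can be scored as a recovery problem, and the RDF contrast between a factor
and its co-compartment mark has a known sign.

All synthetic genomic coordinates live on a fictitious chromosome
("chrS") binned at 5 kb, so no real genome is implied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import ChromofoldError, ConfigError
from .genomics_io import HiCMatrix, PeakSet

__all__ = [
    "SyntheticSpec",
    "make_reference_structure",
    "contacts_from_structure",
    "make_marked_tracks",
    "make_image_pair",
]

SYNTHETIC_CHROM = "chrS"
SYNTHETIC_BIN_SIZE = 5000


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic chromosome and its mark tracks.

    ``enrichment_in`` / ``enrichment_out`` are per-bin peak probabilities
    inside and outside a mark's home compartment; the defaults (0.7 / 0.1)
    give clearly segregated but noisy tracks. ``compartment_block_length``
    beads alternate between compartments along the chain; a trailing
    shorter block is allowed.
    """

    n_beads: int = 200
    n_compartments: int = 2
    compartment_block_length: int = 50
    contact_radius: float = 2.2
    enrichment_in: float = 0.7
    enrichment_out: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_beads < 1 or self.n_compartments < 1:
            raise ConfigError("n_beads and n_compartments must be >= 1")
        if self.compartment_block_length < 1:
            raise ConfigError("compartment_block_length must be >= 1")
        if self.contact_radius <= 0:
            raise ConfigError("contact_radius must be positive")
        for p in (self.enrichment_in, self.enrichment_out):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("enrichment probabilities must lie in [0, 1]")


def compartment_labels(spec: SyntheticSpec) -> np.ndarray:
    """Alternating-block compartment assignment along the chain."""
    blocks = np.arange(spec.n_beads) // spec.compartment_block_length
    return (blocks % spec.n_compartments).astype(np.int64)


def _confined_sarw(
    n: int,
    center: np.ndarray,
    radius: float,
    bond: float,
    excl: float,
    occupied: list[np.ndarray],
    rng: np.random.Generator,
    start: np.ndarray | None = None,
    max_trials: int = 200,
) -> np.ndarray:
    """Grow a SARW of ``n`` beads confined to a sphere, avoiding ``occupied``."""
    pos = np.empty((n, 3))
    occ = np.asarray(occupied).reshape(-1, 3)
    for attempt in range(max_trials):
        if start is None:
            first = center + (radius * 0.5) * rng.uniform(-1, 1, 3)
        else:
            first = start + 0.2 * attempt * rng.normal(size=3)
        if occ.size and np.min(np.linalg.norm(occ - first, axis=1)) < excl:
            continue
        pos[0] = first
        ok = True
        for k in range(1, n):
            placed = False
            for _ in range(max_trials):
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                cand = pos[k - 1] + bond * v
                if np.linalg.norm(cand - center) > radius:
                    continue
                prev = pos[:k]
                if np.min(np.linalg.norm(prev - cand, axis=1)) < excl - 1e-12:
                    continue
                if occ.size and np.min(np.linalg.norm(occ - cand, axis=1)) < excl - 1e-12:
                    continue
                pos[k] = cand
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return pos
    raise ChromofoldError(
        f"could not grow a {n}-bead globule of radius {radius:g} sigma; "
        "the compartment is too dense for the excluded radius"
    )


def make_reference_structure(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """A known 3D reference: one compact globule per compartment.

    Beads alternate between compartments in blocks along the chain; each
    compartment's beads are grown as a confined self-avoiding walk inside
    its own sphere, and the spheres' centres are placed on a line with
    centre-to-centre separation of at least four globule radii, so
    within-compartment distances are sharply smaller than cross-compartment
    ones. Consecutive-block linker bonds stretch between globules and must
    stay below the FENE limit of 20 sigma; infeasible geometry raises.
    """
    rng = np.random.default_rng(spec.seed)
    comp = compartment_labels(spec)
    bond, excl = 0.99, 0.8
    counts = np.bincount(comp, minlength=spec.n_compartments)
    # sphere radius from a dense but walkable packing (~0.4 beads / sigma^3)
    radii = np.maximum((3.0 * counts / (4.0 * np.pi * 0.4)) ** (1.0 / 3.0), 1.5)
    r_max = float(radii.max())
    sep = 4.0 * r_max
    # the worst linker runs from the far side of one globule to the near
    # face of the next: about sep + 0.1 * r_max with face-seeded starts
    if sep + 0.2 * r_max >= 18.0:
        raise ChromofoldError(
            "globule separation would stretch the inter-block linker toward the "
            "FENE limit of 20 sigma; reduce block length or bead count per compartment"
        )
    k = spec.n_compartments
    centers = np.zeros((k, 3))
    if k == 2:
        centers[1, 0] = sep
    elif k > 2:
        # regular k-gon with side length sep: consecutive compartments
        # (the only ones a linker ever joins) are exactly sep apart
        circ = sep / (2.0 * np.sin(np.pi / k))
        ang = 2.0 * np.pi * np.arange(k) / k
        centers[:, 0] = circ * np.cos(ang)
        centers[:, 1] = circ * np.sin(ang)

    pos = np.empty((spec.n_beads, 3))
    occupied: dict[int, list[np.ndarray]] = {c: [] for c in range(k)}
    # grow block by block so the chain order is preserved
    starts = np.flatnonzero(np.diff(comp, prepend=comp[0] - 1))
    block_bounds = list(zip(starts, np.append(starts[1:], spec.n_beads)))
    for lo, hi in block_bounds:
        c = int(comp[lo])
        if lo == 0:
            start = None
        else:
            # seed the block on the sphere face nearest the previous bead so
            # the linker bond stays short
            prev = pos[lo - 1]
            u = prev - centers[c]
            u /= max(np.linalg.norm(u), 1e-12)
            start = centers[c] + 0.88 * radii[c] * u
        blk = _confined_sarw(
            hi - lo, centers[c], radii[c], bond, excl,
            occupied[c] or [np.full(3, 1e9)], rng, start=start,
        )
        pos[lo:hi] = blk
        occupied[c].extend(blk)

    linkers = np.array(
        [np.linalg.norm(pos[lo] - pos[lo - 1]) for lo, _ in block_bounds[1:]]
    )
    if linkers.size and linkers.max() >= 19.0:
        raise ChromofoldError(
            f"inter-block linker stretched to {linkers.max():.1f} sigma, too close "
            "to the FENE limit of 20 sigma"
        )
    return pos, comp


def contacts_from_structure(
    positions: np.ndarray,
    contact_radius: float = 2.2,
    chrom: str = SYNTHETIC_CHROM,
    bin_size: int = SYNTHETIC_BIN_SIZE,
    power_law: bool = False,
) -> HiCMatrix:
    """Contact matrix of a known structure: 1 where distance <= radius.

    The binary map (default) makes structure recovery an unambiguous
    oracle — every unit entry certifies a pair within ``contact_radius`` in
    the reference. With ``power_law=True`` counts decay as 1/distance
    instead (zero beyond 10x the radius), for more Hi-C-like tests.
    """
    if contact_radius <= 0:
        raise ConfigError("contact_radius must be positive")
    d = squareform(pdist(np.asarray(positions, dtype=float)))
    if power_law:
        with np.errstate(divide="ignore"):
            counts = np.where((d > 0) & (d <= 10 * contact_radius), 1.0 / np.maximum(d, 1e-9), 0.0)
    else:
        counts = ((d <= contact_radius) & (d > 0)).astype(float)
    np.fill_diagonal(counts, 0.0)
    return HiCMatrix(chrom=chrom, bin_size=bin_size, counts=counts)


def make_marked_tracks(
    compartments: np.ndarray,
    spec: SyntheticSpec,
) -> tuple[PeakSet, PeakSet, PeakSet]:
    """Three peak tracks: a factor, an active mark, a repressive mark.

    The factor and the active mark share home compartment 0; the
    repressive mark's home is the last compartment. Per bead (5 kb bin), a
    peak spanning the bin is emitted with probability ``enrichment_in``
    in the mark's home compartment and ``enrichment_out`` elsewhere.
    Seeded and deterministic.
    """
    comp = np.asarray(compartments, dtype=np.int64)
    rng = np.random.default_rng(spec.seed + 1)
    homes = {"factor": 0, "active_mark": 0, "repressive_mark": int(comp.max())}
    out = []
    for name, home in homes.items():
        p = np.where(comp == home, spec.enrichment_in, spec.enrichment_out)
        hit = rng.random(comp.size) < p
        ivs = [
            (SYNTHETIC_CHROM, int(k) * SYNTHETIC_BIN_SIZE, (int(k) + 1) * SYNTHETIC_BIN_SIZE)
            for k in np.flatnonzero(hit)
        ]
        out.append(PeakSet(ivs, source=name))
    return tuple(out)


def make_image_pair(
    size: int = 128,
    n_spots: int = 30,
    coloc_fraction: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    spot_sigma: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-channel synthetic spot images for the CCF statistic.

    Channel A holds ``n_spots`` Gaussian spots at random positions; a
    ``coloc_fraction`` of channel B's spots share A's centres and the rest
    are placed independently. Additive Gaussian noise of ``noise_sd`` is
    applied to both. Seeded and deterministic.
    """
    if not 0.0 <= coloc_fraction <= 1.0:
        raise ConfigError("coloc_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)

    def render(centers: np.ndarray) -> np.ndarray:
        img = np.zeros((size, size))
        for cy, cx in centers:
            img += np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * spot_sigma**2))
        return img

    centers_a = rng.uniform(2 * spot_sigma, size - 2 * spot_sigma, size=(n_spots, 2))
    n_shared = int(round(coloc_fraction * n_spots))
    extra = rng.uniform(2 * spot_sigma, size - 2 * spot_sigma, size=(n_spots - n_shared, 2))
    centers_b = np.vstack([centers_a[:n_shared], extra])

    img_a = render(centers_a)
    img_b = render(centers_b)
    if noise_sd > 0:
        img_a = img_a + rng.normal(0.0, noise_sd, img_a.shape)
        img_b = img_b + rng.normal(0.0, noise_sd, img_b.shape)
    return img_a, img_b
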