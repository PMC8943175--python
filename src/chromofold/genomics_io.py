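"""Contact matrices, BED peak sets, peak-to-bead mapping and co-occupancy.

Conventions: all genomic coordinates are 0-based half-open, matching BED.
A chromosome binned at ``bin_size`` bp maps bead ``k`` to the interval
``[k * bin_size, (k + 1) * bin_size)``; an explicit bin list is also
supported for binnings with dropped (unmappable) bins. Peaks are
unstranded intervals; a bead carries a mark if a peak overlaps its bin
(``any_overlap``, the default at 5 kb resolution) or covers at least a
fraction of it (``min_fraction``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from intervaltree import IntervalTree

from .errors import ConfigError, InputFormatError

__all__ = [
    "HiCMatrix",
    "PeakSet",
    "BeadLabeling",
    "read_contact_matrix",
    "write_contact_matrix",
    "read_bed",
    "write_bed",
    "label_beads",
    "cooccupancy",
    "venn_counts",
]

log = logging.getLogger(__name__)


@dataclass
class HiCMatrix:
    """A single-chromosome contact matrix over an ordered genomic binning."""

    chrom: str
    bin_size: int
    counts: np.ndarray
    bins: np.ndarray | None = None  # (n, 2) start/end; regular grid if None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise InputFormatError("contact matrix must be square")
        if np.any(self.counts < 0):
            raise InputFormatError("contact counts must be nonnegative")
        if not np.allclose(self.counts, self.counts.T, atol=1e-9):
            raise InputFormatError("contact matrix must be symmetric (tolerance 1e-9)")
        if self.bins is None:
            n = self.counts.shape[0]
            starts = np.arange(n, dtype=np.int64) * self.bin_size
            self.bins = np.column_stack([starts, starts + self.bin_size])
        else:
            self.bins = np.asarray(self.bins, dtype=np.int64)
            if self.bins.shape != (self.counts.shape[0], 2):
                raise InputFormatError("bin list length must equal the matrix dimension")
            if np.any(self.bins[:, 0] >= self.bins[:, 1]):
                raise InputFormatError("each bin must satisfy start < end")
            if np.any(np.diff(self.bins[:, 0]) <= 0) or np.any(
                self.bins[1:, 0] < self.bins[:-1, 1]
            ):
                raise InputFormatError("bins must be sorted and non-overlapping")

    @property
    def n_bins(self) -> int:
        return int(self.counts.shape[0])


@dataclass
class PeakSet:
    """Sorted, unstranded genomic intervals (e.g. ChIP-seq peaks)."""

    intervals: list[tuple[str, int, int]]
    source: str = ""

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start >= end:
                raise InputFormatError(f"empty or inverted interval {chrom}:{start}-{end}")
        self.intervals = sorted(self.intervals, key=lambda iv: (iv[0], iv[1], iv[2]))

    def __len__(self) -> int:
        return len(self.intervals)

    def on_chrom(self, chrom: str) -> np.ndarray:
        """(k, 2) start/end array of the intervals on one chromosome."""
        ivs = [(s, e) for c, s, e in self.intervals if c == chrom]
        return np.asarray(ivs, dtype=np.int64).reshape(-1, 2)


@dataclass
class BeadLabeling:
    """Boolean per-bead mark labels derived from a PeakSet."""

    labels: np.ndarray
    mark_name: str
    rule: str = "any_overlap"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)

    @property
    def n_labeled(self) -> int:
        return int(self.labels.sum())

    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.labels)


def read_contact_matrix(
    source: str | Path,
    fmt: str = "coo_text",
    chrom: str = "chrS",
    bin_size: int = 5000,
    n_bins: int | None = None,
) -> HiCMatrix:
    """Read a contact matrix from plain text.

    ``coo_text`` lines are ``bin_i<TAB>bin_j<TAB>count`` (whitespace
    tolerated); comment lines starting with ``#`` may carry
    ``key=value`` metadata for chrom / bin_size / n_bins, which explicit
    arguments override only if the caller passes them. Missing entries are
    zero; entries are mirrored across the diagonal, and conflicting
    mirrored values (beyond 1e-6) are an error. ``dense_tsv`` is a square
    numeric grid.
    """
    path = Path(source)
    meta: dict[str, str] = {}
    if fmt == "coo_text":
        entries: list[tuple[int, int, float, int]] = []
        with open(path) as fh:
            for ln, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    for tok in line.lstrip("#").split():
                        if "=" in tok:
                            k, v = tok.split("=", 1)
                            meta[k] = v
                    continue
                parts = line.split()
                if len(parts) != 3:
                    raise InputFormatError(
                        f"{path}: line {ln}: expected 'bin_i bin_j count', got {len(parts)} fields"
                    )
                try:
                    i, j = int(parts[0]), int(parts[1])
                    c = float(parts[2])
                except ValueError as exc:
                    raise InputFormatError(f"{path}: line {ln}: {exc}") from exc
                if c < 0:
                    raise InputFormatError(f"{path}: line {ln}: negative count {c}")
                entries.append((i, j, c, ln))
        chrom = meta.get("chrom", chrom)
        bin_size = int(meta.get("bin_size", bin_size))
        if n_bins is None:
            n_bins = int(meta["n_bins"]) if "n_bins" in meta else None
        if n_bins is None:
            if not entries:
                raise InputFormatError(f"{path}: n_bins unknown (no metadata, no entries)")
            n_bins = max(max(i, j) for i, j, _, _ in entries) + 1
        counts = np.zeros((n_bins, n_bins))
        filled = np.zeros((n_bins, n_bins), dtype=bool)
        for i, j, c, ln in entries:
            if not (0 <= i < n_bins and 0 <= j < n_bins):
                raise InputFormatError(
                    f"{path}: line {ln}: bin index ({i}, {j}) out of range for n_bins={n_bins}"
                )
            if filled[i, j] and abs(counts[i, j] - c) > 1e-6:
                raise InputFormatError(
                    f"{path}: line {ln}: conflicting duplicate/mirrored entry for ({i}, {j}): "
                    f"{counts[i, j]} vs {c}"
                )
            counts[i, j] = counts[j, i] = c
            filled[i, j] = filled[j, i] = True
        return HiCMatrix(chrom=chrom, bin_size=bin_size, counts=counts)

    if fmt == "dense_tsv":
        rows: list[list[float]] = []
        with open(path) as fh:
            for ln, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    if line.startswith("#"):
                        for tok in line.lstrip("#").split():
                            if "=" in tok:
                                k, v = tok.split("=", 1)
                                meta[k] = v
                    continue
                try:
                    rows.append([float(x) for x in line.split()])
                except ValueError as exc:
                    raise InputFormatError(f"{path}: line {ln}: {exc}") from exc
                if len(rows) > 1 and len(rows[-1]) != len(rows[0]):
                    raise InputFormatError(
                        f"{path}: line {ln}: ragged row ({len(rows[-1])} values, "
                        f"expected {len(rows[0])})"
                    )
        chrom = meta.get("chrom", chrom)
        bin_size = int(meta.get("bin_size", bin_size))
        counts = np.asarray(rows, dtype=float)
        if counts.size == 0 or counts.shape[0] != counts.shape[1]:
            raise InputFormatError(f"{path}: dense matrix must be square and non-empty")
        return HiCMatrix(chrom=chrom, bin_size=bin_size, counts=counts)

    raise ConfigError(f"unknown contact-matrix format {fmt!r}")


def write_contact_matrix(hic: HiCMatrix, path: str | Path) -> None:
    """Write the upper triangle of a contact matrix as COO text with metadata."""
    with open(path, "w") as fh:
        fh.write(f"# chrom={hic.chrom} bin_size={hic.bin_size} n_bins={hic.n_bins}\n")
        iu = np.triu_indices(hic.n_bins)
        for i, j in zip(*iu):
            c = hic.counts[i, j]
            if c != 0:
                fh.write(f"{i}\t{j}\t{c:g}\n")


def read_bed(source: str | Path, name: str | None = None) -> PeakSet:
    """Read a BED3+ file (extra columns ignored, track/comment lines skipped)."""
    path = Path(source)
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise InputFormatError(f"{path}: line {ln}: fewer than 3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise InputFormatError(
                    f"{path}: line {ln}: non-integer coordinates {parts[1]!r}, {parts[2]!r}"
                ) from exc
            if start >= end:
                raise InputFormatError(
                    f"{path}: line {ln}: empty or inverted interval {chrom}:{start}-{end}"
                )
            intervals.append((chrom, start, end))
    return PeakSet(intervals, source=name or str(path))


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in peaks.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def label_beads(
    peaks: PeakSet,
    hic: HiCMatrix,
    rule: str = "any_overlap",
    min_fraction: float = 0.5,
    mark_name: str | None = None,
) -> BeadLabeling:
    """Map peaks onto beads (bins) of a binned chromosome.

    ``any_overlap`` labels a bead if at least 1 bp of any peak intersects
    its bin; ``min_fraction`` requires the peaks to cover at least
    ``min_fraction`` of the bin. Peaks on other chromosomes are dropped
    (logged); peaks extending past the binned range are clipped.
    """
    if rule not in ("any_overlap", "min_fraction"):
        raise ConfigError(f"unknown peak-to-bead rule {rule!r}")
    ivs = peaks.on_chrom(hic.chrom)
    n_dropped = len(peaks) - len(ivs)
    if n_dropped:
        log.info("label_beads: dropped %d peaks not on %s", n_dropped, hic.chrom)

    starts, ends = hic.bins[:, 0], hic.bins[:, 1]
    covered = np.zeros(hic.n_bins)
    any_hit = np.zeros(hic.n_bins, dtype=bool)
    for s, e in ivs:
        # bins with start < e and end > s overlap [s, e)
        lo = int(np.searchsorted(ends, s, side="right"))
        hi = int(np.searchsorted(starts, e, side="left"))
        if hi <= lo:
            continue
        any_hit[lo:hi] = True
        ov = np.minimum(ends[lo:hi], e) - np.maximum(starts[lo:hi], s)
        covered[lo:hi] += ov
    if rule == "any_overlap":
        labels = any_hit
    else:
        widths = (ends - starts).astype(float)
        # overlapping peaks may double-count coverage; cap at the bin width
        labels = np.minimum(covered, widths) / widths >= min_fraction
    name = mark_name or peaks.source or "mark"
    rule_desc = rule if rule == "any_overlap" else f"min_fraction({min_fraction})"
    return BeadLabeling(labels=labels, mark_name=name, rule=rule_desc)


def cooccupancy(a: PeakSet, b: PeakSet, max_gap: int = 0) -> dict:
    """Count peaks of A co-occupied by (within ``max_gap`` bp of) a peak of B.

    With the default ``max_gap = 0`` co-occupancy means >= 1 bp overlap.
    Each A peak is counted once no matter how many B peaks it touches; the
    report carries the symmetric counts for B as well.
    """
    def _count(query: PeakSet, subject: PeakSet) -> int:
        trees: dict[str, IntervalTree] = {}
        for chrom, s, e in subject.intervals:
            trees.setdefault(chrom, IntervalTree()).addi(s - max_gap, e + max_gap)
        hits = 0
        for chrom, s, e in query.intervals:
            t = trees.get(chrom)
            if t is not None and t.overlaps(s, e):
                hits += 1
        return hits

    n_a, n_b = len(a), len(b)
    a_hits = _count(a, b)
    b_hits = _count(b, a)
    return {
        "n_a": n_a,
        "n_a_overlapping_b": a_hits,
        "fraction_a": a_hits / n_a if n_a else 0.0,
        "n_b": n_b,
        "n_b_overlapping_a": b_hits,
        "fraction_b": b_hits / n_b if n_b else 0.0,
        "max_gap": max_gap,
    }


def venn_counts(sets: dict[str, PeakSet], max_gap: int = 0) -> dict[str, dict[str, int]]:
    """Per-set membership counts against every other set (Venn-style summary).

    For each named set, reports its size and, for every combination of the
    other sets, how many of its peaks overlap all sets in that combination
    (>= 1 bp within ``max_gap``). Counts are peak-centric in the reference
    set, mirroring three-way co-occupancy summaries of ChIP-seq peaks.
    """
    from itertools import combinations

    names = list(sets)
    trees: dict[str, dict[str, IntervalTree]] = {}
    for name, ps in sets.items():
        t: dict[str, IntervalTree] = {}
        for chrom, s, e in ps.intervals:
            t.setdefault(chrom, IntervalTree()).addi(s - max_gap, e + max_gap)
        trees[name] = t

    def _hits(ps: PeakSet, others: tuple[str, ...]) -> int:
        n = 0
        for chrom, s, e in ps.intervals:
            ok = True
            for o in others:
                t = trees[o].get(chrom)
                if t is None or not t.overlaps(s, e):
                    ok = False
                    break
            if ok:
                n += 1
        return n

    out: dict[str, dict[str, int]] = {}
    for name in names:
        others = [o for o in names if o != name]
        entry = {"total": len(sets[name])}
        for k in range(1, len(others) + 1):
            for combo in combinations(others, k):
                entry["&".join(combo)] = _hits(sets[name], combo)
        out[name] = entry
    return out
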