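"""Plain-text writers for structures, trajectories and reports."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .folding_engine import FoldedStructure, Trajectory, restraint_distances

__all__ = ["write_xyz", "write_structure_tsv", "write_restraint_report"]


def write_xyz(frames, path: str | Path, element: str = "C", comment: str = "") -> None:
    """Write one or more coordinate frames as a multi-frame XYZ file.

    ``frames`` may be a single (N, 3) array, a list of them, or a
    :class:`Trajectory`. Coordinates are in sigma; every bead is tagged
    with the same element symbol.
    """
    if isinstance(frames, Trajectory):
        frames = frames.frames
    arr = np.asarray(frames, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    with open(path, "w") as fh:
        for k, frame in enumerate(arr):
            fh.write(f"{frame.shape[0]}\n")
            fh.write(f"{comment or 'chromofold'} frame={k}\n")
            for x, y, z in frame:
                fh.write(f"{element} {x:.6f} {y:.6f} {z:.6f}\n")


def write_structure_tsv(structure: FoldedStructure, path: str | Path) -> None:
    """Final coordinates with their genomic bins:
    bead_index, chrom, start, end, x, y, z."""
    pd.DataFrame(
        {
            "bead_index": np.arange(structure.n_beads),
            "chrom": structure.chrom,
            "start": structure.bins[:, 0],
            "end": structure.bins[:, 1],
            "x": structure.positions[:, 0],
            "y": structure.positions[:, 1],
            "z": structure.positions[:, 2],
        }
    ).to_csv(path, sep="\t", index=False)


def read_structure_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_restraint_report(structure: FoldedStructure, path: str | Path) -> None:
    """Per-restraint distances in the final structure, as TSV."""
    r = structure.restraints
    d = restraint_distances(structure.positions, r)
    pd.DataFrame(
        {
            "bead_i": r.pairs[:, 0] if len(r) else [],
            "bead_j": r.pairs[:, 1] if len(r) else [],
            "distance_sigma": d,
            "within_activation": d <= r.activation_radius if len(r) else [],
        }
    ).to_csv(path, sep="\t", index=False)
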