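# chromofold

Restraint-based 3D folding of a chromosome from Hi-C contacts, and
colocalization statistics for ChIP-seq marks on the folded structure.

**Who it is for.** Chromatin and regulatory-genomics researchers who want
to ask *where genomic marks sit relative to one another in 3D* — e.g.
whether a corepressor's binding sites lie closer to active
(H3K4me3-like) or repressed (H3K27me3-like) chromatin — using nothing
heavier than a contact matrix and BED peak files, on a laptop.

## The model

A chromosome is a bead-spring polymer in reduced units (one bead = one
genomic bin, 5 kb by default). Three potentials act on it:

* bonded beads: a FENE spring plus a WCA repulsive core,
  `U = -1/2 κ R0² ln[1 − (r/R0)²] + 4ε*[(σ/r)¹² − (σ/r)⁶ + 1/4]`,
  with κ = 30 ε/σ², R0 = 20 σ — equilibrium bond length 0.99 σ,
  stretchable to 20 σ;
* nonbonded beads: the purely repulsive WCA core (cutoff 2^(1/6) σ);
* Hi-C contact pairs: a harmonic restraint `U = K (r − r0)²`,
  K = 1 ε/σ², r0 = 2.2 σ.

The pipeline: grow a self-avoiding random walk; convert contact-matrix
entries into restraints; force every restrained pair into contact by
Metropolis Monte Carlo (staged activation, adaptive moves, and a
stiffness-ramped one-sided polish); relax with underdamped Langevin
dynamics at T = 1, γ = 1/τ, Δt = 0.01 τ. Peaks map onto beads by bin
overlap; the cross radial distribution function g(r) with a
label-permutation baseline measures 3D colocalization, and the Van
Steensel cross-correlation (Pearson vs pixel shift δ) does the same for
two-channel images. A synthetic-data generator provides
known-compartment reference structures so every stage is testable
without downloads. Details and design rationale: `docs/methods.md`.

## Worked example

Fold a synthetic 200-bead two-compartment chromosome from its own
contact map and ask which mark the factor sits closer to:

```sh
python examples/02_fold_synthetic_chromosome.py
python examples/03_rdf_colocalization.py
```

prints (seed 0):

```
reference: 200 beads, 1538 contacts
  n_restraints: 1342
  satisfied_fraction_post_mc: 1.000
  median_restrained_distance_post_bd: 2.132
  mean_kinetic_temperature: 1.006
Spearman(reference distances, recovered distances) = 0.775

factor beads: 79/200
  active_mark     :  90 beads, proximity score (mean g, r <= 2 sigma) = 1.18
  repressive_mark :  70 beads, proximity score (mean g, r <= 2 sigma) = 0.27
```

Reading it: the Monte Carlo stage ended with **100%** of the 1,342
restrained pairs within the 2.2 σ activation radius; after Langevin
relaxation the median restrained distance sits at ~2.1 σ (near the 2.2 σ
rest length) and the thermostat holds T ≈ 1. The folded structure ranks
pairwise distances like the hidden reference (Spearman 0.78). On that
structure, the factor's short-range g(r) against its co-compartment
"active" mark is 1.18 (enriched over chance) versus 0.27 against the
"repressive" mark (depleted) — the 3D-colocalization contrast the
pipeline exists to measure.

The same workflow is available as a CLI
(`chromofold simulate-data | fold | rdf | ccf | cooccupancy`; every run
writes a reproducibility manifest), and the remaining examples cover the
bond potential, image colocalization, and peak co-occupancy counting.

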