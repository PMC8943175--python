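# Methods

## The model

A chromosome segment is represented as a linear bead-spring polymer in
reduced (Lennard-Jones) units: `sigma` is the unit of length (one bead
diameter, one genomic bin), `eps` the unit of energy, and with unit mass
the time unit is `tau = sigma * sqrt(m / eps)`. One bead corresponds to one
fixed-size genomic bin (5 kb by default, so a ~63 Mb chromosome maps to
~12,600 beads; desk-scale studies in this package use 200-bead chains).

Three interactions act on the chain:

**Bonded** (consecutive beads) — a finitely extensible nonlinear elastic
(FENE) spring plus a purely repulsive Weeks-Chandler-Andersen (WCA) core:

    U_bond(r) = -1/2 kappa R0^2 ln[1 - (r/R0)^2]
                + 4 eps* [(sigma/r)^12 - (sigma/r)^6 + 1/4]   for r <= 2^(1/6) sigma
                                                              (0 beyond the cutoff)

with `kappa = 30 eps/sigma^2` and `R0 = 20 sigma`. The combined bond has
its minimum at 0.9886 sigma (printed as 0.99) yet remains extensible to
20 sigma. The WCA term is truncated and shifted by +1/4 at its minimum so
energy and force are both continuous at the cutoff; the same shift is used
in the bonded and nonbonded terms.

**Nonbonded** (all pairs except bonded neighbours, within `2^(1/6) sigma`)
— the WCA core alone: excluded volume without attraction. Bonded
neighbours are excluded because the bonded term already carries the
repulsion (the standard bead-spring convention).

**Hi-C restraint** (selected contact pairs) — a harmonic well
`U = K (r - r0)^2` with `K = 1 eps/sigma^2` and rest length
`r0 = 2.2 sigma`, pulling genomic loci that contact in the experiment
close together in 3D. Restrained pairs that drift inside the WCA cutoff
also feel the nonbonded repulsion; at the 2.2-sigma rest length they sit
well outside it.

## The pipeline

1. **Initial conformation** — a self-avoiding random walk grown bead by
   bead: fixed step 0.99 sigma (the equilibrium bond length), uniformly
   random directions, rejection of any placement within the excluded
   radius (0.9 sigma) of an earlier bead, and bounded backtracking when a
   bead cannot be placed. Collision checks use a hashed spatial grid.

2. **Restraint selection** — off-diagonal contact-matrix entries become
   restraints. Default rule: every nonzero contact with `|i - j| > 1`
   (adjacent bins are already joined by chain bonds). `top_quantile:q`
   and `count_threshold:c` are available for dense matrices; quantile ties
   break deterministically by (count desc, i asc, j asc).

3. **Monte Carlo restraint satisfaction** — single-bead Gaussian trial
   moves accepted by Metropolis on the full system energy at T = 1.
   Restraints activate in four cumulative stages of increasing genomic
   separation (short loops first, which avoids threading long-range
   contacts through unfolded chain). Two departures from a plain fixed
   Metropolis scheme proved necessary:

   * *Adaptive move scale.* As the chain compacts, fixed 0.5-sigma moves
     are almost always rejected and the walk stalls; the move scale is
     retuned each sweep to hold acceptance between 25% and 50% (floor
     0.02 sigma, ceiling the configured scale).
   * *One-sided polish.* A thermal ensemble essentially never holds every
     restrained pair below the activation radius at the same instant, and
     a zero-temperature single-bead walk descends far too slowly. The
     final satisfaction is therefore reached by L-BFGS minimisation of
     the full energy in which each restraint contributes only above an
     upper bound (zero below `0.9 r0`, harmonic beyond), with stiffness
     climbing a ladder (10x, 50x, 200x, 1000x, 5000x K) and ~50 thermal
     shake sweeps between rungs to escape blocking arrangements. The
     one-sidedness matters: restrained reference distances span a range
     (roughly 0.8-2.2 sigma in the synthetic problems), so two-sided
     wells pinned to a single rest length frustrate one another and leave
     a large fraction of pairs unsatisfied at any stiffness, whereas the
     satisfied set is exactly the zero-energy set of the one-sided wells.

   Moves that would stretch any chain bond to R0 are rejected outright, so
   connectivity is preserved at every accepted state. On success, 100% of
   restrained pairs are simultaneously within the activation radius
   (2.2 sigma); otherwise the stage raises with the unsatisfied count and
   worst distance.

4. **Langevin equilibration** — the connected structure relaxes under the
   physical potentials (two-sided harmonic restraints, K = 1,
   r0 = 2.2 sigma) by underdamped Langevin dynamics: BAOAB splitting of
   velocity Verlet, where the Ornstein-Uhlenbeck half-step
   `v <- e^(-gamma dt) v + sqrt((1 - e^(-2 gamma dt)) T/m) xi` enforces
   fluctuation-dissipation at the target temperature exactly. Defaults:
   T = 1, friction gamma = 1/tau, dt = 0.01 tau. At gamma = 0 the
   integrator degenerates to plain velocity Verlet (relative energy drift
   ~1e-6 over 1e3 steps at dt = 0.001 tau, the integrator sanity check).
   Kinetic temperature holds the target to within ~1.5% at dt = 0.01 tau.
   Nonbonded neighbours come from a k-d-tree Verlet list with a 0.4-sigma
   skin, rebuilt when any bead has moved half a skin.

One master seed deterministically derives independent streams for the
walk, the MC stage and the dynamics; identical seeds give bit-identical
structures.

## Genomic mapping and colocalization statistics

Coordinates are 0-based half-open throughout (BED convention); bead `k`
of a regular binning owns `[k*bin_size, (k+1)*bin_size)`, and an explicit
bin list supports binnings with dropped (unmappable) bins. A bead carries
a mark if >= 1 bp of a peak overlaps its bin (`any_overlap`, the default —
the most sensitive convention at 5 kb resolution) or if peaks cover at
least a fraction `f` of the bin (`min_fraction`). Peak co-occupancy
counts each query peak once if any subject peak lies within `max_gap` bp
(default 0, i.e. >= 1 bp overlap — the common peak-overlap tooling
default); the interval-tree implementation is held to an O(n^2) scan by a
property test.

**RDF.** The cross radial distribution function between bead sets A and B
histograms all A-B distances (a bead carrying both labels never pairs
with itself) in bins of width `dr = 0.5 sigma` up to `r_max = 20 sigma`.
Normalisation is by label permutation: the observed histogram is divided
by its mean over `n_permutations = 100` random reassignments of the B
labels across all beads. This baseline respects the polymer's own
geometry; an ideal-gas (uniform density) baseline is biased on a
connected chain and is provided only as an option (`baseline="density"`).
Under permutation normalisation, randomly placed labels give g ~= 1 in
every bin (law of large numbers, ~3/sqrt(n_permutations)). The
`proximity_score` summary is the mean of g over bins with right edge
<= 2 sigma; comparing a factor's score against two marks ranks which mark
it sits closer to in 3D. Because the bin width, range and normalisation
behind published RDF curves are generally unstated, RDF comparisons here
are orderings, not absolute values.

**CCF.** The Van Steensel cross-correlation slides channel B past channel
A along one axis: `CCF(delta) = Pearson(A(x), B(x + delta))` over the
overlapping region, for integer delta in [-max_shift, +max_shift]. A
channel translated by +5 px peaks at delta = +5; colocalized stains peak
at delta = 0, mutually exclusive stains dip at delta = 0. Shifts whose
overlap leaves either channel constant are reported as NaN with a
per-shift flag rather than silently as zero.

## The synthetic-data generator

The generator emulates the statistical structure the 3D analysis probes —
marks segregated into transcriptionally distinct spatial compartments —
without any real genome:

* **Reference structure.** 200 beads in alternating 50-bead blocks over 2
  compartments (both configurable). Each compartment's beads grow as a
  confined self-avoiding walk inside a sphere packed at ~0.4 beads/sigma^3;
  sphere centres sit on a regular polygon with centre-to-centre distance
  4x the largest globule radius, and each block starts on the sphere face
  nearest the previous bead so inter-block linkers stay below the FENE
  limit. Within-compartment distances are therefore sharply smaller than
  cross-compartment ones.
* **Contacts.** `counts(i,j) = 1` where the reference distance is at most
  the contact radius (2.2 sigma, the restraint rest length), else 0. The
  binary map makes recovery an unambiguous oracle: the reference itself
  certifies that the restraint set is satisfiable. A `1/distance`
  power-law option exists for more Hi-C-like tests.
* **Mark tracks.** Per 5 kb bin, a peak is emitted with probability 0.7
  in the mark's home compartment and 0.1 elsewhere; the factor and the
  active mark share compartment 0, the repressive mark lives in the last
  compartment. Coordinates use the fictitious chromosome "chrS".
* **Images.** Gaussian spots; a configurable fraction of channel-B spots
  share channel-A centres, the rest land independently, plus optional
  Gaussian noise.

What the generator does *not* emulate: Hi-C distance-decay and coverage
biases, diploid homolog ambiguity, peak-width and signal-strength
variation, and mapping artifacts. Passing tests therefore demonstrate
that the machinery recovers planted structure under clean conditions, not
that it is robust to every failure mode of real data.

## Problem sizes and numerical choices

Desk-scale studies run 200-bead chromosomes (one compartment pair,
~1,300 restraints), 2e5-step thermostat checks at N = 100, and 3,000-
5,000-step relaxations; a fold takes seconds on one CPU. Key tolerances:
force-vs-finite-difference agreement 1e-5 relative; bond-length and
symmetry invariants 1e-9; root-finding for the equilibrium bond length
1e-9 sigma (reported to two decimals); contact-matrix symmetry 1e-9 with
a 1e-6 mirror-conflict tolerance on input. Degenerate inputs fail loudly:
empty label sets, constant image overlaps, bonds at or beyond R0, and
asymmetric matrices all raise typed errors rather than returning
placeholder values.

## Known limitations

* The full-chromosome problem (~12,600 beads with experimental Hi-C) is
  supported by the data structures but not exercised in the test suite;
  runtimes at that scale depend strongly on restraint density.
* The MC satisfaction stage is a search procedure, not a sampler: its
  output is one restraint-consistent conformation, and ensemble
  statements should be made over independent master seeds.
* Restraints are intra-chromosomal only; there is no nuclear confinement,
  no trans contacts, and no replica exchange.
* The density RDF baseline uses the occupied bounding box and is crude;
  permutation is the supported normalisation.
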