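"""Peak co-occupancy between ChIP-seq tracks.

Two peak sets co-occupy a site when their intervals overlap by >= 1 bp
(max_gap = 0). The report is peak-centric: what fraction of A's peaks
touch at least one B peak, and vice versa. Run on synthetic tracks here;
point `read_bed` at real BED files for genome-scale counts.
"""

import chromofold as cf

spec = cf.SyntheticSpec(seed=0)
_, compartments = cf.make_reference_structure(spec)
factor, active, repressive = cf.make_marked_tracks(compartments, spec)

for name, other in (("active_mark", active), ("repressive_mark", repressive)):
    rep = cf.cooccupancy(factor, other, max_gap=0)
    print(f"factor vs {name}: {rep['n_a_overlapping_b']}/{rep['n_a']} "
          f"factor peaks co-occupied ({100 * rep['fraction_a']:.1f}%)")

venn = cf.venn_counts({"factor": factor, "active": active, "repressive": repressive})
f = venn["factor"]
print(f"of {f['total']} factor peaks: {f['active']} touch the active mark, "
      f"{f['repressive']} the repressive mark, {f['active&repressive']} both")
print("The factor shares its home compartment with the active mark, so its "
      "peaks overlap that track far more often than the repressive one.")
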