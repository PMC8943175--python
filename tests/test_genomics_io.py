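"""Contact-matrix / BED parsing, peak-to-bead mapping, co-occupancy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import chromofold as cf
from chromofold.errors import InputFormatError


@pytest.fixture()
def bins_hic():
    """Empty 4-bin matrix at 5 kb, used purely for its binning."""
    return cf.HiCMatrix(chrom="chr20", bin_size=5000, counts=np.zeros((4, 4)))


class TestContactMatrixIO:
    def test_coo_round_trip_and_symmetrisation(self, tmp_path):
        p = tmp_path / "m.coo"
        p.write_text("# chrom=chr20 bin_size=5000 n_bins=4\n0\t2\t5\n1\t3\t3\n")
        hic = cf.read_contact_matrix(p)
        assert hic.chrom == "chr20" and hic.n_bins == 4
        assert hic.counts[2, 0] == 5 and hic.counts[0, 2] == 5
        assert hic.counts[3, 1] == 3 and hic.counts.sum() == 16
        out = tmp_path / "m2.coo"
        cf.write_contact_matrix(hic, out)
        again = cf.read_contact_matrix(out)
        assert np.array_equal(again.counts, hic.counts)

    def test_empty_file_with_known_bins_is_all_zero(self, tmp_path):
        p = tmp_path / "empty.coo"
        p.write_text("")
        hic = cf.read_contact_matrix(p, n_bins=3)
        assert hic.counts.shape == (3, 3) and hic.counts.sum() == 0

    def test_negative_count_names_the_line(self, tmp_path):
        p = tmp_path / "bad.coo"
        p.write_text("0\t2\t-1\n")
        with pytest.raises(InputFormatError, match="line 1"):
            cf.read_contact_matrix(p, n_bins=4)

    def test_out_of_range_index_and_conflicting_mirror(self, tmp_path):
        p = tmp_path / "oor.coo"
        p.write_text("0\t9\t1\n")
        with pytest.raises(InputFormatError, match="out of range"):
            cf.read_contact_matrix(p, n_bins=4)
        p2 = tmp_path / "conflict.coo"
        p2.write_text("0\t2\t5\n2\t0\t6\n")
        with pytest.raises(InputFormatError, match="line 2"):
            cf.read_contact_matrix(p2, n_bins=4)

    def test_dense_tsv_ragged_row_rejected(self, tmp_path):
        p = tmp_path / "dense.tsv"
        p.write_text("0 1\n1 0\n")
        hic = cf.read_contact_matrix(p, fmt="dense_tsv")
        assert hic.counts[0, 1] == 1
        p2 = tmp_path / "ragged.tsv"
        p2.write_text("0 1 2\n1 0\n")
        with pytest.raises(InputFormatError, match="ragged"):
            cf.read_contact_matrix(p2, fmt="dense_tsv")


class TestBedIO:
    def test_basic_interval_and_sorting(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr20\t7000\t8000\nchr20\t0\t5000\n")
        ps = cf.read_bed(p)
        assert ps.intervals == [("chr20", 0, 5000), ("chr20", 7000, 8000)]

    def test_empty_interval_rejected_with_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr20\t100\t100\n")
        with pytest.raises(InputFormatError, match="line 1"):
            cf.read_bed(p)

    def test_non_integer_coordinates_rejected(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr20\tx\t200\n")
        with pytest.raises(InputFormatError, match="non-integer"):
            cf.read_bed(p)

    def test_round_trip_preserves_intervals(self, tmp_path):
        ps = cf.PeakSet(
            [("chr20", 0, 100), ("chr20", 0, 100), ("chr1", 5, 10)], source="x"
        )
        out = tmp_path / "rt.bed"
        cf.write_bed(ps, out)
        assert cf.read_bed(out).intervals == ps.intervals  # duplicates retained

    def test_track_and_comment_lines_skipped(self, tmp_path):
        p = tmp_path / "t.bed"
        p.write_text("track name=peaks\n# comment\nchr20\t10\t20\textra\tcols\n")
        assert cf.read_bed(p).intervals == [("chr20", 10, 20)]


class TestLabelBeads:
    def test_boundary_straddling_peak_hits_both_bins(self, bins_hic):
        ps = cf.PeakSet([("chr20", 4999, 5001)])
        lab = cf.label_beads(ps, bins_hic)
        assert list(lab.labels) == [True, True, False, False]

    def test_half_open_peak_on_bin_boundary(self, bins_hic):
        ps = cf.PeakSet([("chr20", 5000, 10000)])
        lab = cf.label_beads(ps, bins_hic)
        assert list(lab.labels) == [False, True, False, False]

    def test_min_fraction_rule(self, bins_hic):
        ps = cf.PeakSet([("chr20", 0, 2000)])  # covers 0.4 of bin 0
        lab = cf.label_beads(ps, bins_hic, rule="min_fraction", min_fraction=0.5)
        assert lab.n_labeled == 0
        lab2 = cf.label_beads(ps, bins_hic, rule="min_fraction", min_fraction=0.4)
        assert list(lab2.labels) == [True, False, False, False]

    def test_other_chromosome_dropped_and_overhang_clipped(self, bins_hic):
        ps = cf.PeakSet([("chrX", 0, 5000), ("chr20", 18000, 99999)])
        lab = cf.label_beads(ps, bins_hic)
        assert list(lab.labels) == [False, False, False, True]

    @given(
        start=st.integers(0, 19000),
        length=st.integers(1, 6000),
        f=st.floats(0.05, 1.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_any_overlap_is_superset_of_min_fraction(self, start, length, f):
        hic = cf.HiCMatrix(chrom="chr20", bin_size=5000, counts=np.zeros((4, 4)))
        ps = cf.PeakSet([("chr20", start, start + length)])
        any_ = cf.label_beads(ps, hic).labels
        frac = cf.label_beads(ps, hic, rule="min_fraction", min_fraction=f).labels
        assert np.all(any_ | ~frac)  # frac => any_


def _brute_force_cooccupancy(a, b, max_gap):
    hits = 0
    for ca, sa, ea in a.intervals:
        if any(
            cb == ca and sa < eb + max_gap and sb - max_gap < ea
            for cb, sb, eb in b.intervals
        ):
            hits += 1
    return hits


class TestCooccupancy:
    def test_identical_sets_fully_cooccupied(self):
        ps = cf.PeakSet([("chr1", 0, 10), ("chr1", 50, 60)])
        rep = cf.cooccupancy(ps, ps)
        assert rep["fraction_a"] == 1.0 and rep["fraction_b"] == 1.0

    def test_disjoint_sets(self):
        a = cf.PeakSet([("chr1", 0, 10)])
        b = cf.PeakSet([("chr1", 100, 110)])
        assert cf.cooccupancy(a, b)["fraction_a"] == 0.0

    def test_toy_example(self):
        a = cf.PeakSet([("chr1", 0, 10), ("chr1", 20, 30), ("chr1", 50, 60)])
        b = cf.PeakSet([("chr1", 8, 12), ("chr1", 31, 40)])
        rep = cf.cooccupancy(a, b, max_gap=0)
        assert rep["n_a_overlapping_b"] == 1
        assert rep["fraction_a"] == pytest.approx(1 / 3)

    @given(
        a_ivs=st.lists(
            st.tuples(st.integers(0, 300), st.integers(1, 40)), min_size=1, max_size=15
        ),
        b_ivs=st.lists(
            st.tuples(st.integers(0, 300), st.integers(1, 40)), min_size=1, max_size=15
        ),
        max_gap=st.sampled_from([0, 5, 25]),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_quadratic_scan(self, a_ivs, b_ivs, max_gap):
        a = cf.PeakSet([("chr1", s, s + w) for s, w in a_ivs])
        b = cf.PeakSet([("chr1", s, s + w) for s, w in b_ivs])
        rep = cf.cooccupancy(a, b, max_gap=max_gap)
        assert rep["n_a_overlapping_b"] == _brute_force_cooccupancy(a, b, max_gap)
        assert rep["n_b_overlapping_a"] == _brute_force_cooccupancy(b, a, max_gap)

    def test_three_set_venn_counts(self):
        a = cf.PeakSet([("chr1", 0, 10), ("chr1", 100, 110)])
        b = cf.PeakSet([("chr1", 5, 15)])
        c = cf.PeakSet([("chr1", 8, 12), ("chr1", 105, 106)])
        out = cf.venn_counts({"A": a, "B": b, "C": c})
        assert out["A"]["total"] == 2
        assert out["A"]["B"] == 1  # only the first A peak touches B
        assert out["A"]["C"] == 2
        assert out["A"]["B&C"] == 1
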