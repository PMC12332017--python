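"""Histogram container, truncation, alignment, Hellinger distance and I/O."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import labelkin as lk
from labelkin.histograms import AlignmentError, HistogramParseError


class TestBuildHistogram:
    def test_direct_binning_two_log_decades(self):
        h = lk.build_histogram([10, 50, 1000], lk.BinSpec(1, 10_000, 2), 0.0)
        assert h.counts.tolist() == [2, 1]

    def test_empty_events(self):
        h = lk.build_histogram([], lk.BinSpec(1, 10_000, 2), 0.0)
        assert h.counts.tolist() == [0, 0]

    def test_interior_edge_goes_to_upper_bin(self):
        h = lk.build_histogram([100.0], lk.BinSpec(1, 10_000, 2), 0.0)
        assert h.counts.tolist() == [0, 1]

    def test_out_of_range_events_dropped_and_reported(self):
        h = lk.build_histogram([0.5, 50, 2e4], lk.BinSpec(1, 10_000, 2), 0.0)
        assert h.total == 1
        assert "2 out-of-range" in h.label

    def test_invalid_spec_raises(self):
        with pytest.raises(lk.ConfigurationError):
            lk.BinSpec(10, 1, 4)
        with pytest.raises(lk.ConfigurationError):
            lk.BinSpec(-1, 10, 4, "log10")


class TestTruncate:
    def test_threshold_at_bin_boundary(self, toy_hist):
        t = lk.truncate_at_threshold(toy_hist)
        assert t.bin_edges.tolist() == [10, 100, 1000]
        assert t.counts.tolist() == [7, 9]

    def test_zero_threshold_is_noop(self):
        h = lk.FluorescenceHistogram([1, 10, 100, 1000], [5, 7, 9], 0.0)
        assert lk.truncate_at_threshold(h) == h

    def test_straddling_bin_dropped(self):
        h = lk.FluorescenceHistogram([1, 10, 100, 1000], [5, 7, 9], 50.0)
        t = lk.truncate_at_threshold(h)
        assert t.bin_edges.tolist() == [100, 1000]
        assert t.counts.tolist() == [9]

    def test_threshold_above_all_edges_warns_and_empties(self):
        h = lk.FluorescenceHistogram([1, 10, 100], [5, 7], 1e6)
        with pytest.warns(UserWarning):
            t = lk.truncate_at_threshold(h)
        assert t.n_bins == 0

    def test_idempotent(self, toy_hist):
        once = lk.truncate_at_threshold(toy_hist)
        assert lk.truncate_at_threshold(once) == once


class TestHellinger:
    def test_identity_both_modes(self, toy_hist):
        for mode in ("probability", "count"):
            assert lk.hellinger(toy_hist, toy_hist, mode) == 0.0

    def test_disjoint_support_probability_maximum(self):
        a = lk.FluorescenceHistogram([1, 10, 100], [1, 0])
        b = lk.FluorescenceHistogram([1, 10, 100], [0, 1])
        assert lk.hellinger(a, b, "probability") == pytest.approx(1.0)

    def test_count_mode_hand_computation(self):
        a = lk.FluorescenceHistogram([1, 10, 100], [4, 0])
        b = lk.FluorescenceHistogram([1, 10, 100], [0, 4])
        assert lk.hellinger(a, b, "count") == pytest.approx(2 * np.sqrt(2))

    def test_mismatched_binning_raises(self, toy_hist):
        other = lk.FluorescenceHistogram([1, 10, 100], [1, 2])
        with pytest.raises(AlignmentError):
            lk.hellinger(toy_hist, other)

    def test_all_zero_probability_mode_raises(self):
        z = lk.FluorescenceHistogram([1, 10], [0])
        with pytest.raises(ZeroDivisionError):
            lk.hellinger(z, z, "probability")

    @given(
        c1=st.lists(st.integers(0, 20), min_size=4, max_size=4),
        c2=st.lists(st.integers(0, 20), min_size=4, max_size=4),
        c3=st.lists(st.integers(0, 20), min_size=4, max_size=4),
    )
    def test_probability_mode_is_a_metric(self, c1, c2, c3):
        """Non-negativity, symmetry, identity, triangle inequality, bound."""
        if sum(c1) == 0 or sum(c2) == 0 or sum(c3) == 0:
            return
        edges = [1, 10, 100, 1000, 10_000]
        h1, h2, h3 = (lk.FluorescenceHistogram(edges, c) for c in (c1, c2, c3))
        d12 = lk.hellinger(h1, h2, "probability")
        d21 = lk.hellinger(h2, h1, "probability")
        d13 = lk.hellinger(h1, h3, "probability")
        d23 = lk.hellinger(h2, h3, "probability")
        assert 0.0 <= d12 <= 1.0
        assert d12 == pytest.approx(d21)
        if np.allclose(np.asarray(c1) / sum(c1), np.asarray(c2) / sum(c2)):
            assert d12 == pytest.approx(0.0, abs=1e-12)
        else:
            assert d12 > 0
        assert d13 <= d12 + d23 + 1e-12


class TestAlignBins:
    def test_identical_binnings_unchanged(self, toy_hist):
        a, b = lk.align_bins(toy_hist, toy_hist)
        assert a is toy_hist and b is toy_hist

    def test_log_scale_proportional_split(self):
        coarse = lk.FluorescenceHistogram([10, 1000], [10])
        fine = lk.FluorescenceHistogram([10, 100, 1000], [3, 4])
        a, b = lk.align_bins(coarse, fine)
        assert a.counts.tolist() == pytest.approx([5, 5])
        assert b.counts.tolist() == [3, 4]

    def test_disjoint_ranges_raise(self):
        a = lk.FluorescenceHistogram([1, 10], [3])
        b = lk.FluorescenceHistogram([100, 1000], [4])
        with pytest.raises(AlignmentError):
            lk.align_bins(a, b)

    @given(
        counts=st.lists(st.integers(0, 50), min_size=3, max_size=3),
        split=st.floats(1.05, 95.0),
    )
    def test_total_counts_conserved_over_overlap(self, counts, split):
        h1 = lk.FluorescenceHistogram([1, 10, 100, 1000], counts)
        h2 = lk.FluorescenceHistogram([1, split, 1000], [1, 1])
        a, _ = lk.align_bins(h1, h2)
        assert a.total == pytest.approx(h1.total, rel=1e-9, abs=1e-9)


class TestIO:
    def test_write_read_round_trip(self, toy_hist, tmp_path):
        p = tmp_path / "h.csv"
        lk.write_histogram(toy_hist, p)
        assert lk.read_histogram(p) == toy_hist

    def test_full_precision_round_trip(self, tmp_path):
        h = lk.FluorescenceHistogram(
            np.logspace(0, 5, 11), np.arange(10, dtype=float) / 3.0, 1 / 7
        )
        p = tmp_path / "h.csv"
        lk.write_histogram(h, p)
        back = lk.read_histogram(p)
        assert np.array_equal(back.bin_edges, h.bin_edges)
        assert np.array_equal(back.counts, h.counts)
        assert back.autofluorescence_threshold == h.autofluorescence_threshold

    def test_missing_column(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("bin_lo,count\n1,5\n")
        with pytest.raises(HistogramParseError, match="bin_hi"):
            lk.read_histogram(p)

    def test_non_contiguous_edges_name_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("bin_lo,bin_hi,count\n1,10,5\n20,100,7\n")
        with pytest.raises(HistogramParseError, match="row 1"):
            lk.read_histogram(p)

    def test_negative_count(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("bin_lo,bin_hi,count\n1,10,-5\n")
        with pytest.raises(HistogramParseError, match="row 0"):
            lk.read_histogram(p)
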