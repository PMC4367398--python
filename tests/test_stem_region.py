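import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_otsu, brute_within_class
from tomastem.errors import (DegenerateHistogramError, DegenerateWindowError,
                             EmptyPlantError)
from tomastem.hough import Segment
from tomastem.stem_region import (BreadthHistogram, breadth_histogram,
                                  between_class_variance, build_grid,
                                  filter_segments, median_smooth, otsu,
                                  valley_interval)


class TestGrid:
    def test_symmetric_mask_axis_is_centroid(self):
        m = np.zeros((64, 64), bool)
        m[8:56, 20:44] = True           # symmetric about col 31.5
        g = build_grid(m, cell_px=8)
        assert g.axis_col == pytest.approx(31.5)

    def test_cell_validity_threshold(self):
        # 13 foreground pixels in an 8x8 cell pass the 20% rule (12.8);
        # 12 do not.
        for count, expect in ((13, True), (12, False)):
            m = np.zeros((8, 8), bool)
            m.flat[:count] = True
            if expect:
                g = build_grid(m, cell_px=8, min_valid_frac=0.2)
                assert g.valid[0, 0]
            else:
                with pytest.raises(EmptyPlantError):
                    build_grid(m, cell_px=8, min_valid_frac=0.2)

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptyPlantError):
            build_grid(np.zeros((16, 16), bool))


class TestBreadth:
    def _grid_from_rows(self, row_cells, axis_cell=0):
        """Build a GridSystem whose valid cells per grid row are given."""
        from tomastem.stem_region import GridSystem
        n_rows = len(row_cells)
        n_cols = max(max(c) for c in row_cells if c) + 1
        valid = np.zeros((n_rows, n_cols), bool)
        for i, cells in enumerate(row_cells):
            valid[i, list(cells)] = True
        return GridSystem(cell_px=8, axis_col=axis_cell * 8 + 4, valid=valid,
                          row_start=0, row_stop=n_rows)

    def test_direct_definition(self):
        g = self._grid_from_rows([[0, 3], [0, 3], [0, 1], [1], [2], [0, 2]])
        assert list(breadth_histogram(g).n) == [3, 3, 1, 1, 2, 2]

    def test_zero_substitution_from_above(self):
        g = self._grid_from_rows([[3], [], [2]])
        assert list(breadth_histogram(g).n) == [3, 3, 2]

    def test_zero_substitution_from_below_at_top(self):
        # an empty leading row has no non-zero row above, so it inherits
        # the nearest non-zero row below
        g = self._grid_from_rows([[], [2], [2]])
        assert list(breadth_histogram(g).n) == [2, 2, 2]

    def test_axis_only_row_counts_one_cell(self):
        g = self._grid_from_rows([[0, 4], [0], [0, 3]], axis_cell=0)
        assert list(breadth_histogram(g).n) == [4, 1, 3]


class TestMedianSmooth:
    @pytest.mark.parametrize("n,window,expected", [
        ([4, 4, 4, 4], 3, [4, 4, 4, 4]),
        ([1, 9, 1, 9, 1], 3, [1, 1, 9, 1, 1]),
        ([0, 0, 7, 0, 0], 3, [0, 0, 0, 0, 0]),
    ])
    def test_examples(self, n, window, expected):
        out = median_smooth(BreadthHistogram(n=n), window)
        assert list(out.n) == expected

    def test_window_validation(self):
        with pytest.raises(ValueError):
            median_smooth(BreadthHistogram(n=[1, 2, 3]), 4)
        with pytest.raises(DegenerateWindowError):
            median_smooth(BreadthHistogram(n=[1, 2, 3]), 7)


class TestOtsu:
    def test_hand_worked_histogram(self):
        """n = [6,1,3]: split at k=1 wins with sigma_B^2 = 0.735."""
        res = otsu(BreadthHistogram(n=[6, 1, 3]))
        assert res.k_star == 1
        assert res.sigma_b2 == pytest.approx(0.735)
        assert res.omega0 == pytest.approx(0.6)
        assert res.mu1 == pytest.approx(2.75)
        # identity sigma_B^2 = w0*w1*(mu1-mu0)^2 holds on the result
        assert res.sigma_b2 == pytest.approx(
            res.omega0 * res.omega1 * (res.mu1 - res.mu0) ** 2)

    def test_tie_breaks_to_smallest_k(self):
        res = otsu(BreadthHistogram(n=[5, 5, 0, 0, 5, 5]))
        assert res.k_star == 2
        assert res.sigma_b2 == pytest.approx(4.0)

    def test_single_populated_bar_degenerate(self):
        with pytest.raises(DegenerateHistogramError):
            otsu(BreadthHistogram(n=[0, 10, 0]))

    @given(st.lists(st.integers(0, 30), min_size=2, max_size=64))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_exhaustive_oracle(self, n):
        """Argmax equals the exhaustive scan, and the between/within-class
        variances decompose the total variance at every split."""
        n = np.asarray(n)
        if (n > 0).sum() < 2:
            return
        h = BreadthHistogram(n=n)
        curve, k_oracle = brute_otsu(n)
        res = otsu(h)
        assert res.k_star == k_oracle
        assert res.sigma_b2 == pytest.approx(curve[k_oracle - 1])
        impl_curve = between_class_variance(h)
        np.testing.assert_allclose(impl_curve, curve, atol=1e-9)
        p = n / n.sum()
        pos = np.arange(1, len(n) + 1)
        total = float(((pos - (pos * p).sum()) ** 2 * p).sum())
        for k in range(1, len(n)):
            assert curve[k - 1] + brute_within_class(n, k) == pytest.approx(
                total, abs=1e-9)

    def test_agrees_with_skimage_on_unambiguous_split(self):
        """Cross-check against the scikit-image histogram Otsu."""
        from skimage.filters import threshold_otsu
        n = np.array([9, 8, 9, 1, 1, 0, 1, 7, 8, 9])
        res = otsu(BreadthHistogram(n=n))
        thr = threshold_otsu(hist=(n, np.arange(1, len(n) + 1).astype(float)))
        # skimage returns the last bin of C0 as a bin center
        assert res.k_star == int(thr)


class TestValleyInterval:
    def test_balanced_bimodal_single_pass(self):
        h = BreadthHistogram(n=[5, 6, 5, 1, 1, 5, 6, 5])
        iv = valley_interval(h, balance_ratio=1.5)
        assert iv.passes == 1
        _, k_oracle = brute_otsu(h.n)
        assert iv.k_star == k_oracle == iv.k_first

    def test_canopy_heavy_triggers_second_pass(self):
        """Top mass ~2.4x bottom: the first threshold is biased toward the
        canopy; the re-run on the weaker side lands deeper in the valley."""
        n = [9, 10, 9, 8, 2, 1, 1, 2, 4, 5, 4]
        iv = valley_interval(BreadthHistogram(n=n), balance_ratio=1.5)
        assert iv.passes == 2
        assert iv.k_star > iv.k_first
        # two-pass oracle: re-run the exhaustive scan on the weaker side
        _, k1 = brute_otsu(n)
        assert iv.k_first == k1
        if sum(n[:k1]) >= sum(n[k1:]):
            _, k2 = brute_otsu(n[k1:])
            assert iv.k_star == k1 + k2
        else:
            _, k2 = brute_otsu(n[:k1])
            assert iv.k_star == k2

    def test_infinite_balance_ratio_degenerates_to_single_pass(self):
        n = [9, 10, 9, 8, 2, 1, 1, 2, 4, 5, 4]
        iv = valley_interval(BreadthHistogram(n=n), balance_ratio=math.inf)
        assert iv.passes == 1
        assert iv.k_star == iv.k_first

    @given(st.lists(st.integers(0, 20), min_size=3, max_size=40))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_interval_brackets_threshold(self, n):
        n = np.asarray(n)
        if (n > 0).sum() < 2:
            return
        iv = valley_interval(BreadthHistogram(n=n))
        assert 1 <= iv.lo <= iv.k_star <= iv.hi <= len(n)


class TestFilterSegments:
    def _setup(self):
        from tomastem.stem_region import GridSystem, StemInterval
        valid = np.zeros((12, 10), bool)
        valid[:3, 1:9] = True      # canopy rows: width 8
        valid[3:8, 4] = True       # waist rows: width 1
        valid[8:12, 1:7] = True    # pot rows: width 6
        grid = GridSystem(cell_px=8, axis_col=36.0, valid=valid,
                          row_start=0, row_stop=12)
        iv = StemInterval(k_star=5, sigma0=2.0, sigma1=2.0, lo=3, hi=7,
                          passes=1, k_first=5)
        return grid, iv

    def seg(self, row0, row1, col=36):
        return Segment.from_endpoints((col, row0), (col, row1))

    def test_canopy_segment_removed(self):
        grid, iv = self._setup()
        # rows 0..15 px -> grid rows 1..2, entirely above lo=3
        assert filter_segments([self.seg(0, 15)], iv, grid) == []

    def test_straddling_segment_kept(self):
        grid, iv = self._setup()
        # spans grid rows 2..4: one end inside the interval
        kept = filter_segments([self.seg(12, 28)], iv, grid)
        assert len(kept) == 1

    def test_pot_width_rule(self):
        grid, iv = self._setup()
        # straddles hi, midpoint below k*; spanned rows are mostly 6 cells
        # wide (mean 4.33) -> removed at pot_breadth_max 4, kept at 8
        seg = self.seg(48, 95)
        assert filter_segments([seg], iv, grid, pot_breadth_max=4) == []
        assert filter_segments([seg], iv, grid, pot_breadth_max=8) == [seg]

    def test_output_subset_of_input(self):
        grid, iv = self._setup()
        segs = [self.seg(0, 15), self.seg(30, 60), self.seg(70, 92)]
        kept = filter_segments(segs, iv, grid)
        assert set(kept) <= set(segs)


def test_proportions_sum_to_one():
    h = BreadthHistogram(n=[3, 0, 5, 2])
    assert h.p.sum() == pytest.approx(1.0)
    assert h.N == 10
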