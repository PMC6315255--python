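import numpy as np
import pandas as pd
import pytest

from funcprofile.profiles import (
    assign_class,
    build_grid,
    chebyshev_bounds,
    drop_sparse_classes,
    function_profile,
    profile_table,
)


def seg_frame(rows):
    return pd.DataFrame(
        rows, columns=["subject_id", "day", "start", "end", "mean", "sd", "duration"]
    )


@pytest.fixture
def wide_grid():
    segs = seg_frame(
        [("s", 0, 0, 10, 4100.0, 2000.0, 10), ("s", 0, 10, 20, 100.0, 10.0, 10)]
    )
    return build_grid(segs, 700.0)


class TestGrid:
    def test_bin_counts_from_maxima(self, wide_grid):
        assert wide_grid.n_mean_bins == 6
        assert wide_grid.n_sd_bins == 3
        assert wide_grid.n_classes == 18

    def test_single_segment_grid(self):
        grid = build_grid(seg_frame([("s", 0, 0, 5, 100.0, 10.0, 5)]), 700.0)
        assert grid.n_mean_bins == 1 and grid.n_sd_bins == 1

    def test_zero_width_rejected(self, wide_grid):
        with pytest.raises(ValueError):
            build_grid(seg_frame([("s", 0, 0, 5, 1.0, 1.0, 5)]), 0.0)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            build_grid(seg_frame([]), 700.0)


class TestAssignClass:
    def test_moderate_low_sd_class(self, wide_grid):
        # the width-700 cell holding (3150, 350): mean bin 4, SD bin 0
        assert assign_class(3150.0, 350.0, wide_grid) == (4, 0)

    def test_origin(self, wide_grid):
        assert assign_class(0.0, 0.0, wide_grid) == (0, 0)

    def test_maximum_lands_in_top_bin(self, wide_grid):
        mb, sb = assign_class(wide_grid.max_mean, wide_grid.max_sd, wide_grid)
        assert mb == wide_grid.n_mean_bins - 1 and sb == wide_grid.n_sd_bins - 1

    def test_beyond_reference_clips(self, wide_grid):
        mb, sb = assign_class(99999.0, 99999.0, wide_grid)
        assert mb == wide_grid.n_mean_bins - 1 and sb == wide_grid.n_sd_bins - 1

    def test_negative_rejected(self, wide_grid):
        with pytest.raises(ValueError):
            assign_class(-1.0, 0.0, wide_grid)

    def test_refining_width_never_merges(self):
        rng = np.random.default_rng(0)
        segs = seg_frame(
            [
                ("s", 0, 0, 5, float(m), float(s), 5)
                for m, s in zip(
                    rng.uniform(0, 5000, 50), rng.uniform(0, 2500, 50)
                )
            ]
        )
        g1 = build_grid(segs, 700.0)
        g2 = build_grid(segs, 350.0)
        a1 = np.array(assign_class(segs["mean"], segs["sd"], g1)).T
        a2 = np.array(assign_class(segs["mean"], segs["sd"], g2)).T
        for i in range(len(segs)):
            for j in range(i + 1, len(segs)):
                if tuple(a1[i]) != tuple(a1[j]):
                    assert tuple(a2[i]) != tuple(a2[j])


class TestFunctionProfile:
    def test_two_day_average(self):
        grid = build_grid(seg_frame([("s", 0, 0, 5, 100.0, 10.0, 5)]), 700.0)
        segs = seg_frame(
            [("s", 0, 0, 30, 100.0, 10.0, 30), ("s", 1, 0, 50, 100.0, 10.0, 50)]
        )
        a = function_profile(segs, grid, n_valid_days=2)
        assert a.sum() == pytest.approx(40.0)

    def test_single_day_conservation(self):
        grid = build_grid(seg_frame([("s", 0, 0, 5, 100.0, 10.0, 5)]), 700.0)
        segs = seg_frame([("s", 0, 0, 700, 90.0, 5.0, 700)])
        a = function_profile(segs, grid, n_valid_days=1)
        assert a.sum() == 700.0 and (a > 0).sum() == 1

    def test_no_valid_days_rejected(self):
        grid = build_grid(seg_frame([("s", 0, 0, 5, 100.0, 10.0, 5)]), 700.0)
        with pytest.raises(ValueError):
            function_profile(seg_frame([]), grid, n_valid_days=0)

    def test_cohort_conservation_full_precision(self, small_cohort):
        """Sum of profile entries equals mean daily wear minutes exactly."""
        grid = build_grid(small_cohort.segments, 700.0)
        table = profile_table(
            small_cohort.segments, grid, small_cohort.valid_days
        )
        cols = [c for c in table.columns if c.startswith("m")]
        for _, row in table.iterrows():
            segs = small_cohort.segments[
                small_cohort.segments["subject_id"] == row["subject_id"]
            ]
            expected = segs["duration"].sum() / row["K"]
            assert row[cols].sum() == pytest.approx(expected, rel=1e-12)

    def test_intense_classes_are_sparse(self, small_cohort):
        """Time thins out toward high-mean classes: the top-quartile
        mean bins hold less total time than the bottom mean bin."""
        segs = small_cohort.segments
        grid = build_grid(segs, 700.0)
        mb, _ = assign_class(segs["mean"], segs["sd"], grid)
        top = mb >= int(np.ceil(0.75 * grid.n_mean_bins))
        bottom = mb == 0
        assert segs.loc[top, "duration"].sum() < segs.loc[bottom, "duration"].sum()

    def test_sparse_column_dropping(self):
        df = pd.DataFrame(
            {
                "subject_id": list("abcde"),
                "K": [1] * 5,
                "m0_700_s0_700": [1.0, 2.0, 3.0, 4.0, 5.0],
                "m700_1400_s0_700": [0.0, 0.0, 0.0, 1.0, 0.0],
            }
        )
        out = drop_sparse_classes(df, min_support=3)
        assert "m0_700_s0_700" in out.columns
        assert "m700_1400_s0_700" not in out.columns


class TestChebyshev:
    def test_moderate_class_endpoints(self):
        lo, hi, p = chebyshev_bounds((2800, 3500), (0, 700), k=1.8)
        assert (lo, hi) == (2520.0, 3780.0)
        assert p == pytest.approx(1 - 1 / 1.8**2)

    def test_higher_sd_class_upper_endpoint(self):
        _, hi, _ = chebyshev_bounds((2800, 3500), (1400, 2100), k=1.8)
        assert hi == 6300.0

    def test_k_one_gives_vacuous_bound(self):
        assert chebyshev_bounds((0, 700), (0, 700), k=1.0)[2] == 0.0

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            chebyshev_bounds((0, 700), (0, 700), k=0.0)
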