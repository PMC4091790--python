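"""Unit and property tests for the sliding-window scanner statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from spermage import (
    bh_fdr,
    call_and_merge,
    confirm_ttest,
    enumerate_windows,
    paired_wilcoxon,
    pseudo_median,
    regression_filter,
    transform_fdr,
    window_log2_ratio,
)

from oracles import (
    bh_stepup,
    ols_slope,
    paired_t_p_df2,
    walsh_median,
    wilcoxon_enumeration,
)


def _manifest(positions, chrom="chr1"):
    return pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(len(positions))],
            "chrom": chrom,
            "pos": positions,
        }
    )


class TestEnumerateWindows:
    def test_three_probes_within_span_form_one_window(self):
        win = enumerate_windows(_manifest([11, 501, 901]))
        assert len(win) == 1
        row = win.iloc[0]
        assert (row.start, row.end, row.n_probes) == (10, 1010, 3)

    def test_sparse_probes_yield_no_window(self):
        assert enumerate_windows(_manifest([10, 5000])).empty

    def test_tight_probe_cluster_collapses_to_single_candidate(self):
        # 5 probes within 100 bp: later anchors cover subsets of the first
        win = enumerate_windows(_manifest([101, 121, 141, 161, 201]))
        assert len(win) == 1
        assert win.iloc[0].n_probes == 5

    def test_empty_manifest(self):
        assert enumerate_windows(_manifest([])).empty

    def test_overlapping_distinct_probe_sets_are_kept(self):
        # second anchor reaches a probe the first cannot: both survive
        win = enumerate_windows(_manifest([1, 401, 801, 1201]))
        assert len(win) == 2


class TestPseudoMedian:
    def test_constant_and_symmetry(self):
        assert pseudo_median([0.4, 0.4, 0.4]) == pytest.approx(0.4)
        assert pseudo_median([-1, 0, 1]) == pytest.approx(0.0)

    def test_walsh_enumeration_example(self):
        assert pseudo_median([1, 2, 6]) == pytest.approx(2.75)

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(
            st.floats(-10, 10, allow_nan=False, allow_infinity=False),
            min_size=1,
            max_size=50,
        )
    )
    def test_matches_walsh_average_oracle(self, values):
        assert pseudo_median(values) == pytest.approx(walsh_median(values))


class TestPairedWilcoxon:
    def test_all_positive_n5(self):
        assert paired_wilcoxon([1, 2, 3, 4, 5]) == pytest.approx(2 / 32)

    def test_perfectly_balanced_pair(self):
        assert paired_wilcoxon([-1, 1]) == pytest.approx(1.0)

    def test_all_zero_differences_returns_one(self):
        assert paired_wilcoxon([0.0, 0.0, 0.0]) == 1.0

    def test_large_one_sided_sample_is_astronomically_significant(self):
        rng = np.random.default_rng(0)
        d = -np.abs(rng.normal(1.0, 0.1, size=85))
        assert paired_wilcoxon(d) < 1e-14

    @settings(max_examples=80, derandomize=True)
    @given(
        st.lists(
            st.integers(-5, 5).map(float),
            min_size=1,
            max_size=10,
        )
    )
    def test_exact_mode_matches_sign_flip_enumeration(self, diffs):
        if all(d == 0 for d in diffs):
            return
        assert paired_wilcoxon(diffs) == pytest.approx(wilcoxon_enumeration(diffs))

    def test_normal_approximation_agrees_with_scipy(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            d = rng.normal(0.1, 1.0, size=40)
            ours = paired_wilcoxon(d)
            ref = sps.wilcoxon(d, correction=False, method="approx").pvalue
            assert ours == pytest.approx(ref, rel=1e-9)


class TestBhFdr:
    def test_single_value_passthrough(self):
        assert bh_fdr([0.05]) == pytest.approx([0.05])

    def test_three_value_stepup_by_hand(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_stepup_properties_and_oracle(self, p):
        q = bh_fdr(p)
        assert np.all(q >= np.asarray(p) - 1e-12)
        assert np.all(q <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert q == pytest.approx(bh_stepup(p))


class TestTransformFdr:
    def test_printed_reference_points(self):
        assert transform_fdr(0.0001) == pytest.approx(40.0)
        assert transform_fdr(0.01) == pytest.approx(20.0)
        assert transform_fdr(1.0) == pytest.approx(0.0)

    def test_strictly_decreasing_and_floored(self):
        qs = np.array([1e-3, 1e-2, 0.5, 1.0])
        out = transform_fdr(qs)
        assert np.all(np.diff(out) < 0)
        assert transform_fdr(0.0) == pytest.approx(300.0)  # floored at 1e-30


class TestWindowLog2Ratio:
    def test_equal_pseudomedians_give_zero(self):
        assert window_log2_ratio(0.37, 0.37) == pytest.approx(0.0, abs=1e-9)

    def test_hypomethylation_is_negative(self):
        assert window_log2_ratio(0.4, 0.5) == pytest.approx(-0.321928, abs=1e-4)

    def test_threshold_corresponds_to_roughly_ten_percent_change(self):
        # |log2| = 0.2 at baseline 0.5 is an absolute beta change of ~0.05-0.07
        up = 0.5 * (2**0.2 - 1)
        down = 0.5 * (1 - 2**-0.2)
        assert 0.05 <= down <= up <= 0.08


class TestRegressionFilter:
    def test_noiseless_line_recovers_slope_and_keeps(self):
        ages = np.array([25.0, 30.0, 40.0, 55.0, 60.0])
        means = 0.6 - 0.003 * ages
        slope, p, keep = regression_filter(means, ages)
        assert slope == pytest.approx(-0.003)
        assert keep and p < 1e-6

    def test_constant_mean_is_dropped(self):
        ages = np.array([25.0, 30.0, 40.0])
        slope, p, keep = regression_filter(np.full(3, 0.5), ages)
        assert slope == pytest.approx(0.0)
        assert not keep

    def test_zero_age_variance_drops_window(self):
        slope, p, keep = regression_filter([0.1, 0.2, 0.3], [40.0, 40.0, 40.0])
        assert not keep and np.isnan(slope)

    def test_slope_matches_closed_form_ols(self):
        ages = [20.0, 35.0, 50.0]
        means = [0.61, 0.55, 0.44]
        slope, _, _ = regression_filter(means, ages)
        assert slope == pytest.approx(ols_slope(ages, means))


class TestConfirmTtest:
    def test_equal_nonzero_differences_flag_undefined_variance(self):
        p = confirm_ttest([0.5, 0.6, 0.7], [0.45, 0.55, 0.65])
        assert np.isnan(p)

    def test_three_pair_p_matches_closed_form(self):
        young = np.array([0.5, 0.5, 0.5])
        aged = young + np.array([-0.05, -0.04, -0.06])
        assert confirm_ttest(young, aged) == pytest.approx(
            paired_t_p_df2([-0.05, -0.04, -0.06])
        )

    def test_identical_groups_have_zero_mean_difference(self):
        y = np.array([0.2, 0.4, 0.6])
        assert np.isnan(confirm_ttest(y, y))  # zero differences, zero variance


class TestCallAndMerge:
    @staticmethod
    def _win(start, end, log2, q=5e-5, keep=True, chrom="chr1"):
        return dict(
            chrom=chrom, start=start, end=end, log2_ratio=log2, q_bh=q,
            regression_keep=keep,
        )

    def test_threshold_application(self):
        win = pd.DataFrame([self._win(0, 1000, -0.3)])
        regions = call_and_merge(win)
        assert list(regions["direction"]) == ["hypo"]

    def test_overlapping_same_direction_windows_merge(self):
        win = pd.DataFrame([self._win(100, 1100, -0.3), self._win(600, 1600, -0.4)])
        regions = call_and_merge(win)
        assert len(regions) == 1
        assert (regions.iloc[0].start, regions.iloc[0].end) == (100, 1600)
        assert regions.iloc[0].n_windows == 2

    def test_book_ended_windows_merge(self):
        win = pd.DataFrame([self._win(0, 1000, -0.3), self._win(1000, 2000, -0.3)])
        assert len(call_and_merge(win)) == 1

    def test_opposite_directions_stay_separate(self):
        win = pd.DataFrame([self._win(100, 1100, -0.3), self._win(600, 1600, 0.4)])
        regions = call_and_merge(win)
        assert len(regions) == 2
        assert set(regions["direction"]) == {"hypo", "hyper"}

    def test_filters_respected(self):
        win = pd.DataFrame(
            [
                self._win(0, 1000, -0.1),          # log2 too small
                self._win(2000, 3000, -0.5, q=0.01),  # q too large
                self._win(4000, 5000, -0.5, keep=False),  # regression filtered
            ]
        )
        assert call_and_merge(win).empty
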