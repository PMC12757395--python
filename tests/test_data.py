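"""Unit tests for signal normalization, windowing, aggregation and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from glymseg import (
    RegionMap,
    RegionSeries,
    aggregate_regions,
    cohort_summary,
    filter_scan_window,
    load_scan_table,
    normalize_signal,
    region_series,
)
from glymseg.data import chi_square_test, pooled_t_test
from glymseg.exceptions import (
    DegenerateTestError,
    EmptySeriesError,
    InvalidReferenceError,
    MappingError,
    MissingCohortError,
)


class TestNormalizeSignal:
    @pytest.mark.parametrize(
        "raw, ref, expected",
        [(100.0, 50.0, 2.0), (7.3, 7.3, 1.0), (1.0, 4.0, 0.25)],
    )
    def test_ratio(self, raw, ref, expected):
        assert normalize_signal(raw, ref) == pytest.approx(expected)

    @pytest.mark.parametrize("bad_ref", [0.0, -1.0, np.nan, np.inf])
    def test_invalid_reference(self, bad_ref):
        with pytest.raises(InvalidReferenceError):
            normalize_signal(100.0, bad_ref)

    @given(
        raw=st.floats(0.1, 1e4), ref=st.floats(0.1, 1e4), scale=st.floats(1e-3, 1e3)
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, raw, ref, scale):
        assert normalize_signal(scale * raw, scale * ref) == pytest.approx(
            normalize_signal(raw, ref), rel=1e-9
        )


class TestFilterScanWindow:
    def test_drops_late_scans_keeps_preinjection(self):
        s = RegionSeries("REF", "r",
                         np.array([-0.5, 0.5, 2.0, 6.5, 24.1, 48.0]),
                         np.ones(6))
        out, n_removed = filter_scan_window(s, 7.0)
        assert out.time_h.tolist() == [-0.5, 0.5, 2.0, 6.5]
        assert n_removed == 2

    def test_noop_when_all_within_window(self, noiseless_series):
        out, n_removed = filter_scan_window(noiseless_series, 7.0)
        assert n_removed == 0
        np.testing.assert_array_equal(out.time_h, noiseless_series.time_h)

    def test_empty_result_raises(self):
        s = RegionSeries("REF", "r", np.array([24.0, 48.0]), np.ones(2))
        with pytest.raises(EmptySeriesError):
            filter_scan_window(s, 7.0)

    def test_idempotent(self, noiseless_series):
        once, _ = filter_scan_window(noiseless_series, 4.0)
        twice, n = filter_scan_window(once, 4.0)
        assert n == 0
        np.testing.assert_array_equal(once.time_h, twice.time_h)
        np.testing.assert_array_equal(once.signal, twice.signal)


class TestAggregateRegions:
    def _map(self, mode="unweighted_mean"):
        return RegionMap(
            {"ctx-lh-frontal": "frontal cortex", "ctx-rh-frontal": "frontal cortex"},
            mode=mode,
        )

    def _two_segment_frame(self, s1, s2, v1=1.0, v2=1.0):
        return pd.DataFrame(
            {
                "subject_id": ["a", "a"],
                "cohort": ["REF", "REF"],
                "region": ["ctx-lh-frontal", "ctx-rh-frontal"],
                "time_h": [1.0, 1.0],
                "signal": [s1, s2],
                "volume_mm3": [v1, v2],
            }
        )

    def test_unweighted_mean(self):
        out = aggregate_regions(self._two_segment_frame(1.0, 3.0), self._map())
        assert out["signal"].tolist() == [2.0]
        assert out["region"].tolist() == ["frontal cortex"]

    def test_volume_weighted_mean(self):
        out = aggregate_regions(
            self._two_segment_frame(1.0, 3.0, v1=1.0, v2=3.0),
            self._map("volume_weighted_mean"),
        )
        assert out["signal"].tolist() == [2.5]

    def test_equal_volumes_match_unweighted(self):
        df = self._two_segment_frame(1.2, 3.4, v1=7.0, v2=7.0)
        w = aggregate_regions(df, self._map("volume_weighted_mean"))
        u = aggregate_regions(df, self._map())
        assert w["signal"].tolist() == pytest.approx(u["signal"].tolist())

    def test_single_segment_identity(self):
        df = self._two_segment_frame(1.7, 9.9).iloc[:1]
        out = aggregate_regions(df, self._map())
        assert out["signal"].tolist() == [1.7]

    def test_unmapped_segment_named_in_error(self):
        df = self._two_segment_frame(1.0, 2.0)
        with pytest.raises(MappingError, match="ctx-lh-frontal"):
            aggregate_regions(df, RegionMap({"ctx-rh-frontal": "frontal cortex"}))


class TestCohortSummary:
    def test_identical_groups_t_zero(self):
        out = cohort_summary(values_by_group={"a": [1, 2, 3], "b": [1, 2, 3]})
        assert out["statistic"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)

    def test_pooled_t_against_hand_formula(self):
        # independent oracle: pooled-variance formula evaluated directly
        a, b = np.array([0.0, 0.0, 1.0, 1.0]), np.array([2.0, 2.0, 3.0, 3.0])
        sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
            a.size + b.size - 2
        )
        t_expected = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / a.size + 1 / b.size))
        p_expected = 2 * stats.t.sf(abs(t_expected), a.size + b.size - 2)
        t, p, dof = pooled_t_test(a, b)
        assert t == pytest.approx(t_expected)  # -4.898979...
        assert p == pytest.approx(p_expected)
        assert dof == 6

    def test_chi_square_independence(self):
        out = cohort_summary(counts=[[10, 10], [10, 10]])
        assert out["statistic"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)

    @given(st.integers(1, 50), st.integers(1, 50), st.integers(2, 5))
    @settings(max_examples=25, deadline=None)
    def test_proportional_rows_give_zero_statistic(self, a, b, k):
        stat, p, _ = chi_square_test([[a, b], [k * a, k * b]])
        assert stat == pytest.approx(0.0, abs=1e-10)

    def test_degenerate_zero_variance(self):
        with pytest.raises(DegenerateTestError):
            pooled_t_test([3.0, 3.0, 3.0], [3.0, 3.0])


class TestScanTableIO:
    def test_roundtrip_and_region_series(self, scan_frame, tmp_path):
        path = tmp_path / "scans.csv"
        scan_frame.to_csv(path, index=False)
        df = load_scan_table(path)
        s = region_series(df, "REF", "ctx-lh-frontal")
        assert s.n_subjects == 2
        assert s.n_obs == 10

    def test_signal_checked_against_raw_ratio(self, tmp_path):
        df = pd.DataFrame(
            {
                "subject_id": ["a"], "cohort": ["REF"], "region": ["r"],
                "time_h": [1.0], "signal": [2.0], "raw_t1": [100.0], "ref_t1": [49.0],
            }
        )
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="line 2"):
            load_scan_table(path)

    def test_missing_cohort(self, scan_frame):
        with pytest.raises(MissingCohortError):
            region_series(scan_frame, "NPH", "ctx-lh-frontal")
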