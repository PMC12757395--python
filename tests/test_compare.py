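"""Tests for the two-cohort z test, Holm adjustment and joint model."""

import numpy as np
import pytest

from glymseg import (
    BreakpointEstimate,
    RegionSeries,
    SegmentedRegressor,
    compare_breakpoints,
    comparison_table,
    fit_joint_two_group,
    holm_adjust,
)
from glymseg.compare import attach_holm, grid_profile_oracle_2d
from glymseg.datasets import load_cohort_breakpoint_table
from glymseg.exceptions import EmptyFamilyError, NonConvergenceError


def _holm_stepdown_reference(p):
    """Direct sequential-rejection definition of Holm's procedure."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[idx]))
        adj[idx] = running
    return adj


class TestCompareBreakpoints:
    def test_published_parietal_white_matter_difference(self):
        tab = load_cohort_breakpoint_table().set_index("region")
        r = tab.loc["parietal white matter"]
        c = compare_breakpoints(
            BreakpointEstimate.from_ci(r.psi_ref, r.ref_lo, r.ref_hi),
            BreakpointEstimate.from_ci(r.psi_iih, r.iih_lo, r.iih_hi),
        )
        assert round(c.diff, 1) == 2.4
        assert (round(c.ci_diff[0], 1), round(c.ci_diff[1], 1)) == (1.5, 3.3)
        assert c.p < 0.001

    def test_published_temporal_cortex_difference(self):
        tab = load_cohort_breakpoint_table().set_index("region")
        r = tab.loc["temporal cerebral cortex"]
        c = compare_breakpoints(
            BreakpointEstimate.from_ci(r.psi_ref, r.ref_lo, r.ref_hi),
            BreakpointEstimate.from_ci(r.psi_iih, r.iih_lo, r.iih_hi),
        )
        assert round(c.diff, 1) == -0.6
        assert round(c.p, 3) == 0.035

    def test_identical_models(self):
        e = BreakpointEstimate(psi=1.5, se_psi=0.2)
        c = compare_breakpoints(e, e)
        assert c.diff == 0.0
        assert c.z == 0.0
        assert c.p == pytest.approx(1.0)

    def test_antisymmetry(self):
        a = BreakpointEstimate(psi=1.0, se_psi=0.3)
        b = BreakpointEstimate(psi=2.2, se_psi=0.5)
        fwd, rev = compare_breakpoints(a, b), compare_breakpoints(b, a)
        assert rev.diff == pytest.approx(-fwd.diff)
        assert rev.z == pytest.approx(-fwd.z)
        assert rev.p == pytest.approx(fwd.p)
        assert fwd.se_diff == pytest.approx(np.hypot(0.3, 0.5))

    def test_unconverged_model_rejected(self, noiseless_series):
        m = SegmentedRegressor()  # not fitted
        with pytest.raises(NonConvergenceError):
            compare_breakpoints(m, BreakpointEstimate(1.0, 0.1))


class TestHolm:
    def test_single_p_unchanged(self):
        adj, flags = holm_adjust([0.04])
        assert adj[0] == pytest.approx(0.04)
        assert flags[0]

    def test_two_values(self):
        adj, flags = holm_adjust([0.01, 0.04])
        assert adj == pytest.approx([0.02, 0.04])
        assert flags.all()

    def test_matches_direct_stepdown_and_bonferroni_bound(self):
        rng = np.random.default_rng(31)
        p = rng.uniform(1e-4, 1.0, size=17)
        adj, flags = holm_adjust(p)
        np.testing.assert_allclose(adj, _holm_stepdown_reference(p), atol=1e-12)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= np.minimum(17 * p, 1.0) + 1e-15)

    def test_published_family_leaves_two_regions_significant(self):
        tab = load_cohort_breakpoint_table()
        adj, flags = holm_adjust(tab["p"].to_numpy())
        assert sorted(tab.region[flags]) == [
            "insular white matter",
            "parietal white matter",
        ]

    def test_empty_family(self):
        with pytest.raises(EmptyFamilyError):
            holm_adjust([])

    def test_attach_holm_orders_preserved(self):
        a = BreakpointEstimate(1.0, 0.1)
        b = BreakpointEstimate(1.5, 0.1)
        comps = [compare_breakpoints(a, b, region="x"),
                 compare_breakpoints(a, a, region="y")]
        out = attach_holm(comps)
        assert [c.region for c in out] == ["x", "y"]
        assert all(c.p_holm >= c.p for c in out)

    def test_comparison_table_columns_and_rounding(self):
        tab = load_cohort_breakpoint_table()
        comps = [
            compare_breakpoints(
                BreakpointEstimate.from_ci(r.psi_ref, r.ref_lo, r.ref_hi),
                BreakpointEstimate.from_ci(r.psi_iih, r.iih_lo, r.iih_hi),
                region=r.region,
            )
            for r in tab.itertuples()
        ]
        df = comparison_table(comps, decimals=1)
        assert df.shape[0] == 17
        assert df["significant_holm"].sum() == 2
        row = df.set_index("region").loc["parietal white matter"]
        assert (row["diff"], row["ci_low"], row["ci_high"]) == (2.4, 1.5, 3.3)


class TestJointTwoGroup:
    def _series(self, t, y, cohort):
        return RegionSeries(cohort, "r", t, y)

    def test_identical_groups_match_single_fit(self, noiseless_series):
        m = fit_joint_two_group(noiseless_series, noiseless_series)
        assert m.psi_[0] == pytest.approx(2.0, abs=1e-6)
        assert m.psi_[1] == pytest.approx(2.0, abs=1e-6)
        assert m.beta0_ == pytest.approx(10.0, abs=1e-6)
        np.testing.assert_allclose(m.beta1_, [5.0, 5.0], atol=1e-6)

    def test_exact_recovery_shared_baseline(self):
        t = np.array([-1.0, 0.0, 0.5, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0])
        s_ref = self._series(t, 10.0 + 4.0 * np.maximum(t - 1.0, 0.0), "REF")
        s_iih = self._series(t, 10.0 + 2.0 * np.maximum(t - 3.0, 0.0), "IIH")
        m = fit_joint_two_group(s_ref, s_iih)
        assert m.beta0_ == pytest.approx(10.0, abs=1e-7)
        np.testing.assert_allclose(m.psi_, [1.0, 3.0], atol=1e-7)
        np.testing.assert_allclose(m.beta1_, [4.0, 2.0], atol=1e-7)
        assert m.groups_ == ("REF", "IIH")

    def test_agrees_with_2d_grid_oracle(self):
        from glymseg import SimulationScenario, simulate_cohort

        rng = np.random.default_rng(404)
        s_ref, _ = simulate_cohort(
            SimulationScenario(true_psi=1.0, n_subjects=20, seed=0), rng=rng
        )
        s_iih, _ = simulate_cohort(
            SimulationScenario(true_psi=3.0, n_subjects=12, seed=0), rng=rng
        )
        m = fit_joint_two_group(s_ref, s_iih)
        grid = np.arange(0.2, 5.5, 0.05)
        (p0, p1), rss = grid_profile_oracle_2d(s_ref, s_iih, grid, grid)
        assert abs(m.psi_[0] - p0) <= 0.05 + 1e-9
        assert abs(m.psi_[1] - p1) <= 0.05 + 1e-9
        assert m.rss_ <= rss + 1e-9

    def test_no_preinjection_scans_in_one_group(self):
        t_ok = np.array([-1.0, 0.5, 1.5, 2.5, 3.5, 4.5])
        t_bad = np.array([0.5, 1.5, 2.5, 3.5, 4.5, 5.5])
        s_ok = self._series(t_ok, 1 + 0.1 * np.maximum(t_ok - 1, 0), "REF")
        s_bad = self._series(t_bad, 1 + 0.1 * np.maximum(t_bad - 1, 0), "IIH")
        with pytest.raises(NonConvergenceError, match="pre-breakpoint"):
            fit_joint_two_group(s_ok, s_bad)
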