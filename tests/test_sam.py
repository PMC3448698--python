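"""SAM statistic, fudge factor, permutation null, calling and δ choice."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from probescreen.sam import (build_delta_table, call_significant, choose_delta,
                             estimate_pi0, estimate_s0, fold_change,
                             sam_permutation_test, sam_statistic)


def _theta(rows, columns=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    columns = columns or [f"s{i}" for i in range(rows.shape[1])]
    return pd.DataFrame(rows, columns=columns)


def _groups(theta, n1):
    return pd.Series(["g1"] * n1 + ["g2"] * (theta.shape[1] - n1), index=theta.columns)


class TestStatistic:
    def test_textbook_pooled_t_example(self):
        theta = _theta([[1, 2, 3, 4, 5, 6]])
        out = sam_statistic(theta, _groups(theta, 3), "g1", "g2", s0=0.0)
        assert out["d"].iloc[0] == pytest.approx(3.6742346, abs=1e-6)

    def test_equal_means_give_zero_d(self):
        theta = _theta([[1, 2, 3, 3, 2, 1]])
        for s0 in (0.0, 0.5, 2.0):
            out = sam_statistic(theta, _groups(theta, 3), "g1", "g2", s0=s0)
            assert out["d"].iloc[0] == 0.0

    def test_d_strictly_decreases_with_s0(self):
        theta = _theta([[1, 2, 3, 7, 8, 9]])
        groups = _groups(theta, 3)
        ds = [abs(sam_statistic(theta, groups, "g1", "g2", s0=s0)["d"].iloc[0])
              for s0 in (0.0, 0.5, 1.0, 2.0)]
        assert all(a > b for a, b in zip(ds, ds[1:]))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(2, 5), st.integers(2, 5))
    def test_d_at_zero_s0_is_pooled_t(self, seed, n1, n2):
        rng = np.random.default_rng(seed)
        theta = _theta(rng.normal(0, 1, (40, n1 + n2)))
        groups = _groups(theta, n1)
        d = sam_statistic(theta, groups, "g1", "g2", s0=0.0)["d"].values
        t = sps.ttest_ind(theta.values[:, n1:], theta.values[:, :n1], axis=1).statistic
        assert np.allclose(d, t, rtol=1e-12, atol=1e-12)

    def test_swapping_groups_negates_d(self, two_group_theta):
        theta, groups = two_group_theta
        fwd = sam_statistic(theta, groups, "g1", "g2", s0=0.1)
        rev = sam_statistic(theta, groups, "g2", "g1", s0=0.1)
        assert np.allclose(fwd["d"].values, -rev["d"].values)
        assert np.allclose(fwd["r"].values, -rev["r"].values)

    def test_zero_scatter_sentinel(self):
        theta = _theta([[1, 1, 1, 2, 2, 2]])
        out = sam_statistic(theta, _groups(theta, 3), "g1", "g2", s0=0.0)
        assert np.isposinf(out["d"].iloc[0])


class TestFudgeFactor:
    def test_all_equal_scatter_returns_zero_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert estimate_s0(np.arange(200.0), np.full(200, 2.0)) == 0.0

    def test_chosen_s0_stabilizes_d(self, two_group_theta):
        theta, groups = two_group_theta
        out = sam_statistic(theta, groups, "g1", "g2", s0=0.0)
        r, s = out["r"].values, out["s"].values
        s0 = estimate_s0(r, s)

        def cv(alpha, n_bins=20):
            d = r / (s + alpha)
            edges = np.quantile(s, np.linspace(0, 1, n_bins + 1))
            idx = np.clip(np.searchsorted(edges[1:-1], s, side="right"), 0, n_bins - 1)
            mads = [np.median(np.abs(d[idx == b] - np.median(d[idx == b])))
                    for b in range(n_bins) if (idx == b).sum() >= 2]
            return np.std(mads, ddof=1) / np.mean(mads)

        assert cv(s0) <= cv(0.0) + 1e-12

    def test_scale_equivariance(self, two_group_theta):
        theta, groups = two_group_theta
        out = sam_statistic(theta, groups, "g1", "g2", s0=0.0)
        s0 = estimate_s0(out["r"].values, out["s"].values)
        s0_scaled = estimate_s0(7.0 * out["r"].values, 7.0 * out["s"].values)
        assert s0_scaled == pytest.approx(7.0 * s0, rel=1e-12)


class TestPermutationNull:
    def test_three_vs_three_enumerates_twenty_splits(self, two_group_theta):
        theta, groups = two_group_theta
        null = sam_permutation_test(theta, groups, "g1", "g2", n_permutations=800, seed=0)
        assert null.exhaustive and null.n_permutations == 20 and null.n_distinct == 20

    def test_identical_samples_give_zero_null(self):
        theta = _theta(np.tile([[5.0]], (10, 6)))
        null = sam_permutation_test(theta, _groups(theta, 3), "g1", "g2", seed=0, s0=1.0)
        assert np.allclose(null.d_bar, 0.0)
        assert np.allclose(null.d_star, 0.0)

    def test_sampled_permutations_deterministic_under_seed(self):
        rng = np.random.default_rng(8)
        theta = _theta(rng.normal(0, 1, (50, 12)))
        groups = _groups(theta, 6)  # C(12,6) = 924 > 100 -> sampling
        a = sam_permutation_test(theta, groups, "g1", "g2", n_permutations=100, seed=3)
        b = sam_permutation_test(theta, groups, "g1", "g2", n_permutations=100, seed=3)
        c = sam_permutation_test(theta, groups, "g1", "g2", n_permutations=100, seed=4)
        assert not a.exhaustive and a.n_permutations == 100
        assert np.array_equal(a.d_star, b.d_star)
        assert not np.array_equal(a.d_star, c.d_star)

    def test_null_quantiles_track_expected_order_statistics(self, two_group_theta):
        theta, groups = two_group_theta
        out = sam_statistic(theta, groups, "g1", "g2", s0=0.0)
        s0 = estimate_s0(out["r"].values, out["s"].values)
        d = np.sort(sam_statistic(theta, groups, "g1", "g2", s0=s0)["d"].values)
        null = sam_permutation_test(theta, groups, "g1", "g2", seed=0, s0=s0)
        # on null data the observed order statistics hug the null expectation
        assert np.mean(np.abs(d - null.d_bar) > 1.0) < 0.01

    def test_rejects_zero_permutations(self, two_group_theta):
        theta, groups = two_group_theta
        with pytest.raises(ValueError):
            sam_permutation_test(theta, groups, "g1", "g2", n_permutations=0)


class TestCallingAndDelta:
    def _null_parts(self, two_group_theta):
        theta, groups = two_group_theta
        out = sam_statistic(theta, groups, "g1", "g2", s0=0.0)
        s0 = estimate_s0(out["r"].values, out["s"].values)
        d = sam_statistic(theta, groups, "g1", "g2", s0=s0)["d"].values
        null = sam_permutation_test(theta, groups, "g1", "g2", seed=0, s0=s0)
        fold = fold_change(theta, groups, "g1", "g2").values
        return d, null, fold

    def test_infinite_delta_calls_nothing(self, two_group_theta):
        d, null, fold = self._null_parts(two_group_theta)
        res = call_significant(d, null.d_bar, np.inf, fold, d_star=null.d_star)
        assert res.n_called == 0 and res.median_fdr == 0.0

    def test_null_data_at_zero_delta_two_sided(self, two_group_theta):
        # with fold_min = 1 the up/down fold gates split the null sets in two,
        # so about half of them are called at delta = 0
        d, null, fold = self._null_parts(two_group_theta)
        pi0 = estimate_pi0(d, null.d_star)
        res = call_significant(d, null.d_bar, 0.0, fold, fold_min=1.0,
                               direction="both", d_star=null.d_star, pi0=pi0)
        # essentially half the sets called; estimated FDR near 1
        assert 0.25 <= res.n_called / len(d) <= 0.75
        assert res.median_fdr > 0.8

    def test_fold_gate_blocks_large_d(self):
        d = np.array([0.0, 5.0])
        d_bar = np.zeros(2)
        fold = np.array([1.0, 1.5])
        res = call_significant(d, d_bar, delta=1.0, fold_change=fold, fold_min=2.0)
        assert res.n_called == 0
        res = call_significant(d, d_bar, delta=1.0, fold_change=fold, fold_min=1.2)
        assert res.n_called == 1

    def test_choose_delta_definition_on_monotone_table(self, two_group_theta):
        d, null, fold = self._null_parts(two_group_theta)
        table = build_delta_table(d, null.d_bar, fold, fold_min=1.0,
                                  d_star=null.d_star, pi0=1.0, n_steps=50)
        target = 0.2
        delta = choose_delta(table, target_fdr=target)
        row = table[table["delta"] == delta].iloc[0]
        assert row["median_fdr"] < target
        earlier = table[table["delta"] < delta]
        assert (earlier["median_fdr"] >= target).all()

    def test_choose_delta_target_one_returns_zero(self, two_group_theta):
        d, null, fold = self._null_parts(two_group_theta)
        table = build_delta_table(d, null.d_bar, fold, fold_min=1.0,
                                  d_star=null.d_star, pi0=1.0, n_steps=50)
        assert choose_delta(table, target_fdr=1.01) == 0.0

    def test_choose_delta_warns_when_unreachable(self):
        table = pd.DataFrame({"delta": [0.0, 1.0], "n_called": [5, 2],
                              "median_fdr": [0.5, 0.4]})
        with pytest.warns(UserWarning, match="no delta"):
            assert choose_delta(table, target_fdr=0.0) == 1.0

    def test_fold_change_floor_stabilizes_small_values(self):
        theta = _theta([[0.0, 0.0, 0.0, 0.1, 0.1, 0.1]])
        groups = _groups(theta, 3)
        assert fold_change(theta, groups, "g1", "g2", floor=1.0).iloc[0] == pytest.approx(1.1)
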