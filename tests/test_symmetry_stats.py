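"""Symmetry Index and Wilcoxon signed-rank statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mammometry.errors import StatsError
from mammometry.metrology import Measurement, MeasurementTable
from mammometry.symmetry_stats import (MEASUREMENT_NAMES, compare_methods,
                                       descriptive_table, symmetry_index,
                                       wilcoxon_signed_rank)

positive_values = st.lists(
    st.floats(min_value=0.5, max_value=50.0, allow_nan=False), min_size=7,
    max_size=7)


def brute_force_wilcoxon_p(d):
    """Two-tailed exact p by explicit enumeration of all 2^n sign flips."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    w_all = [np.array(signs) @ ranks
             for signs in itertools.product([0, 1], repeat=len(d))]
    w_all = np.asarray(w_all)
    p_le = np.mean(w_all <= w_obs + 1e-12)
    p_ge = np.mean(w_all >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


def table_from_values(scan_id, left, right, method="automatic"):
    records = [Measurement(name=n, side=s, value=v, method=method)
               for s, vals in (("left", left), ("right", right))
               for n, v in zip(MEASUREMENT_NAMES, vals)]
    return MeasurementTable(scan_id=scan_id, records=records)


class TestSymmetryIndex:
    def test_identical_sides_give_100(self):
        values = dict(zip(MEASUREMENT_NAMES, [21.5, 8.5, 16.1, 12.4, 11.8,
                                              24.9, 20.8]))
        assert symmetry_index(values, values).symmetry_index == 100.0

    def test_single_measurement_ratio(self):
        left = dict(zip(MEASUREMENT_NAMES, [8.0] * 7))
        right = dict(zip(MEASUREMENT_NAMES, [10.0] * 7))
        result = symmetry_index(left, right, included=["SN_N"])
        assert result.symmetry_index == pytest.approx(80.0)

    @given(positive_values, positive_values,
           st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=50, deadline=None)
    def test_side_swap_and_scale_invariance(self, left, right, c):
        si_lr = symmetry_index(left, right).symmetry_index
        si_rl = symmetry_index(right, left).symmetry_index
        si_scaled = symmetry_index([c * v for v in left],
                                   [c * v for v in right]).symmetry_index
        assert si_lr == si_rl
        assert si_scaled == pytest.approx(si_lr, rel=1e-12)
        assert 0.0 < si_lr <= 100.0

    def test_strictly_decreasing_in_any_single_ratio(self):
        left = [20.0] * 7
        right = [20.0] * 7
        base = symmetry_index(left, right).symmetry_index
        for i in range(7):
            worse = list(right)
            worse[i] = 18.0
            si = symmetry_index(left, worse).symmetry_index
            assert si < base

    def test_errors(self):
        good = dict(zip(MEASUREMENT_NAMES, [1.0] * 7))
        bad = dict(good, SN_N=-1.0)
        with pytest.raises(StatsError, match="nonpositive"):
            symmetry_index(bad, good)
        with pytest.raises(StatsError, match="empty"):
            symmetry_index(good, good, included=[])


class TestWilcoxon:
    @pytest.mark.parametrize("seed,n,with_ties", [(0, 6, False), (1, 9, False),
                                                  (2, 12, False), (3, 10, True)])
    def test_exact_p_matches_brute_force(self, seed, n, with_ties):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = x + rng.normal(scale=0.8, size=n)
        if with_ties:
            y = x + rng.choice([-0.5, 0.5, 1.0], size=n)  # tied |differences|
        result = wilcoxon_signed_rank(x, y)
        assert result.p_two_tailed == pytest.approx(
            brute_force_wilcoxon_p(x - y), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=15)
        y = x + rng.normal(scale=1.0, size=15)
        ours = wilcoxon_signed_rank(x, y)
        ref = sps.wilcoxon(x, y, mode="exact")
        assert ours.p_two_tailed == pytest.approx(ref.pvalue, rel=1e-9)
        assert ours.statistic == pytest.approx(ref.statistic)

    def test_large_shift_is_significant(self):
        rng = np.random.default_rng(11)
        y = rng.normal(size=10)
        x = y + 5.0 + 0.1 * rng.normal(size=10)
        assert wilcoxon_signed_rank(x, y).p_two_tailed < 0.05

    def test_all_zero_differences_reported_undefined(self):
        x = np.arange(8.0)
        result = wilcoxon_signed_rank(x, x)
        assert np.isnan(result.p_two_tailed)
        assert result.n_zero_dropped == 8
        assert not result.defined

    def test_zero_differences_dropped(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([1.0, 2.5, 2.0, 4.0, 4.2, 6.5])
        result = wilcoxon_signed_rank(x, y)
        assert result.n_zero_dropped == 2
        assert result.p_two_tailed == pytest.approx(
            brute_force_wilcoxon_p(x - y), abs=1e-12)

    def test_invariant_under_common_shift(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=14)
        y = x + rng.normal(scale=0.5, size=14)
        p1 = wilcoxon_signed_rank(x, y).p_two_tailed
        p2 = wilcoxon_signed_rank(x + 100.0, y + 100.0).p_two_tailed
        assert p1 == p2

    def test_normal_approximation_close_to_exact_at_boundary(self):
        # compare the two modes on the same 26-pair sample by forcing a
        # fictitious 26th pair through both code paths
        rng = np.random.default_rng(31)
        x = rng.normal(size=26)
        y = x + rng.normal(scale=1.0, size=26)
        from mammometry.symmetry_stats import (_exact_p_two_tailed,
                                               _normal_p_two_tailed)
        d = x - y
        ranks = sps.rankdata(np.abs(d))
        w_plus = ranks[d > 0].sum()
        p_exact = _exact_p_two_tailed(ranks, w_plus)
        p_normal = _normal_p_two_tailed(ranks, w_plus)
        assert p_normal == pytest.approx(p_exact, abs=0.02)


class TestCohortSummaries:
    def test_single_scan_descriptives(self):
        table = table_from_values("s1", [10.0] * 7, [12.0] * 7)
        rows = descriptive_table([table])
        for row in rows:
            assert row.n == 1
            assert row.minimum == row.maximum == row.median == 11.0
            assert row.sd == 0.0

    def test_descriptives_match_direct_recomputation(self, rng):
        tables = []
        for i in range(6):
            left = rng.uniform(5, 25, size=7)
            right = rng.uniform(5, 25, size=7)
            tables.append(table_from_values(f"s{i}", left, right))
        rows = {r.name: r for r in descriptive_table(tables)}
        sn_means = [t.mean_left_right("SN_N") for t in tables]
        assert rows["SN_N"].median == pytest.approx(np.median(sn_means))
        assert rows["SN_N"].sd == pytest.approx(np.std(sn_means, ddof=1))
        assert rows["SN_N"].minimum == pytest.approx(min(sn_means))

    def test_compare_methods_has_eight_rows(self, rng):
        manual, automatic = [], []
        for i in range(12):
            left = rng.uniform(8, 25, size=7)
            right = rng.uniform(8, 25, size=7)
            manual.append(table_from_values(f"s{i}", left, right, "manual"))
            automatic.append(table_from_values(
                f"s{i}", left + rng.normal(scale=0.1, size=7),
                right + rng.normal(scale=0.1, size=7), "automatic"))
        rows = compare_methods(manual, automatic)
        assert len(rows) == 8
        assert [r.name for r in rows] == list(MEASUREMENT_NAMES) + ["SI"]

    def test_identical_methods_give_undefined_tests(self, rng):
        tables_m, tables_a = [], []
        for i in range(5):
            left = rng.uniform(8, 25, size=7)
            right = rng.uniform(8, 25, size=7)
            tables_m.append(table_from_values(f"s{i}", left, right, "manual"))
            tables_a.append(table_from_values(f"s{i}", left, right, "automatic"))
        rows = compare_methods(tables_m, tables_a)
        assert all(np.isnan(r.p_two_tailed) for r in rows)

    def test_bias_in_one_measurement_flags_only_that_row(self, rng):
        manual, automatic = [], []
        for i in range(20):
            left = rng.uniform(10, 25, size=7)
            right = rng.uniform(10, 25, size=7)
            manual.append(table_from_values(f"s{i}", left, right, "manual"))
            biased_l = left + rng.normal(scale=0.05, size=7)
            biased_r = right + rng.normal(scale=0.05, size=7)
            biased_l[2] += 1.5  # constant offset in UBP_N only
            biased_r[2] += 1.5
            automatic.append(table_from_values(f"s{i}", biased_l, biased_r,
                                               "automatic"))
        rows = {r.name: r for r in compare_methods(manual, automatic)}
        assert rows["UBP_N"].p_two_tailed < 0.05
        for name in ("SN_N", "LBP_N", "XI_N", "LABP_N", "BREAST_WIDTH",
                     "IMF_LENGTH"):
            assert rows[name].p_two_tailed > 0.05

    def test_mismatched_cohorts_rejected(self, rng):
        a = [table_from_values("s1", [10.0] * 7, [11.0] * 7, "manual")]
        b = [table_from_values("s2", [10.0] * 7, [11.0] * 7, "automatic")]
        with pytest.raises(StatsError, match="mismatched"):
            compare_methods(a, b)
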