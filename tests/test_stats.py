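import itertools
import math

import numpy as np
import pandas as pd
import pytest

from fgfr2axis import DegenerateTableError
from fgfr2axis.reference import (
    ASSOCIATION_TABLES,
    LAUREN_BY_ESRP1,
    LAUREN_BY_IIIC,
    SUBTYPE_BY_IIIC,
    VITAL_BY_IIIC,
)
from fgfr2axis.stats import (
    benjamini_hochberg,
    build_table1,
    contingency_test,
    km_estimate,
    logrank,
    pairwise_logrank,
    students_t,
    survival_from_clinical,
    wilcoxon_rank_sum,
)


def enumerate_rank_sum_p(x, y):
    """Independent exact two-sided rank-sum p: full enumeration of rank splits."""
    pooled = sorted(x) + sorted(y)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    n, total = len(x), len(pooled)
    w_obs = sum(ranks[v] for v in x)
    mean = n * (total + 1) / 2
    dev = abs(w_obs - mean)
    splits = list(itertools.combinations(range(1, total + 1), n))
    hits = sum(1 for s in splits if abs(sum(s) - mean) >= dev - 1e-9)
    return hits / len(splits)


def hand_product_limit(records):
    """Independent product-limit survival: explicit risk-set bookkeeping."""
    times = sorted({t for t, _ in records})
    surv, s = {}, 1.0
    for t in times:
        at_risk = sum(1 for ti, _ in records if ti >= t)
        deaths = sum(1 for ti, e in records if ti == t and e == 1)
        s *= 1.0 - deaths / at_risk
        surv[t] = s
    return surv


class TestContingency:
    def test_proportional_rows_give_independence(self):
        result = contingency_test([[1, 2], [2, 4], [3, 6]])
        assert result.statistic == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0)

    def test_yates_applied_only_to_2x2(self):
        assert contingency_test(VITAL_BY_IIIC).correction == "yates"
        assert contingency_test(LAUREN_BY_IIIC).correction == "none"

    def test_invariant_under_row_and_column_permutation(self):
        base = contingency_test(SUBTYPE_BY_IIIC)
        shuffled = SUBTYPE_BY_IIIC.iloc[[2, 0, 3, 1], [1, 0]]
        perm = contingency_test(shuffled)
        assert perm.statistic == pytest.approx(base.statistic)
        assert perm.p_value == pytest.approx(base.p_value)

    def test_zero_margin_is_degenerate(self):
        with pytest.raises(DegenerateTableError):
            contingency_test([[0, 0], [3, 4]])

    def test_published_association_pvalues(self):
        expected = {
            "lauren_by_iiic": 1.21e-6,
            "vital_by_iiic": 1.46e-2,
            "subtype_by_iiic": 3.54e-7,
            "lauren_by_esrp1": 3.14e-10,
        }
        for name, table in ASSOCIATION_TABLES.items():
            p = contingency_test(table).p_value
            assert p == pytest.approx(expected[name], rel=5e-3), name


class TestWilcoxonRankSum:
    def test_small_exact_two_sided(self):
        result = wilcoxon_rank_sum([1, 2], [3, 4], mode="exact")
        assert result.p_value == pytest.approx(1 / 3)

    def test_identical_samples_give_unit_p(self):
        result = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert result.p_value == pytest.approx(1.0)

    def test_large_shift_detected(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 200)
        y = rng.normal(2, 1, 200)
        assert wilcoxon_rank_sum(x, y).p_value < 1e-6

    def test_exact_mode_matches_full_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(1, 6))
            m = int(rng.integers(1, 11 - n))
            pooled = rng.choice(np.arange(1, 100), size=n + m, replace=False).astype(float)
            x, y = pooled[:n], pooled[n:]
            got = wilcoxon_rank_sum(x, y, mode="exact").p_value
            want = enumerate_rank_sum_p(list(x), list(y))
            assert got == pytest.approx(want, abs=1e-12), (x, y)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestStudentsT:
    def test_identical_groups_give_unit_p(self):
        result = students_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert result.p_value == pytest.approx(1.0)

    def test_degenerate_variance_flagged(self):
        result = students_t([0.0, 0.0], [1.0, 1.0])
        assert result.p_value == pytest.approx(0.0)
        assert result.flag == "degenerate-variance"

    def test_pooled_t_matches_hand_computation(self):
        result = students_t([1, 2, 3], [2, 3, 4])
        assert result.statistic == pytest.approx(-math.sqrt(1.5))
        # closed-form two-sided p: numeric integration of the t density, df=4
        df = 4
        c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
        grid = np.linspace(abs(result.statistic), 60, 400_000)
        tail = np.trapezoid(c * (1 + grid**2 / df) ** (-(df + 1) / 2), grid)
        assert result.p_value == pytest.approx(2 * tail, rel=1e-5)


class TestKaplanMeier:
    def test_distinct_events_step_by_quarter(self):
        curve = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        assert np.allclose(curve.survival, [0.75, 0.5, 0.25, 0.0])
        assert np.allclose(curve.at_risk, [4, 3, 2, 1])

    def test_all_censored_curve_is_flat_at_one(self):
        curve = km_estimate([5, 6, 7], [0, 0, 0])
        assert np.allclose(curve.survival, 1.0)

    def test_mixed_set_matches_hand_product_limit(self):
        records = [(1, 1), (2, 0), (3, 1)]
        curve = km_estimate([t for t, _ in records], [e for _, e in records])
        want = hand_product_limit(records)
        for t, s in want.items():
            assert curve.survival_at(t) == pytest.approx(s)
        assert curve.survival_at(3) == pytest.approx(0.0)

    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(10, size=60).round(1)
        curve = km_estimate(times, np.ones_like(times, dtype=int))
        for t in np.unique(times):
            ecdf = np.mean(times <= t)
            assert curve.survival_at(t) == pytest.approx(1 - ecdf, abs=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1, 2], [1, 1])


class TestLogrank:
    def test_identical_groups_give_null_result(self):
        times = [1, 2, 3, 4, 1, 2, 3, 4]
        events = [1, 1, 0, 1] * 2
        groups = ["a"] * 4 + ["b"] * 4
        result = logrank(times, events, groups)
        assert result.statistic == pytest.approx(0.0, abs=1e-10)
        assert result.p_value == pytest.approx(1.0)

    def test_label_permutation_symmetry(self):
        rng = np.random.default_rng(5)
        times = rng.exponential(10, 40)
        events = rng.integers(0, 2, 40)
        groups = np.array(["a"] * 20 + ["b"] * 20)
        r1 = logrank(times, events, groups)
        swapped = np.where(groups == "a", "b", "a")
        r2 = logrank(times, events, swapped)
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_no_events_is_degenerate(self):
        with pytest.raises(DegenerateTableError):
            logrank([1, 2], [0, 0], ["a", "b"])

    def test_single_group_is_degenerate(self):
        with pytest.raises(DegenerateTableError):
            logrank([1, 2], [1, 1], ["a", "a"])

    def test_pairwise_covers_all_label_pairs(self):
        rng = np.random.default_rng(6)
        times = rng.exponential(10, 60)
        events = np.ones(60, dtype=int)
        groups = np.repeat(["a", "b", "c"], 20)
        pairs = pairwise_logrank(times, events, groups)
        assert set(map(tuple, pairs[["group_a", "group_b"]].values)) == {
            ("a", "b"), ("a", "c"), ("b", "c")}


class TestBuildTable1:
    @staticmethod
    def states_from_counts(table, factor_name, category_name):
        rows = []
        for level, counts in table.iterrows():
            for category, n in counts.items():
                rows.extend(
                    {factor_name: level, category_name: category} for _ in range(int(n))
                )
        df = pd.DataFrame(rows)
        df["sample_id"] = [f"S{i}" for i in range(len(df))]
        return df

    def test_reconstructed_lauren_by_esrp1_reproduces_published_p(self):
        states = self.states_from_counts(LAUREN_BY_ESRP1, "lauren", "esrp1_expr_cat")
        table, result = build_table1(states, "lauren", "esrp1_expr_cat")
        assert result.p_value == pytest.approx(3.14e-10, rel=5e-3)
        assert table.loc["Diffuse", "below"] == 17

    def test_na_level_displayed_but_not_tested(self):
        states = self.states_from_counts(VITAL_BY_IIIC, "stage", "iiic_cat")
        na_rows = pd.DataFrame(
            {"stage": ["NA"] * 5, "iiic_cat": ["above"] * 5,
             "sample_id": [f"N{i}" for i in range(5)]})
        with_na = pd.concat([states, na_rows], ignore_index=True)
        table_na, result_na = build_table1(with_na, "stage", "iiic_cat")
        _, result_plain = build_table1(states, "stage", "iiic_cat")
        assert "NA" in table_na.index
        assert result_na.p_value == pytest.approx(result_plain.p_value)

    def test_single_level_factor_is_degenerate(self):
        states = pd.DataFrame(
            {"lauren": ["Diffuse"] * 4, "iiic_cat": ["above", "below"] * 2,
             "sample_id": list("abcd")})
        with pytest.raises(DegenerateTableError):
            build_table1(states, "lauren", "iiic_cat")


class TestSurvivalPlumbing:
    def test_time_and_event_derived_from_vital_status(self):
        clin = pd.DataFrame(
            {
                "sample_id": ["A", "B"],
                "vital_status": ["Dead", "Alive"],
                "days_to_death": [100.0, np.nan],
                "days_to_last_follow_up": [np.nan, 300.0],
            }
        )
        surv = survival_from_clinical(clin)
        assert list(surv["time"]) == [100.0, 300.0]
        assert list(surv["event"]) == [1, 0]

    def test_bh_adjustment_is_monotone_and_bounded(self):
        p = [0.001, 0.01, 0.04, 0.5]
        adj = benjamini_hochberg(p)
        assert np.all(adj >= p)
        assert np.all(adj <= 1.0)
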