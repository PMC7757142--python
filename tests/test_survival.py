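"""Closure tables, percent-permeable curves, and the Mantel-Cox log-rank."""

import itertools

import numpy as np
import pandas as pd
import pytest

from fusbbb import (
    EnhancementRecord,
    bonferroni_threshold,
    build_closure_table,
    compare_all_groups,
    generate_group_fixture,
    logrank_test,
    percent_permeable,
)
from conftest import random_closure_table


def make_records(flags_by_focus, mouse="m0"):
    records = []
    for focus, flags in enumerate(flags_by_focus):
        for t, flag in zip((0.0, 6.0, 12.0, 20.0), flags):
            records.append(
                EnhancementRecord(
                    mouse=mouse, focus=focus, timepoint_h=t,
                    roi_mean=0.0, contra_mean=0.0, contra_sd=0.0, permeable=flag,
                )
            )
    return records


def brute_force_logrank(ta, oa, tb, ob):
    """Independent evaluation of the Mantel-Cox hypergeometric sums."""
    times = sorted(set([t for t, o in zip(ta, oa) if o] + [t for t, o in zip(tb, ob) if o]))
    num = var = 0.0
    for t in times:
        na = sum(1 for x in ta if x >= t)
        nb = sum(1 for x in tb if x >= t)
        n = na + nb
        da = sum(1 for x, o in zip(ta, oa) if o and x == t)
        db = sum(1 for x, o in zip(tb, ob) if o and x == t)
        d = da + db
        if n <= 1 or d == 0:
            continue
        num += da - d * na / n
        var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    return num * num / var


class TestBuildClosureTable:
    def test_first_closure_rule(self):
        table = build_closure_table(make_records([(True, False, False, False)]))
        assert table.iloc[0]["event_time_h"] == 6.0
        assert table.iloc[0]["event"] == "closed"

    def test_never_closed_censored_at_20h(self):
        table = build_closure_table(make_records([(True, True, True, True)]))
        assert table.iloc[0]["event_time_h"] == 20.0
        assert table.iloc[0]["event"] == "censored"

    def test_reopening_scored_at_first_closure_and_logged(self, caplog):
        with caplog.at_level("WARNING"):
            table = build_closure_table(make_records([(True, False, True, False)]))
        assert table.iloc[0]["event_time_h"] == 6.0
        assert "re-opened" in caplog.text

    def test_focus_not_open_at_t0_excluded_with_warning(self, caplog):
        recs = make_records([(False, False, False, False), (True, True, True, True)])
        with caplog.at_level("WARNING"):
            table = build_closure_table(recs)
        assert len(table) == 1
        assert "opening failed" in caplog.text

    def test_missing_timepoint_is_an_error(self):
        recs = make_records([(True, True, True, True)])
        recs += make_records([(True, False)], mouse="m1")  # only 0 and 6 h
        with pytest.raises(ValueError, match="missing a timepoint"):
            build_closure_table(recs)


class TestPercentPermeable:
    @pytest.mark.parametrize(
        "label,printed",
        [("TgCRND8-VT", (26, 17, 13)), ("nonTg-PBS", (83, 54, 42))],
    )
    def test_canonical_fixtures_match_printed_percentages(self, label, printed):
        table = generate_group_fixture(label).to_closure_table()
        curve = percent_permeable(table, label)
        assert curve.percent_permeable[0] == 100.0
        assert tuple(round(p) for p in curve.percent_permeable[1:]) == printed

    def test_all_closed_by_6h(self):
        table = pd.DataFrame(
            {
                "mouse": "m0", "focus": range(4), "group": "g",
                "event_time_h": 6.0, "event": "closed",
            }
        )
        curve = percent_permeable(table, "g")
        assert curve.percent_permeable == (100.0, 0.0, 0.0, 0.0)

    def test_curve_non_increasing_and_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            table = random_closure_table(rng, "g", 23)
            p = percent_permeable(table, "g").percent_permeable
            assert all(100.0 >= a >= b >= 0.0 for a, b in zip(p, p[1:]))

    def test_empty_group_rejected(self):
        table = generate_group_fixture("nonTg-VT").to_closure_table()
        with pytest.raises(ValueError):
            percent_permeable(table, "no-such-group")


class TestLogrank:
    def test_identical_tables_give_null_result(self):
        t = generate_group_fixture("TgCRND8-PBS").to_closure_table()
        res = logrank_test(t, t)
        assert res.chi_square == 0.0 and res.p_value == 1.0

    def test_hand_example_matches_brute_force(self):
        a = pd.DataFrame(
            {"mouse": "a", "focus": range(3), "group": "A",
             "event_time_h": [6.0, 6.0, 20.0],
             "event": ["closed", "closed", "censored"]}
        )
        b = pd.DataFrame(
            {"mouse": "b", "focus": range(3), "group": "B",
             "event_time_h": [20.0, 20.0, 20.0], "event": ["closed"] * 3}
        )
        res = logrank_test(a, b)
        expected = brute_force_logrank(
            [6.0, 6.0, 20.0], [True, True, False], [20.0] * 3, [True] * 3
        )
        assert res.chi_square == pytest.approx(expected, abs=1e-12)

    def test_canonical_treated_vs_untreated_transgenic_significant(self):
        a = generate_group_fixture("TgCRND8-VT").to_closure_table()
        b = generate_group_fixture("TgCRND8-PBS").to_closure_table()
        res = logrank_test(a, b)
        assert res.p_value < 0.0125

    def test_symmetry_under_group_swap(self):
        rng = np.random.default_rng(1)
        a = random_closure_table(rng, "A", 20)
        b = random_closure_table(rng, "B", 25, p=(0.5, 0.2, 0.1, 0.2))
        r1, r2 = logrank_test(a, b), logrank_test(b, a)
        assert r1.chi_square == pytest.approx(r2.chi_square, abs=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)

    def test_matches_lifelines_on_random_tables(self):
        """Chi-square agrees with an established survival library to 1e-8."""
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(2)
        for _ in range(50):
            na, nb = rng.integers(5, 31, 2)
            a = random_closure_table(rng, "A", na, p=rng.dirichlet(np.ones(4)))
            b = random_closure_table(rng, "B", nb, p=rng.dirichlet(np.ones(4)))
            if not ((a["event"] == "closed").any() or (b["event"] == "closed").any()):
                continue
            mine = logrank_test(a, b)
            ref = ll_logrank(
                a["event_time_h"], b["event_time_h"],
                event_observed_A=(a["event"] == "closed").astype(int),
                event_observed_B=(b["event"] == "closed").astype(int),
            )
            assert mine.chi_square == pytest.approx(ref.test_statistic, abs=1e-8)
            assert mine.p_value == pytest.approx(ref.p_value, abs=1e-8)

    def test_no_events_rejected(self):
        t = pd.DataFrame(
            {"mouse": "m", "focus": [0], "group": "g",
             "event_time_h": [20.0], "event": ["censored"]}
        )
        with pytest.raises(ValueError):
            logrank_test(t, t)

    def test_null_calibration_of_type_i_error(self):
        """Two groups drawn from the same discrete closure distribution
        reject at alpha=0.05 in 5% +/- 2% of replicates."""
        rng = np.random.default_rng(3)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = random_closure_table(rng, "A", 23)
            b = random_closure_table(rng, "B", 23)
            if not ((a["event"] == "closed").any() or (b["event"] == "closed").any()):
                continue
            if logrank_test(a, b).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07


class TestMultipleComparisons:
    @pytest.mark.parametrize(
        "alpha,m,expected", [(0.05, 4, 0.0125), (0.05, 1, 0.05), (0.01, 5, 0.002)]
    )
    def test_bonferroni_threshold(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 4)

    def test_four_pairs_tested_at_corrected_threshold(self):
        tables = pd.concat(
            [generate_group_fixture(g).to_closure_table()
             for g in ("TgCRND8-VT", "TgCRND8-PBS", "nonTg-VT", "nonTg-PBS")],
            ignore_index=True,
        )
        pairs = [
            ("TgCRND8-VT", "TgCRND8-PBS"),
            ("nonTg-VT", "nonTg-PBS"),
            ("TgCRND8-PBS", "nonTg-PBS"),
            ("TgCRND8-VT", "nonTg-VT"),
        ]
        results = compare_all_groups(tables, pairs, alpha=0.05)
        assert all(r.threshold == pytest.approx(0.0125) for r in results)
        by_label = {r.comparison: r for r in results}
        assert by_label["TgCRND8-VT vs TgCRND8-PBS"].significant

    def test_identical_groups_never_significant(self):
        t = generate_group_fixture("nonTg-PBS").to_closure_table()
        t2 = t.copy()
        t2["group"] = "nonTg-PBS-copy"
        both = pd.concat([t, t2], ignore_index=True)
        res = compare_all_groups(both, [("nonTg-PBS", "nonTg-PBS-copy")])
        assert not res[0].significant and res[0].p_value == 1.0

    def test_unknown_group_rejected(self):
        t = generate_group_fixture("nonTg-PBS").to_closure_table()
        with pytest.raises(ValueError, match="unknown group"):
            compare_all_groups(t, [("nonTg-PBS", "ghost")])
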