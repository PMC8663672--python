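import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from biocue.scales import (
    DEFAULT_SCALE_CONFIGS,
    ScaleConfig,
    pearson_r,
    scale_scores,
    score_report,
    sus_score,
    wilcoxon_matched_pairs,
)


def sus_oracle(responses):
    return (sum(r - 1 for r in responses[0::2])
            + sum(5 - r for r in responses[1::2])) * 2.5


class TestSusScore:
    def test_most_favorable_pattern_scores_100(self):
        assert sus_score([5, 1] * 5) == 100.0

    def test_least_favorable_pattern_scores_0(self):
        assert sus_score([1, 5] * 5) == 0.0

    def test_all_neutral_scores_50(self):
        assert sus_score([3] * 10) == 50.0

    @settings(max_examples=300, derandomize=True)
    @given(st.lists(st.integers(1, 5), min_size=10, max_size=10))
    def test_matches_formula_oracle(self, responses):
        score = sus_score(responses)
        assert score == sus_oracle(responses)
        assert 0.0 <= score <= 100.0
        assert score % 2.5 == 0.0  # image is the 2.5-grid

    def test_monotone_in_positive_antitone_in_negative_items(self):
        base = [3] * 10
        for i in range(10):
            up = list(base)
            up[i] = 4
            if i % 2 == 0:  # positively worded (odd item number)
                assert sus_score(up) > sus_score(base)
            else:
                assert sus_score(up) < sus_score(base)

    def test_missing_item_rejected(self):
        with pytest.raises(ValueError):
            sus_score([3] * 9)
        with pytest.raises(ValueError):
            sus_score([3] * 9 + [None])


def long_table(instrument, rows):
    """rows: (respondent, timepoint, item, response)"""
    return pd.DataFrame(
        [(r, tp, instrument, i, v) for r, tp, i, v in rows],
        columns=["respondent_id", "timepoint", "instrument", "item_id",
                 "response"])


class TestScaleScores:
    def test_uniform_responses_score_as_the_response(self):
        config = DEFAULT_SCALE_CONFIGS["AQ-SF"]
        table = long_table("AQ-SF", [("p1", "T0", i, 1) for i in config.items])
        out = scale_scores(table, config)
        assert out.loc[("p1", "T0"), "total"] == 1.0
        for sub in config.subscales:
            assert out.loc[("p1", "T0"), sub] == 1.0
        absq = DEFAULT_SCALE_CONFIGS["ABSQ"]
        t2 = long_table("ABSQ", [("p1", "T0", i, 5) for i in absq.items])
        assert scale_scores(t2, absq).loc[("p1", "T0"), "total"] == 5.0

    def test_reverse_keyed_items_reflected(self):
        config = ScaleConfig(name="X", items=("a", "b"),
                             reverse_items=frozenset({"b"}))
        table = long_table("X", [("p", "T0", "a", 5), ("p", "T0", "b", 5)])
        # b reflects 5 -> 1, so mean is (5+1)/2
        assert scale_scores(table, config).loc[("p", "T0"), "total"] == 3.0

    def test_proration_and_missing_threshold(self):
        config = DEFAULT_SCALE_CONFIGS["AQ-SF"]
        # 10 of 12 items answered (83%): total prorated; the subscale with
        # only 1 of 3 answered (33%) is a missing marker
        rows = [("p", "T0", i, 2) for i in config.items[:10]]
        out = scale_scores(long_table("AQ-SF", rows), config)
        assert out.loc[("p", "T0"), "total"] == 2.0
        assert math.isnan(out.loc[("p", "T0"), "hostility"])

    def test_random_tables_match_independent_recomputation(self, rng):
        config = DEFAULT_SCALE_CONFIGS["STAXI-2"]
        rows = []
        for r in ("p1", "p2", "p3"):
            for tp in ("T0", "T1"):
                for i in config.items:
                    rows.append((r, tp, i, int(rng.integers(1, 5))))
        table = long_table("STAXI-2", rows)
        out = scale_scores(table, config)
        for (r, tp), grp in table.groupby(["respondent_id", "timepoint"]):
            vals = dict(zip(grp["item_id"], grp["response"]))
            for sub, ids in config.subscales.items():
                expect = np.mean([vals[i] for i in ids])
                assert out.loc[(r, tp), sub] == pytest.approx(expect)
            assert out.loc[(r, tp), "total"] == pytest.approx(
                np.mean([vals[i] for i in config.items]))

    def test_row_order_invariance(self, rng):
        config = DEFAULT_SCALE_CONFIGS["ABSQ"]
        rows = [("p", "T0", i, int(rng.integers(1, 6))) for i in config.items]
        table = long_table("ABSQ", rows)
        shuffled = table.sample(frac=1, random_state=0).reset_index(drop=True)
        pd.testing.assert_frame_equal(scale_scores(table, config),
                                      scale_scores(shuffled, config))

    def test_out_of_range_response_rejected(self):
        config = DEFAULT_SCALE_CONFIGS["STAXI-2"]  # 1..4
        table = long_table("STAXI-2", [("p", "T0", config.items[0], 5)]
                           + [("p", "T0", i, 2) for i in config.items[1:]])
        with pytest.raises(ValueError):
            scale_scores(table, config)


def rank_with_average_ties(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        for k in range(i, j + 1):
            ranks[order[k]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def wilcoxon_enumeration_oracle(pre, post):
    """Brute force over all sign vectors; own ranking code."""
    d = [b - a for a, b in zip(pre, post) if b != a]
    ranks = rank_with_average_ties([abs(x) for x in d])
    w_plus = sum(r for x, r in zip(d, ranks) if x > 0)
    w_minus = sum(r for x, r in zip(d, ranks) if x < 0)
    w, total = min(w_plus, w_minus), w_plus + w_minus
    le = ge = 0
    for bits in itertools.product((0, 1), repeat=len(d)):
        wp = sum(r for b, r in zip(bits, ranks) if b)
        le += wp <= w
        ge += wp >= total - w
    return w, min(1.0, (le + ge) / 2 ** len(d))


class TestWilcoxon:
    def test_identical_vectors_degenerate(self):
        res = wilcoxon_matched_pairs([1, 2, 3], [1, 2, 3])
        assert (res.p, res.w, res.n_effective) == (1.0, 0.0, 0)
        assert res.method == "degenerate"

    def test_six_distinct_positive_differences(self):
        res = wilcoxon_matched_pairs([1, 2, 3, 4, 5, 6],
                                     [2, 4, 6, 8, 10, 12])
        assert res.p == pytest.approx(2 / 2 ** 6)
        assert res.w == 0.0
        assert res.z > 0  # post > pre

    def test_sign_of_z_follows_direction(self):
        res = wilcoxon_matched_pairs([5, 6, 7, 8, 9, 10], [1, 2, 3, 4, 5, 6])
        assert res.z < 0

    def test_random_instances_match_enumeration_oracle(self, rng):
        for _ in range(40):
            n = int(rng.integers(2, 11))
            pre = rng.integers(0, 6, n).astype(float)
            post = rng.integers(0, 6, n).astype(float)  # ties and zeros likely
            if np.all(pre == post):
                continue
            res = wilcoxon_matched_pairs(pre, post)
            w, p = wilcoxon_enumeration_oracle(pre, post)
            assert res.method == "exact"
            assert res.w == pytest.approx(w)
            assert res.p == pytest.approx(p, abs=1e-12)

    def test_agrees_with_scipy_on_tiefree_data(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 13))
            pre = rng.normal(0, 1, n)
            post = pre + rng.normal(0.3, 1, n)
            res = wilcoxon_matched_pairs(pre, post)
            ref = stats.wilcoxon(post, pre, method="exact")
            assert res.w == pytest.approx(ref.statistic)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_close_to_exact_at_n15(self, rng):
        # checked under a clear shift: the approximation's tail accuracy is
        # what significance decisions rely on
        for _ in range(10):
            pre = rng.normal(0, 1, 15)
            post = pre + rng.normal(1.0, 1, 15)
            exact = wilcoxon_matched_pairs(pre, post, exact_threshold=15)
            approx = wilcoxon_matched_pairs(pre, post, exact_threshold=0)
            assert approx.method == "normal"
            assert abs(exact.p - approx.p) < 0.01

    def test_pratt_policy_keeps_zero_ranks_out_but_counted(self):
        pre = [1.0, 2.0, 3.0, 4.0]
        post = [1.0, 4.0, 6.0, 9.0]  # one zero difference
        res_w = wilcoxon_matched_pairs(pre, post, zero_policy="wilcox")
        res_p = wilcoxon_matched_pairs(pre, post, zero_policy="pratt")
        assert res_w.n_effective == res_p.n_effective == 3
        # pratt ranks |d| including the zero, shifting ranks up by one
        assert res_p.w == res_w.w  # both zero here (all positive)
        assert res_p.p <= 1.0


class TestPearson:
    def test_perfect_positive_linear(self):
        r, df, p = pearson_r([1, 2, 3, 4], [3, 5, 7, 9])
        assert r == pytest.approx(1.0)
        assert df == 2

    def test_perfect_negative(self):
        r, _, _ = pearson_r([1, 2, 3, 4], [-1, -2, -3, -4])
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        x = rng.normal(0, 1, 10)
        y = rng.normal(0, 1, 10)
        r, df, p = pearson_r(x, y)
        expect = (np.sum((x - x.mean()) * (y - y.mean()))
                  / np.sqrt(np.sum((x - x.mean()) ** 2)
                            * np.sum((y - y.mean()) ** 2)))
        assert r == pytest.approx(expect, abs=1e-12)
        assert df == 8
        t = expect * np.sqrt(8 / (1 - expect ** 2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 8), abs=1e-12)

    def test_affine_invariance(self, rng):
        x = rng.normal(0, 1, 12)
        y = rng.normal(0, 1, 12)
        r1, _, _ = pearson_r(x, y)
        r2, _, _ = pearson_r(3.0 * x + 7.0, 0.5 * y - 2.0)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_spearman_flag(self):
        r, _, _ = pearson_r([1, 2, 3, 4], [1, 8, 27, 64], method="spearman")
        assert r == pytest.approx(1.0)


class TestScoreReport:
    def test_table_shape_and_wilcoxon_columns(self, rng):
        config = DEFAULT_SCALE_CONFIGS["ABSQ"]
        rows = []
        for r in [f"p{k}" for k in range(6)]:
            for tp in ("T0", "T1"):
                for i in config.items:
                    rows.append((r, tp, i, int(rng.integers(1, 6))))
        table = long_table("ABSQ", rows)
        report = score_report(table, {"ABSQ": config})
        assert len(report) == 1
        row = report.iloc[0]
        assert row["scale"] == "total"
        assert not math.isnan(row["mean_T0"]) and not math.isnan(row["sd_T1"])
        assert row["n_pairs"] == 6
        assert 0 <= row["p"] <= 1
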