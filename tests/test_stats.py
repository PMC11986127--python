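import numpy as np
import pandas as pd
import pytest

import mstates as ms
from mstates.stats import GroupSummary, ARSQ_DOMAINS


def summaries_of(groups):
    return [GroupSummary(float(np.mean(g)), float(np.std(g, ddof=1)), len(g))
            for g in groups]


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        res = ms.anova_oneway([g, g.copy(), g.copy()])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_raw_and_summary_agree_exactly(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(i, 1 + i / 2, 10 + 5 * i) for i in range(3)]
        raw = ms.anova_oneway(groups)
        summ = ms.anova_from_summary(summaries_of(groups))
        assert summ.statistic == pytest.approx(raw.statistic, abs=1e-10)
        assert summ.p_raw == pytest.approx(raw.p_raw, abs=1e-10)
        assert summ.df == raw.df

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1.2, 15)
        f = ms.anova_oneway([a, b]).statistic
        t = ms.pairwise_t(a, b).statistic
        assert f == pytest.approx(t ** 2, rel=1e-10)

    def test_equal_means_zero_f_from_summary(self):
        res = ms.anova_from_summary([GroupSummary(5.0, 1.0, 10),
                                     GroupSummary(5.0, 2.0, 20)])
        assert res.statistic == 0.0

    def test_cognitive_screening_group_summaries(self):
        # overall cognitive screening score: three groups, printed summaries
        res = ms.anova_from_summary([GroupSummary(23.40, 4.15, 30),
                                     GroupSummary(26.73, 2.56, 60),
                                     GroupSummary(27.97, 1.85, 60)])
        assert res.df == (2, 147)
        assert res.statistic == pytest.approx(28.41, abs=0.005)
        # memory index score
        res2 = ms.anova_from_summary([GroupSummary(9.00, 4.19, 30),
                                      GroupSummary(12.67, 3.06, 60),
                                      GroupSummary(13.28, 2.74, 60)])
        assert res2.statistic == pytest.approx(19.07, abs=0.005)


class TestPairwiseT:
    def test_identical_samples(self):
        a = np.array([1.0, 2.0, 3.0])
        res = ms.pairwise_t(a, a.copy())
        assert res.statistic == pytest.approx(0.0)
        assert res.p_raw == pytest.approx(1.0)

    def test_hand_computed_pair(self):
        # a = (1, 2, 3), b = (2, 4, 6): pooled sd = sqrt((2 + 8)/4) = sqrt(2.5)
        # t = (2 - 4)/(sqrt(2.5) * sqrt(2/3)) = -1.549...
        a, b = np.array([1.0, 2, 3]), np.array([2.0, 4, 6])
        res = ms.pairwise_t(a, b)
        expected = -2.0 / (np.sqrt(2.5) * np.sqrt(2 / 3))
        assert res.statistic == pytest.approx(expected, rel=1e-12)
        assert res.df == 4

    def test_antisymmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 9)
        assert ms.pairwise_t(a, b).statistic == pytest.approx(
            -ms.pairwise_t(b, a).statistic)

    def test_welch_variant_differs_under_heteroscedasticity(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 10), rng.normal(0, 5, 30)
        pooled = ms.pairwise_t(a, b, "pooled")
        welch = ms.pairwise_t(a, b, "welch")
        assert pooled.df != welch.df


class TestCohensD:
    def test_identical_groups(self):
        g = np.array([1.0, 2, 3, 4])
        assert ms.cohens_d(g, g.copy()) == 0.0

    def test_unit_difference_unit_sd(self):
        rng = np.random.default_rng(4)
        base = rng.normal(0, 1, 5000)
        base = (base - base.mean()) / base.std(ddof=1)
        assert ms.cohens_d(base, base + 1.0) == pytest.approx(-1.0, abs=1e-9)

    def test_sign_flips_on_swap(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 12)
        assert ms.cohens_d(a, b) == pytest.approx(-ms.cohens_d(b, a))


def bh_stepup_oracle(p, alpha=0.05):
    """Independent step-up implementation for cross-checking."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        val = p[i] * m / (rank_idx + 1)
        prev = min(prev, val)
        adj[i] = prev
    return adj, adj <= alpha


class TestFdrBh:
    def test_worked_stepup_case(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        adj, reject = ms.fdr_bh(p)
        assert reject.all()
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        adj, _ = ms.fdr_bh(np.array([0.03]))
        assert adj[0] == pytest.approx(0.03)

    def test_all_ones_none_rejected(self):
        adj, reject = ms.fdr_bh(np.ones(5))
        assert not reject.any()

    def test_matches_independent_oracle_on_random_vectors(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            p = rng.uniform(0, 1, rng.integers(2, 15))
            adj, reject = ms.fdr_bh(p)
            adj_o, reject_o = bh_stepup_oracle(p)
            np.testing.assert_allclose(adj, adj_o, atol=1e-12)
            np.testing.assert_array_equal(reject, reject_o)

    def test_null_simulation_controls_fdr(self):
        rng = np.random.default_rng(7)
        false_rates = []
        for _ in range(300):
            p = rng.uniform(0, 1, 10)  # all nulls
            _, reject = ms.fdr_bh(p, alpha=0.05)
            false_rates.append(reject.any())
        assert np.mean(false_rates) < 0.05 + 0.03


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p = ms.pearson_corr(x, 2 * x)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_orthogonalized_is_zero(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 50)
        y = rng.normal(0, 1, 50)
        y = y - (y @ (x - x.mean())) / ((x - x.mean()) @ (x - x.mean())) * (x - x.mean())
        r, _ = ms.pearson_corr(x, y)
        assert r == pytest.approx(0.0, abs=1e-10)

    def test_planted_correlation_recovered(self):
        rng = np.random.default_rng(9)
        estimates = []
        for _ in range(20):
            x = rng.standard_normal(100)
            y = 0.3 * x + np.sqrt(1 - 0.09) * rng.standard_normal(100)
            estimates.append(ms.pearson_corr(x, y)[0])
        assert abs(np.mean(estimates) - 0.3) < 0.05
        assert all(abs(e - 0.3) < 0.3 for e in estimates)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ms.pearson_corr(np.ones(5), np.arange(5.0))


class TestArsq:
    def _items(self, fill):
        return pd.DataFrame(np.full((3, 30), fill),
                            index=["s1", "s2", "s3"],
                            columns=[f"item{i + 1:02d}" for i in range(30)])

    def test_all_ones_gives_domain_minimum(self):
        scores = ms.arsq_domains(self._items(1))
        assert (scores == 3).all().all()
        assert list(scores.columns) == ARSQ_DOMAINS

    def test_all_fives_gives_domain_maximum(self):
        assert (ms.arsq_domains(self._items(5)) == 15).all().all()

    def test_out_of_range_item_names_subject(self):
        items = self._items(3)
        items.iloc[1, 4] = 6
        with pytest.raises(ValueError, match="s2"):
            ms.arsq_domains(items)


@pytest.fixture(scope="module")
def metrics():
    rng = np.random.default_rng(10)
    rows = []
    for group in ["g1", "g2", "g3"]:
        for s in range(12):
            for state in "ABCD":
                shift = -10.0 if (group == "g1" and state == "C") else 0.0
                rows.append(dict(
                    subject_id=f"{group}-{s}", group=group, state=state,
                    gev_pct=rng.normal(25, 5),
                    duration_ms=rng.normal(70 + shift, 5),
                    coverage_pct=rng.normal(25, 5),
                    occurrence_per_s=rng.normal(3.5, 0.4)))
    return pd.DataFrame(rows)


class TestGroupComparisonReport:
    def test_planted_difference_detected_with_fdr(self, metrics):
        report = ms.group_comparison_report(metrics)
        rows = report[(report.parameter == "duration_ms")
                      & (report.state == "C") & (report.test == "t")]
        sig = rows[(rows.group_a == "g1") | (rows.group_b == "g1")]
        assert (sig.p_fdr < 0.05).all()
        assert (sig[sig.group_a == "g1"].statistic < 0).all()

    def test_structure_one_anova_three_pairs_per_panel(self, metrics):
        report = ms.group_comparison_report(metrics)
        panel = report[(report.parameter == "gev_pct") & (report.state == "A")]
        assert (panel.test == "anova").sum() == 1
        assert (panel.test == "t").sum() == 3
        assert panel[panel.test == "t"]["cohens_d"].notna().all()

    def test_adjusted_p_not_below_raw(self, metrics):
        report = ms.group_comparison_report(metrics)
        t_rows = report[report.test == "t"]
        assert (t_rows.p_fdr >= t_rows.p_raw - 1e-12).all()

    def test_deterministic(self, metrics):
        a = ms.group_comparison_report(metrics)
        b = ms.group_comparison_report(metrics)
        pd.testing.assert_frame_equal(a, b)
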