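"""ANOVA layer, normality screen, and contingency tests against oracles."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tidecycle.stats import (
    fisher_exact_2xk,
    g_test_2xk,
    kruskal_wallis,
    normality_screen,
    one_way_pooled_anova,
    pearson_chi2_2xk,
    rhythmicity_contingency,
    two_way_anova,
)


def brute_force_chi2(table):
    """Oracle: Σ (O−E)²/E from the marginals."""
    table = np.asarray(table, dtype=float)
    E = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    return float(((table - E) ** 2 / E).sum())


# ------------------------------------------------------------- contingency

class TestContingency:
    @pytest.mark.parametrize("seed", range(6))
    def test_pearson_chi2_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(1, 80, size=(2, rng.integers(2, 5)))
        stat, df, _ = pearson_chi2_2xk(table)
        assert stat == pytest.approx(brute_force_chi2(table), rel=1e-12)
        assert df == table.shape[1] - 1

    def test_g_statistic_close_to_pearson_when_expected_large(self, rng):
        table = rng.integers(20, 120, size=(2, 3))
        chi2, _, _ = pearson_chi2_2xk(table)
        g, _, _ = g_test_2xk(table)
        assert abs(g - chi2) <= 0.15 * chi2

    def test_identical_proportions_give_zero(self):
        stat, _, p = pearson_chi2_2xk(np.array([[10, 20, 40], [5, 10, 20]]))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("table", [
        [[8, 2], [1, 5]],
        [[10, 10], [10, 10]],
        [[3, 15], [12, 4]],
        [[40, 12], [22, 31]],
    ])
    def test_fisher_exact_matches_scipy_on_2x2(self, table):
        ours = fisher_exact_2xk(np.array(table))
        theirs = sps.fisher_exact(np.array(table)).pvalue
        assert ours == pytest.approx(theirs, rel=1e-9)

    def test_rhythmicity_contingency_reports_all_three_statistics(self):
        counts = {"control": (63, 7), "bmal1i": (66, 35), "cry2i": (59, 10)}
        res = rhythmicity_contingency(counts)
        assert set(res.all_stats) == {"pearson_chi2", "g_test", "fisher_exact"}
        assert res.df == 2
        assert res.statistic == pytest.approx(brute_force_chi2(res.table), rel=1e-12)
        assert 0 < res.all_stats["fisher_exact"]["p"] < 0.01

    def test_zero_total_group_dropped_with_warning(self):
        with pytest.warns(UserWarning):
            res = rhythmicity_contingency(
                {"a": (10, 5), "b": (8, 9), "empty": (0, 0)})
        assert res.table.shape == (2, 2) and res.dropped_groups == ["empty"]


# ------------------------------------------------------------------ ANOVA

def simulated_cohort_df(rng, shift=0.0, n=30, sd=0.2):
    rows = []
    for coll in ("early", "mid"):
        for kd, mu in (("control", 1.0), ("kd", 1.0 + shift)):
            for v in rng.normal(mu, sd, size=n):
                rows.append(dict(collection=coll, knockdown=kd, MI=v))
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_null_data_give_large_p(self, rng):
        df = simulated_cohort_df(rng, shift=0.0)
        res = two_way_anova(df, "MI", control_level="control")
        assert res.p("knockdown") > 0.001
        assert 0 <= res.eta_sq("knockdown") <= 1
        total_eta = res.table["eta_sq"].sum()
        assert total_eta == pytest.approx(1.0, abs=0.05)

    def test_knockdown_shift_detected_in_most_replicates(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            df = simulated_cohort_df(rng, shift=-0.3)
            res = two_way_anova(df, "MI", control_level="control")
            hits += res.p("knockdown") < 0.01
        assert hits >= 90

    def test_empty_cell_degrades_to_main_effects(self, rng):
        df = simulated_cohort_df(rng)
        df = df[~((df.collection == "mid") & (df.knockdown == "kd"))]
        with pytest.warns(UserWarning):
            res = two_way_anova(df, "MI", control_level="control")
        assert res.degraded_to_main_effects
        assert "collection:knockdown" not in set(res.table.term)

    def test_dunnett_and_tukey_posthocs_present_and_ordered(self, rng):
        df = simulated_cohort_df(rng, shift=-0.4)
        res = two_way_anova(df, "MI", control_level="control")
        methods = {p["method"] for p in res.posthoc}
        assert methods == {"dunnett", "tukey"}
        # adjusted Dunnett p is never below the raw two-sample t-test p
        raw = sps.ttest_ind(df.loc[df.knockdown == "kd", "MI"],
                            df.loc[df.knockdown == "control", "MI"]).pvalue
        dunnett_p = [p["p_adj"] for p in res.posthoc if p["method"] == "dunnett"][0]
        assert dunnett_p >= raw - 1e-12


class TestOneWayAnova:
    def test_balanced_two_group_f_equals_t_squared(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(0.5, 1, 40)
        df = pd.DataFrame(dict(knockdown=["a"] * 40 + ["b"] * 40,
                               y=np.concatenate([a, b])))
        res = one_way_pooled_anova(df, "y", control_level="a")
        t = sps.ttest_ind(a, b).statistic
        F = float(res.table.loc[res.table.term == "knockdown", "F"].iloc[0])
        assert F == pytest.approx(t ** 2, rel=1e-9)

    def test_separated_groups_significant(self, rng):
        df = pd.DataFrame(dict(
            knockdown=["a"] * 50 + ["b"] * 50 + ["c"] * 50,
            y=np.concatenate([rng.normal(0, 1, 50), rng.normal(0, 1, 50),
                              rng.normal(1, 1, 50)])))
        res = one_way_pooled_anova(df, "y", control_level="a")
        assert res.p("knockdown") < 0.01

    def test_constant_groups_flagged_degenerate(self):
        df = pd.DataFrame(dict(knockdown=list("aabbcc"), y=[1.0] * 6))
        res = one_way_pooled_anova(df, "y")
        assert res.degenerate

    def test_kruskal_companion_appears_for_non_normal_response(self, rng):
        y = np.concatenate([rng.exponential(1, 60), rng.exponential(1, 60),
                            rng.exponential(3, 60)])
        df = pd.DataFrame(dict(knockdown=["a"] * 60 + ["b"] * 60 + ["c"] * 60, y=y))
        res = one_way_pooled_anova(df, "y", control_level="a")
        assert res.normality is not None and not res.normality["passed"]
        assert res.kruskal is not None and res.kruskal["p"] < 0.01


def test_kruskal_wallis_matches_hand_computed_toy():
    """Groups {1,2,3}, {4,5,6}, {7,8,9}: H = 12/(9·10)·(27+0+27)·3/3 = 7.2."""
    groups = [np.array([1.0, 2, 3]), np.array([4.0, 5, 6]), np.array([7.0, 8, 9])]
    res = kruskal_wallis(groups)
    assert res["H"] == pytest.approx(7.2, rel=1e-12)
    assert res["df"] == 2


class TestNormalityScreen:
    def test_normal_samples_pass_nearly_always(self):
        passes = sum(
            normality_screen(np.random.default_rng(s).normal(size=100))["passed"]
            for s in range(60)
        )
        assert passes >= 57  # ≥95%

    def test_exponential_samples_fail_nearly_always(self):
        fails = sum(
            not normality_screen(np.random.default_rng(s).exponential(size=200))["passed"]
            for s in range(60)
        )
        assert fails >= 54  # ≥90%

    def test_constant_and_tiny_vectors_fail_conservatively(self):
        const = normality_screen(np.full(50, 3.3))
        assert not const["passed"] and const["reason"] == "constant vector"
        tiny = normality_screen(np.arange(5.0))
        assert not tiny["passed"] and tiny["reason"] == "n < 8"
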