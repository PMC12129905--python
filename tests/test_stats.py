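"""Normality-gated statistics: routing, omnibus, post hoc, rank two-way."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from rgcquant.stats import (
    StatRoute,
    TestResult,
    games_howell,
    normality_gate,
    omnibus_test,
    pairwise_posthoc,
    scheirer_ray_hare,
    two_factor_rank_anova,
    welch_anova,
)


def nonparam_route(k=2):
    return StatRoute(route="nonparametric", per_group_normality_p=(0.01,) * k)


def param_route(k=2):
    return StatRoute(route="parametric", per_group_normality_p=(0.5,) * k)


class TestNormalityGate:
    def test_all_normal_groups_route_parametric(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(size=20) for _ in range(3)]
        route = normality_gate(groups)
        assert route.route == "parametric"
        assert all(p >= 0.05 for p in route.per_group_normality_p)

    def test_one_failing_group_routes_nonparametric(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(size=30), np.repeat([0.0, 100.0], 15)]
        assert normality_gate(groups).route == "nonparametric"

    def test_small_group_is_insufficient_data(self):
        with pytest.raises(ValueError):
            normality_gate([[1.0, 2.0], [1.0, 2.0, 3.0]])

    def test_heavy_tailed_data_mostly_routes_nonparametric(self):
        rng = np.random.default_rng(2)
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            groups = [rng.standard_cauchy(50) for _ in range(2)]
            if normality_gate(groups).route == "nonparametric":
                hits += 1
        assert hits / n_sim > 0.8

    def test_route_invariant_enforced(self):
        with pytest.raises(ValueError):
            StatRoute(route="parametric", per_group_normality_p=(0.01, 0.5))


class TestOmnibus:
    def test_kruskal_wallis_hand_computed(self):
        res = omnibus_test([[1, 2, 3], [4, 5, 6]], nonparam_route())
        assert res.test_name == "kruskal_wallis"
        assert res.statistic == pytest.approx(27 / 7, rel=1e-9)  # 3.857142...

    def test_identical_groups_no_separation(self):
        res = omnibus_test([[2.0, 2.0, 2.0], [2.0, 2.0, 2.0]], nonparam_route())
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_welch_f_equals_squared_welch_t_on_two_groups(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 12), rng.normal(0.7, 2.5, 7)
        f = omnibus_test([a, b], param_route())
        t = sps.ttest_ind(a, b, equal_var=False)
        assert f.statistic == pytest.approx(t.statistic**2, rel=1e-9)
        assert f.p_value == pytest.approx(t.pvalue, rel=1e-9)

    def test_empty_group_is_domain_error(self):
        with pytest.raises(ValueError):
            omnibus_test([[1.0, 2.0], []], nonparam_route())

    def test_kruskal_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(0, 1, 8), rng.normal(1, 1, 9), rng.normal(2, 1, 7)]
        h1 = omnibus_test(groups, nonparam_route(3)).statistic
        h2 = omnibus_test([np.exp(g) for g in groups], nonparam_route(3)).statistic
        assert h1 == pytest.approx(h2, rel=1e-12)


def exact_mannwhitney_p(a, b):
    """Brute-force two-sided Mann-Whitney p by enumerating all splits."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        us.append(ranks[list(comb)].sum() - n1 * (n1 + 1) / 2)
    us = np.asarray(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(1.0, p)


class TestPairwise:
    def test_mann_whitney_matches_exact_enumeration(self):
        rng = np.random.default_rng(5)
        for n1, n2 in [(3, 3), (4, 5), (6, 6), (5, 3)]:
            for _ in range(5):
                a, b = rng.normal(0, 1, n1), rng.normal(0.8, 1, n2)
                res = pairwise_posthoc([a, b], nonparam_route())[0]
                assert res.p_value == pytest.approx(exact_mannwhitney_p(a, b), abs=0.02)

    def test_complete_separation_gives_u_zero(self):
        res = pairwise_posthoc([[1, 2, 3], [4, 5, 6]], nonparam_route())[0]
        # U for the first group against the second is 0 under complete separation
        assert min(res.statistic, 9 - res.statistic) == 0.0

    def test_three_groups_give_three_pairs_bonferroni(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(i, 1, 6) for i in range(3)]
        res = pairwise_posthoc(groups, nonparam_route(3))
        assert len(res) == 3
        assert all(r.adjustment == "bonferroni" for r in res)

    def test_bonferroni_multiplies_and_caps(self):
        rng = np.random.default_rng(7)
        groups = [rng.normal(i * 0.3, 1, 6) for i in range(3)]
        raw = [
            sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")[1]
            for a, b in itertools.combinations(groups, 2)
        ]
        res = pairwise_posthoc(groups, nonparam_route(3))
        for r, p in zip(res, raw):
            assert r.p_value == pytest.approx(min(1.0, 3 * p), rel=1e-9)

    def test_parametric_route_uses_games_howell(self):
        rng = np.random.default_rng(8)
        groups = [rng.normal(i, 1 + i, 9) for i in range(3)]
        res = pairwise_posthoc(groups, param_route(3))
        assert all(r.test_name == "games_howell" for r in res)


class TestGamesHowell:
    # Standard studentized-range critical values q(k, df, alpha=0.05); the
    # reference distribution must match published tables to 2 decimals.
    @pytest.mark.parametrize(
        "k,df,q_crit",
        [(2, 10, 3.15), (3, 10, 3.88), (2, 1e6, 2.77), (3, 1e6, 3.31), (4, 1e6, 3.63)],
    )
    def test_studentized_range_matches_tables(self, k, df, q_crit):
        assert sps.studentized_range.ppf(0.95, k, df) == pytest.approx(q_crit, abs=0.005)

    def test_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(9)
        groups = [rng.normal(i * 0.8, 1 + i, 10) for i in range(3)]
        ours = games_howell(groups, labels=["a", "b", "c"])
        df = pd.DataFrame(
            {
                "y": np.concatenate(groups),
                "g": np.repeat(["a", "b", "c"], [len(g) for g in groups]),
            }
        )
        ref = pg.pairwise_gameshowell(dv="y", between="g", data=df)
        for r in ours:
            row = ref[(ref["A"] == r.group_pair[0]) & (ref["B"] == r.group_pair[1])]
            assert r.p_value == pytest.approx(float(row["pval"].iloc[0]), abs=1e-6)


def test_welch_anova_agrees_with_pingouin():
    pg = pytest.importorskip("pingouin")
    import pandas as pd

    rng = np.random.default_rng(10)
    groups = [rng.normal(i * 0.5, 1 + 0.5 * i, 8 + i) for i in range(3)]
    ours = welch_anova(groups)
    df = pd.DataFrame(
        {
            "y": np.concatenate(groups),
            "g": np.repeat(list("abc"), [len(g) for g in groups]),
        }
    )
    ref = pg.welch_anova(dv="y", between="g", data=df)
    assert ours.statistic == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
    assert ours.p_value == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-6)
    assert ours.df[1] == pytest.approx(float(ref["ddof2"].iloc[0]), rel=1e-9)


class TestScheirerRayHare:
    def test_constant_data_gives_unit_p(self):
        y = np.ones(16)
        a = np.repeat(["y", "o"], 8)
        b = np.tile(np.repeat([0, 14], 4), 2)
        for res in scheirer_ray_hare(y, a, b):
            assert res.statistic == 0.0
            assert res.p_value == 1.0

    def test_additive_shift_power_and_interaction_size(self):
        """Age main effect detected; interaction stays at nominal size."""
        rng = np.random.default_rng(11)
        n_sim, n_cell = 400, 10
        age_rej = inter_rej = 0
        for _ in range(n_sim):
            cells = {
                ("y", 0): rng.normal(0, 1, n_cell),
                ("y", 14): rng.normal(0, 1, n_cell),
                ("o", 0): rng.normal(1.2, 1, n_cell),
                ("o", 14): rng.normal(1.2, 1, n_cell),
            }
            y = np.concatenate(list(cells.values()))
            a = np.repeat([k[0] for k in cells], n_cell)
            b = np.repeat([k[1] for k in cells], n_cell)
            res = {r.test_name: r for r in scheirer_ray_hare(y, a, b)}
            age_rej += res["srh_factor_a"].p_value < 0.05
            inter_rej += res["srh_interaction"].p_value < 0.05
        assert age_rej / n_sim > 0.9
        assert 0.01 < inter_rej / n_sim < 0.10

    def test_single_level_factor_is_design_error(self):
        with pytest.raises(ValueError):
            scheirer_ray_hare(np.arange(6.0), ["a"] * 6, [0, 0, 0, 1, 1, 1])

    def test_missing_cell_is_design_error(self):
        y = np.arange(6.0)
        a = ["y", "y", "y", "o", "o", "o"]
        b = [0, 0, 0, 0, 0, 14]  # (y, 14) cell empty
        with pytest.raises(ValueError):
            scheirer_ray_hare(y, a, b)

    def test_table_interface(self):
        import pandas as pd

        rng = np.random.default_rng(12)
        rows = []
        for age in ("6w", "18w"):
            for dpi in (4, 14):
                for v in rng.normal(70, 5, 6):
                    rows.append({"age_label": age, "dpi": dpi, "survival_pct": v})
        res = two_factor_rank_anova(pd.DataFrame(rows))
        assert [r.test_name for r in res] == [
            "srh_factor_a", "srh_factor_b", "srh_interaction",
        ]


class TestTypeIError:
    def test_both_routes_hold_nominal_size(self):
        """Null rejections stay at 5% +- 1.5% over 2000 simulations."""
        rng = np.random.default_rng(13)
        n_sim = 2000
        rej_np = rej_p = 0
        for _ in range(n_sim):
            groups = [rng.normal(0, 1, 10) for _ in range(3)]
            if sps.kruskal(*groups).pvalue < 0.05:
                rej_np += 1
            if welch_anova(groups).p_value < 0.05:
                rej_p += 1
        assert rej_np / n_sim == pytest.approx(0.05, abs=0.015)
        assert rej_p / n_sim == pytest.approx(0.05, abs=0.015)


def test_result_validation():
    with pytest.raises(ValueError):
        TestResult(test_name="x", statistic=0.0, p_value=1.5)
    with pytest.raises(ValueError):
        TestResult(test_name="x", statistic=0.0, p_value=0.5, adjustment="fdr")
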