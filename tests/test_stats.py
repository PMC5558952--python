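"""Trend, change-point, rank and pooled-t inference, and pattern rules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from dendrocarbon.stats import (
    ClassifierConfig,
    classify_pattern,
    compare_species,
    cox_stuart,
    dunn_test,
    holm_adjust,
    pearson_correlation,
    pettitt,
)

from oracles import dunn_z_brute, pettitt_brute


class TestCoxStuart:
    def test_monotone_series_minimal_p(self):
        res = cox_stuart(np.arange(20.0), alternative="increasing")
        assert res.n_pairs_used == 10
        assert res.s_plus == 10
        assert res.p_value == pytest.approx(0.5**10, rel=1e-12)
        assert res.direction == "increasing"

    def test_odd_length_drops_middle(self):
        res = cox_stuart(np.arange(21.0))
        assert res.n_pairs_used == 10

    def test_constant_series_degenerate(self):
        res = cox_stuart(np.full(30, 2.0))
        assert res.degenerate
        assert res.p_value == 1.0
        assert res.direction == "none"

    def test_two_sided_doubles_tail(self):
        x = np.arange(20.0)
        two = cox_stuart(x, alternative="two_sided")
        one = cox_stuart(x, alternative="increasing")
        assert two.p_value == pytest.approx(2 * one.p_value)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            cox_stuart([1.0, 2.0, 3.0])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=40)
        a = cox_stuart(x)
        b = cox_stuart(np.exp(x))  # strictly increasing transform
        assert a.s_plus == b.s_plus
        assert a.p_value == b.p_value


class TestPettitt:
    def test_constant_series(self):
        res = pettitt(np.full(20, 1.0))
        assert res.k == 0
        assert res.p_approx == 1.0

    def test_step_series_hand_case(self):
        x = np.concatenate([np.zeros(50), np.full(50, 10.0)])
        res = pettitt(x)
        assert res.k == 2500
        assert res.tau == 50

    def test_brute_force_equivalence(self, rng):
        for _ in range(60):
            n = int(rng.integers(8, 31))
            x = rng.normal(size=n)
            if rng.random() < 0.3:  # exercise ties
                x = np.round(x, 0)
            res = pettitt(x)
            k, tau = pettitt_brute(x)
            assert res.k == k
            assert res.tau == tau

    def test_significance_formula(self):
        x = np.concatenate([np.zeros(10), np.full(10, 5.0)])
        res = pettitt(x)
        t = 20
        assert res.p_approx == pytest.approx(
            2 * math.exp(-6 * res.k**2 / (t**3 + t**2))
        )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=30)
        a = pettitt(x)
        b = pettitt(x**3)  # strictly increasing transform
        assert a.k == b.k and a.tau == b.tau


class TestDunn:
    def test_identical_groups(self):
        res = dunn_test({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert res[0].z == pytest.approx(0.0)
        assert res[0].p_raw == pytest.approx(1.0)

    def test_hand_computed_case(self):
        # ranks 1,2,3 vs 4,5,6: z = (2-5)/sqrt((6*7/12)(1/3+1/3)) = -3/sqrt(7/3)
        (res,) = dunn_test({"a": [1, 2, 3], "b": [10, 11, 12]})
        assert res.z == pytest.approx(-3 / math.sqrt(7 / 3), rel=1e-12)
        assert res.z == pytest.approx(-1.9640, abs=5e-5)

    def test_tie_corrected_z_matches_brute_force(self, rng):
        for _ in range(100):
            sizes = rng.integers(3, 8, size=int(rng.integers(2, 5)))
            groups = [list(rng.integers(0, 6, s).astype(float)) for s in sizes]
            if len(set(v for g in groups for v in g)) < 2:
                continue
            named = {f"g{i}": g for i, g in enumerate(groups)}
            results = dunn_test(named)
            for pc in results:
                ia = int(pc.group_a[1:])
                ib = int(pc.group_b[1:])
                z = dunn_z_brute(groups[ia], groups[ib], groups)
                assert pc.z == pytest.approx(z, rel=1e-12, abs=1e-12)

    def test_holm_adjustment_applied(self, rng):
        groups = {f"g{i}": rng.normal(i, 1, 10) for i in range(4)}
        res_none = dunn_test(groups, adjustment="none")
        res_holm = dunn_test(groups, adjustment="holm")
        for a, b in zip(res_none, res_holm):
            assert b.p_adjusted >= a.p_raw

    def test_degenerate_ranking_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            dunn_test({"a": [1, 1], "b": [1, 1]})


class TestHolm:
    def test_never_below_raw_and_monotone(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 1, int(rng.integers(1, 12)))
            adj = holm_adjust(p)
            assert np.all(adj >= p - 1e-15)
            order = np.argsort(p)
            assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 9)
        _, expected, _, _ = multipletests(p, method="holm")
        np.testing.assert_allclose(holm_adjust(p), expected, rtol=1e-12)

    def test_single_comparison_unchanged(self):
        np.testing.assert_allclose(holm_adjust([0.03]), [0.03])


class TestPearson:
    def test_perfect_lines(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson_correlation(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_scipy(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 60))
            x, y = rng.normal(size=n), rng.normal(size=n)
            r, r2, p = pearson_correlation(x, y)
            ref = sps.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-8)
            assert r2 == pytest.approx(r * r)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 1, 1], [1, 2, 3])


class TestCompareSpecies:
    def test_identical_groups_null(self):
        g = {"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4], "c": [1.0, 2, 3, 4]}
        res = compare_species(g)
        assert res.f_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_two_groups_holm_equals_raw(self, rng):
        g = {"a": rng.normal(0, 1, 10), "b": rng.normal(1, 1, 10)}
        res = compare_species(g)
        (pc,) = res.pairwise
        assert pc.p_adjusted == pytest.approx(pc.p_raw)

    def test_anova_matches_scipy(self, rng):
        groups = {f"g{i}": rng.normal(i * 0.5, 1, 12) for i in range(3)}
        res = compare_species(groups)
        ref = sps.f_oneway(*groups.values())
        assert res.f_statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-8)

    def test_power_on_separated_group(self, rng):
        # means 0/0/5, sd 1, n=20: only comparisons against the third
        # group should reject at alpha=0.05 in nearly all replicates
        hits, false = 0, 0
        reps = 200
        for _ in range(reps):
            g = {
                "a": rng.normal(0, 1, 20),
                "b": rng.normal(0, 1, 20),
                "c": rng.normal(5, 1, 20),
            }
            res = compare_species(g)
            for pc in res.pairwise:
                sig = pc.p_adjusted <= 0.05
                if "c" in (pc.group_a, pc.group_b):
                    hits += sig
                else:
                    false += sig
        assert hits / (2 * reps) >= 0.95
        assert false / reps <= 0.10

    def test_small_group_excluded(self, rng):
        g = {"a": rng.normal(size=5), "b": rng.normal(size=5), "c": [1.0]}
        res = compare_species(g)
        assert res.excluded == ["c"]


class TestClassifier:
    def _carbon(self, archetype, age=150, **overrides):
        from dendrocarbon.carbon import carbon_trajectory
        from dendrocarbon.ringio import RingSeries
        from dendrocarbon.series import reconstruct_diameter
        from dendrocarbon.synthetic import default_archetype_params, mean_structure

        w = mean_structure(
            default_archetype_params(archetype, **overrides), age, rho=0.72
        )
        s = RingSeries(tree_id="T", radius_id="m", widths=w, last_year=age)
        return carbon_trajectory(reconstruct_diameter(s), 0.72, 0.0).annual_c_kg

    @pytest.mark.parametrize(
        "archetype",
        ["sustained_increase", "increase_with_depression", "plateau",
         "rise_then_decline"],
    )
    @pytest.mark.parametrize("age", [84, 150, 255])
    def test_noiseless_archetypes_recovered(self, archetype, age):
        label = classify_pattern(self._carbon(archetype, age=age))
        assert label.label == archetype

    def test_depression_evidence_reported(self):
        label = classify_pattern(self._carbon("increase_with_depression"))
        start, length, rel = label.depression
        assert length >= 15
        assert rel < 0.8

    def test_scale_invariance(self):
        x = self._carbon("increase_with_depression")
        a = classify_pattern(x)
        b = classify_pattern(x * 1234.5)
        assert a.label == b.label
        assert a.trend_p == b.trend_p

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="40"):
            classify_pattern(np.arange(30.0))
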