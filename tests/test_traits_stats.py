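"""Trait classification and the statistical battery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from fireflora import traits_stats as ts


class TestFireResponse:
    @pytest.mark.parametrize("r,p,rtype,persister", [
        ("Rplus", "Pplus", ts.FACULTATIVE, True),
        ("Rplus", "Pminus", ts.OBLIGATE_RESPROUTER, True),
        ("Rminus", "Pplus", ts.OBLIGATE_SEEDER, True),
        ("Rminus", "Pminus", ts.NON_PERSISTER, False),
        ("unknown", "Pplus", ts.UNKNOWN, True),
        ("Rplus", "unknown", ts.UNKNOWN, True),
        ("Rminus", "unknown", ts.UNKNOWN, None),  # negative alone settles nothing
        ("unknown", "unknown", ts.UNKNOWN, None),
    ])
    def test_classification(self, r, p, rtype, persister):
        fr = ts.classify_fire_response(r, p)
        assert fr.response_type == rtype and fr.persister == persister


class TestFrameworkType:
    @pytest.mark.parametrize("re_t,persister,history,expected", [
        (50, True, "frequent", "A"),
        (600, True, "frequent", "D"),
        (50, True, "infrequent", "B"),
        (600, True, "infrequent", "B"),
        (50, False, "frequent", "C"),
        (600, False, "infrequent", "E"),
        (300, True, "frequent", None),   # intermediate range, unresolved
        (300, False, "frequent", None),
    ])
    def test_placement(self, re_t, persister, history, expected):
        assert ts.classify_framework_type(re_t, persister, history) == expected

    def test_bad_history_rejected(self):
        with pytest.raises(ValueError):
            ts.classify_framework_type(50, True, "sometimes")


class TestGroupDifferences:
    def test_hand_computed_kw(self):
        """Three groups of tied-free ranks 1..9 give H = 7.2 exactly."""
        res = ts.test_group_differences([1, 2, 3, 4, 5, 6, 7, 8, 9],
                                        ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert res[0].statistic == pytest.approx(7.2)
        assert res[0].df == 2

    def test_identical_values_give_zero(self):
        res = ts.test_group_differences([5.0] * 6, ["a"] * 3 + ["b"] * 3)
        assert res[0].statistic == 0.0 and res[0].p_value == 1.0

    def test_pairwise_bh_adjustment(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(0, 1, 15), rng.normal(2, 1, 15),
                               rng.normal(4, 1, 15)])
        groups = ["a"] * 15 + ["b"] * 15 + ["c"] * 15
        res = ts.test_group_differences(vals, groups, pairwise=True)
        assert len(res) == 1 + 3
        for r in res[1:]:
            assert r.adjustment == "BH"
            assert r.p_value >= r.extras["p_raw"]

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            ts.test_group_differences([1, 2, 3], ["a"] * 3)

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(deadline=None, max_examples=15, derandomize=True)
    def test_kw_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=24)
        groups = rng.choice(["a", "b", "c"], size=24)
        if min((groups == g).sum() for g in "abc") < 1:
            return
        h1 = ts.test_group_differences(vals, groups)[0].statistic
        h2 = ts.test_group_differences(np.exp(vals), groups)[0].statistic
        assert h1 == pytest.approx(h2)


class TestBenjaminiHochberg:
    def test_textbook_example(self):
        assert ts.benjamini_hochberg([0.01, 0.02, 0.03]).tolist() == \
            pytest.approx([0.03, 0.03, 0.03])

    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1,
                    max_size=20))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_never_below_raw_and_monotone(self, pvals):
        raw = np.asarray(pvals)
        adj = ts.benjamini_hochberg(raw)
        assert np.all(adj >= raw - 1e-12)
        assert np.all(adj <= 1.0)
        order = np.argsort(raw)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestQuantileRegression:
    def test_exact_linear_recovery(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 100, 60)
        y = 2.5 * x + 1.0
        out = ts.quantile_pf_range(x, y, taus=[0.1, 0.5, 0.9])
        assert np.allclose(out["slope"], 2.5, atol=1e-8)
        assert np.allclose(out["intercept"], 1.0, atol=1e-6)

    def test_constant_response_gives_zero_slope(self):
        x = np.linspace(0, 10, 30)
        out = ts.quantile_pf_range(x, np.full(30, 3.0), taus=[0.5])
        assert out["slope"].iloc[0] == pytest.approx(0.0, abs=1e-10)
        assert not out["significant"].iloc[0]

    def test_triangular_cloud_upper_envelope(self):
        """Decreasing upper envelope: negative significant slope at tau=0.9,
        matching the inverse range-size / burn-fraction relationship."""
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 100, 400)
        y = rng.uniform(0, 1, 400) * (1 - x / 100.0)
        out = ts.quantile_pf_range(x, y, taus=[0.9])
        row = out.iloc[0]
        assert row.slope < 0
        assert row.ci_high < 0 and row.significant

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ts.quantile_pf_range(np.ones(30), np.random.default_rng(0).random(30))
        with pytest.raises(ValueError):
            ts.quantile_pf_range(np.arange(10), np.arange(10))

    def test_check_loss_local_optimality(self):
        """The fitted coefficients minimise the tilted absolute loss locally."""
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 10, 50)
        y = 0.5 * x + rng.normal(0, 1, 50)
        tau = 0.7
        out = ts.quantile_pf_range(x, y, taus=[tau])
        a, b = out["intercept"].iloc[0], out["slope"].iloc[0]

        def loss(a_, b_):
            r = y - a_ - b_ * x
            return np.sum(np.where(r >= 0, tau * r, (tau - 1) * r))

        base = loss(a, b)
        for da in (-0.05, 0.05):
            for db in (-0.02, 0.02):
                assert base <= loss(a + da, b + db) + 1e-9


class TestDistributionShape:
    def test_symmetric_sample(self):
        res = ts.distribution_shape([-1.0, 0.0, 1.0])
        assert res.extras["skewness"] == pytest.approx(0.0)

    def test_moment_formula(self):
        v = np.array([1.0, 2.0, 3.0, 10.0])
        m = v - v.mean()
        g1 = (m ** 3).mean() / (m ** 2).mean() ** 1.5
        assert ts.distribution_shape(v).extras["skewness"] == pytest.approx(g1)

    def test_normal_sample_high_w(self):
        v = np.random.default_rng(7).standard_normal(500)
        res = ts.distribution_shape(v)
        assert res.statistic >= 0.99

    @pytest.mark.parametrize("n", [2, 5001])
    def test_sample_size_limits(self, n):
        with pytest.raises(ValueError):
            ts.distribution_shape(np.ones(n))


class TestContingency:
    def test_exact_independence_gives_zero(self):
        t = np.outer([10, 20, 30], [1, 2, 3])
        assert ts.contingency_test(t).statistic == pytest.approx(0.0)

    def test_hand_computed_2x2(self):
        res = ts.contingency_test([[10, 20], [20, 10]])
        assert res.statistic == pytest.approx(20 / 3)
        assert res.df == 1

    def test_df_for_4x6(self):
        t = np.ones((4, 6)) * 5
        assert ts.contingency_test(t).df == 15

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            ts.contingency_test([[0, 0], [1, 2]])


class TestAnova:
    def test_identical_groups_f_zero(self):
        res = ts.anova_tukey([1.0, 2.0, 3.0] * 2, ["a"] * 3 + ["b"] * 3)
        assert res.statistic == pytest.approx(0.0)

    def test_two_group_hand_computation(self):
        """F for two groups equals the textbook between/within ratio on the
        transformed values."""
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([10.0, 12.0, 14.0, 16.0])
        res = ts.anova_tukey(np.concatenate([a, b]),
                             ["a"] * 4 + ["b"] * 4)
        ta, tb = np.log10(a + 1), np.log10(b + 1)
        grand = np.concatenate([ta, tb]).mean()
        ssb = 4 * ((ta.mean() - grand) ** 2 + (tb.mean() - grand) ** 2)
        ssw = ((ta - ta.mean()) ** 2).sum() + ((tb - tb.mean()) ** 2).sum()
        f = (ssb / 1) / (ssw / 6)
        assert res.statistic == pytest.approx(f)
        assert res.df == (1, 6)

    def test_df_shape(self):
        rng = np.random.default_rng(0)
        vals = rng.random(700)
        groups = np.repeat(["a", "b", "c", "d"], 175)
        res = ts.anova_tukey(vals, groups)
        assert res.df == (3, 696)
        assert isinstance(res.extras["tukey"], pd.DataFrame)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            ts.anova_tukey([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestSpeciesReport:
    def make_tables(self, n=120, seed=0):
        """Synthetic stand-in species/trait tables with the pipeline schema."""
        rng = np.random.default_rng(seed)
        re_t = np.exp(rng.normal(4, 1, n))
        pf_m = np.clip(rng.uniform(0.2, 1.1, n) - re_t / 4000, 0, 1)
        pf_sr = pf_m * rng.uniform(0.8, 1.0, n)
        species = pd.DataFrame({
            "taxon": [f"t{i}" for i in range(n)],
            "pf_sr": pf_sr, "pf_br": pf_m * rng.uniform(0.8, 1.0, n),
            "pf_sdm": pf_m, "pf_m": pf_m,
            "support_class": rng.integers(1, 8, n),
            "high_impact": pf_m > 0.5,
            "re_t_km": re_t, "endemism": "ENDEMIC",
        })
        traits = pd.DataFrame({
            "taxon": species.taxon,
            "life_form": rng.choice(ts.LIFE_FORMS, n),
            "rf_class": rng.choice(ts.RF_CLASSES, n, p=[0.1, 0.1, 0.1, 0.7]),
            "resprouter": rng.choice(["Rplus", "Rminus"], n, p=[0.8, 0.2]),
            "propagule_persister": rng.choice(["Pplus", "Pminus"], n,
                                              p=[0.7, 0.3]),
        })
        return species, traits

    def test_counts_match_direct_computation(self):
        species, traits = self.make_tables()
        rep = ts.species_report(species, traits, quantiles=False)
        high = species[species.high_impact]
        assert rep["n_high_impact"] == len(high)
        assert rep["n_endemic_high_impact"] == len(high)
        assert rep["n_multi_support"] == int((high.support_class >= 4).sum())

    def test_statistics_match_scipy_direct(self):
        species, traits = self.make_tables()
        rep = ts.species_report(species, traits, quantiles=False)
        high = species[species.high_impact].merge(traits, on="taxon")
        h, p = sps.kruskal(*[g["pf_m"].to_numpy()
                             for _, g in high.groupby("rf_class")])
        assert rep["kw_pf_by_rf_class"][0].statistic == pytest.approx(h)
        assert rep["range_shape"].extras["skewness"] == pytest.approx(
            sps.skew(high_re := species[species.high_impact]["re_t_km"]))

    def test_persister_share(self):
        species, traits = self.make_tables()
        rep = ts.species_report(species, traits, quantiles=False)
        high = species[species.high_impact].merge(traits, on="taxon")
        persisters = ((high.resprouter == "Rplus")
                      | (high.propagule_persister == "Pplus")).sum()
        assert rep["n_persisters"] == persisters
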