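"""Cohort statistics: QC filtering, ANOVA + Bonferroni, OLS, AROC/DeLong,
reproducibility CV, and MOPP."""

import numpy as np
import pandas as pd
import pytest

import omagflux.stats as st


def make_df(groups):
    rows = []
    for g, values in groups.items():
        for i, v in enumerate(values):
            rows.append({"id": f"{g}{i}", "group": g, "metric": v, "signal_strength": 10})
    return pd.DataFrame(rows)


class TestQcFilter:
    def test_cutoff_is_strictly_below(self):
        df = pd.DataFrame(
            {"id": ["a", "b", "c"], "signal_strength": [6, 5, 10], "metric": [1, 2, 3]}
        )
        out = st.qc_filter(df)
        assert list(out["id"]) == ["a", "c"]  # SS = 6 retained, SS = 5 removed

    def test_all_passing_is_identity(self):
        df = pd.DataFrame({"id": ["a", "b"], "signal_strength": [7, 9], "metric": [1, 2]})
        assert len(st.qc_filter(df)) == 2

    def test_record_objects_filtered(self):
        recs = [
            st.SubjectRecord(id="a", group="normal", signal_strength=6),
            st.SubjectRecord(id="b", group="glaucoma", signal_strength=3),
        ]
        kept = st.qc_filter(recs)
        assert [r.id for r in kept] == ["a"]


class TestGroupCompare:
    def test_bonferroni_alpha_three_comparisons(self):
        assert st.bonferroni_alpha(3) == pytest.approx(0.0167, abs=5e-5)

    def test_hand_computed_anova(self):
        """Groups {1,2,3},{2,3,4},{3,4,5}: SSB = 3*((2-3)^2+(3-3)^2+(4-3)^2) = 6,
        MSB = 3, SSW = 6 on 6 df, MSW = 1, so F = 3.0 on (2, 6) df."""
        df = make_df({"normal": [1, 2, 3], "suspect": [2, 3, 4], "glaucoma": [3, 4, 5]})
        res = st.group_compare(df, "metric")
        assert res["anova_F"] == pytest.approx(3.0, rel=1e-10)
        # independent oracle: explicit sums of squares
        all_vals = df["metric"].to_numpy(dtype=float)
        grand = all_vals.mean()
        ssb = sum(3 * (np.mean(v) - grand) ** 2 for v in ([1, 2, 3], [2, 3, 4], [3, 4, 5]))
        ssw = sum(((np.asarray(v) - np.mean(v)) ** 2).sum() for v in ([1, 2, 3], [2, 3, 4], [3, 4, 5]))
        assert res["anova_F"] == pytest.approx((ssb / 2) / (ssw / 6), rel=1e-10)

    def test_identical_groups_f_zero(self):
        df = make_df({"normal": [1, 2, 3], "suspect": [1, 2, 3], "glaucoma": [1, 2, 3]})
        res = st.group_compare(df, "metric")
        assert res["anova_F"] == pytest.approx(0.0, abs=1e-12)
        assert res["anova_p"] == pytest.approx(1.0)

    def test_two_group_anova_equals_t_squared(self, rng):
        df = make_df({"normal": rng.normal(0, 1, 12), "glaucoma": rng.normal(1, 1, 9)})
        res = st.group_compare(df, "metric")
        t = res["pairwise"]["glaucoma_vs_normal"]["t"]
        assert res["anova_F"] == pytest.approx(t**2, rel=1e-9)

    def test_bonferroni_never_more_liberal(self, rng):
        df = make_df({g: rng.normal(i * 0.5, 1, 10) for i, g in enumerate(["normal", "suspect", "glaucoma"])})
        res = st.group_compare(df, "metric")
        for pw in res["pairwise"].values():
            assert pw["p_bonferroni"] >= pw["p"]
            if pw["significant"]:
                assert pw["p"] < 0.05 / 3

    def test_empty_group_refused(self):
        df = make_df({"normal": [1, 2, 3], "glaucoma": [4]})
        with pytest.raises(ValueError, match=">= 2"):
            st.group_compare(df, "metric")


class TestRegression:
    def test_hand_computed_ols(self):
        """Points (0,0),(1,1),(2,2),(3,4): slope 1.3, intercept -0.2."""
        df = pd.DataFrame({"x": [0, 1, 2, 3], "y": [0, 1, 2, 4]})
        res = st.univariate_regression(df, "x", "y")
        assert res["slope"] == pytest.approx(1.3)
        assert res["intercept"] == pytest.approx(-0.2)

    def test_collinear_r_squared_one(self):
        df = pd.DataFrame({"x": [0.0, 1, 2, 3], "y": [5.0, 7, 9, 11]})
        res = st.univariate_regression(df, "x", "y")
        assert res["r_squared"] == pytest.approx(1.0)
        assert res["p"] < 1e-10

    def test_null_slope_p_uniform(self, rng):
        """Independent x, y: slope ~ 0 and p approximately uniform."""
        ps = []
        for _ in range(200):
            x = rng.normal(0, 1, 25)
            y = rng.normal(0, 1, 25)
            res = st.univariate_regression(pd.DataFrame({"x": x, "y": y}), "x", "y")
            ps.append(res["p"])
        ps = np.asarray(ps)
        assert abs((ps < 0.5).mean() - 0.5) < 0.1
        assert (ps < 0.05).mean() < 0.12

    def test_cross_check_against_statsmodels(self, rng):
        import statsmodels.api as sm

        x = rng.normal(0, 1, 30)
        y = 2.0 * x + rng.normal(0, 0.5, 30)
        mine = st.univariate_regression(pd.DataFrame({"x": x, "y": y}), "x", "y")
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        assert mine["slope"] == pytest.approx(fit.params[1], rel=1e-10)
        assert mine["p"] == pytest.approx(fit.pvalues[1], rel=1e-8)


class TestAroc:
    def test_hand_counted_auroc_with_tie(self):
        """Positives {3,4,5} vs negatives {1,2,3}: (8 + 0.5)/9 ~ 0.944."""
        r = st.compute_aroc(np.array([3, 4, 5]), np.array([1, 2, 3]))
        assert r.auroc == pytest.approx(8.5 / 9)

    def test_perfect_separation(self):
        r = st.compute_aroc(np.array([10.0, 11, 12]), np.array([1.0, 2, 3]))
        assert r.auroc == 1.0

    def test_identical_distributions_near_chance(self, rng):
        r = st.compute_aroc(rng.normal(0, 1, 400), rng.normal(0, 1, 400), orient=False)
        assert r.auroc == pytest.approx(0.5, abs=0.06)

    def test_orientation_flips_low_scores(self):
        """Lower flux in disease still reports a discriminative AROC >= 0.5."""
        r = st.compute_aroc(np.array([0.1, 0.2, 0.15]), np.array([0.5, 0.6, 0.7]))
        assert r.auroc == 1.0
        assert r.direction == -1

    def test_monotone_transform_invariance(self, rng):
        pos = rng.normal(1, 1, 30)
        neg = rng.normal(0, 1, 40)
        a = st.compute_aroc(pos, neg).auroc
        b = st.compute_aroc(np.exp(pos), np.exp(neg)).auroc
        assert a == pytest.approx(b, abs=1e-12)

    def test_cross_check_against_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        pos = rng.normal(0.8, 1, 25)
        neg = rng.normal(0, 1, 35)
        mine = st.compute_aroc(pos, neg, orient=False).auroc
        ref = roc_auc_score([1] * 25 + [0] * 35, np.concatenate([pos, neg]))
        assert mine == pytest.approx(ref, abs=1e-12)

    def test_delong_comparison_detects_better_metric(self, rng):
        """A clean metric beats a pure-noise metric on the same eyes."""
        n = 60
        disease = np.r_[np.ones(n), np.zeros(n)].astype(bool)
        good = np.where(disease, rng.normal(2, 1, 2 * n), rng.normal(0, 1, 2 * n))
        noise = rng.normal(0, 1, 2 * n)
        r_good = st.compute_aroc(good[disease], good[~disease], orient=False)
        r_noise = st.compute_aroc(noise[disease], noise[~disease], orient=False)
        res = st.compare_arocs(r_good, r_noise)
        assert res["delta"] > 0.2
        assert res["p"] < 0.01

    def test_delong_same_metric_p_near_one(self, rng):
        pos, neg = rng.normal(1, 1, 30), rng.normal(0, 1, 30)
        r1 = st.compute_aroc(pos, neg)
        res = st.compare_arocs(r1, st.compute_aroc(pos, neg))
        assert res["p"] == pytest.approx(1.0)

    def test_empty_class_refused(self):
        with pytest.raises(ValueError, match="non-empty"):
            st.compute_aroc(np.array([]), np.array([1.0]))


class TestReproducibilityCv:
    def test_identical_visits_zero_cv(self):
        x = np.array([10.0, 20.0, 30.0])
        res = st.reproducibility_cv(x, x)
        assert res["mean"] == 0.0 and res["max"] == 0.0

    def test_hand_computed_cv(self):
        """x1=100, x2=110: CV = (10/sqrt(2))/105 * 100 ~ 6.73%."""
        res = st.reproducibility_cv(np.array([100.0]), np.array([110.0]))
        assert res["mean"] == pytest.approx(100 * (10 / np.sqrt(2)) / 105, rel=1e-9)
        assert res["mean"] == pytest.approx(6.73, abs=0.01)

    def test_three_percent_noise_gives_three_percent_cv(self, rng):
        truth = rng.uniform(0.2, 0.3, 100)
        x1 = truth * (1 + 0.03 * rng.standard_normal(100))
        x2 = truth * (1 + 0.03 * rng.standard_normal(100))
        res = st.reproducibility_cv(x1, x2)
        assert 2.0 <= res["mean"] <= 4.0


class TestMopp:
    def test_worked_example_both_modes(self):
        """sbp=120, dbp=80, iop=15: MAP=93.33; paper mode 52.22, outside 47.22."""
        assert st.compute_mopp(120, 80, 15, mode="paper") == pytest.approx(52.22, abs=0.005)
        assert st.compute_mopp(120, 80, 15, mode="outside") == pytest.approx(47.22, abs=0.005)

    def test_equal_pressures_map_identity(self):
        assert st.compute_mopp(90, 90, 0, mode="paper") == pytest.approx(2 / 3 * 90)

    def test_negative_mopp_allowed(self):
        assert st.compute_mopp(80, 70, 80, mode="paper") < 0

    def test_invalid_pressures_refused(self):
        with pytest.raises(ValueError, match="sbp"):
            st.compute_mopp(70, 80, 10)
        with pytest.raises(ValueError, match="IOP"):
            st.compute_mopp(120, 80, -1)
        with pytest.raises(ValueError, match="mode"):
            st.compute_mopp(120, 80, 10, mode="bogus")
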