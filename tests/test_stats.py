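"""Transforms, routed tests, selection, PCA/LDA/CVA and permutation MANOVA."""

import numpy as np
import pandas as pd
import pytest

from lithotex.stats import (
    CanonicalVariates,
    FeatureTable,
    circular_to_linear,
    cva,
    lda_cv,
    logit_transform,
    manova_permutation,
    pca,
    robust_summary,
    select_variables,
    shapiro_route,
    wilks_lambda,
)


class TestTransforms:
    @pytest.mark.parametrize("p,expected", [(0.5, 0.0), (0.9, np.log(9.0))])
    def test_logit_closed_form(self, p, expected):
        assert logit_transform(p) == pytest.approx(expected, abs=1e-12)

    def test_logit_boundary_clipped_finite(self):
        v = logit_transform(1.0)  # e.g. isotropy of 100%
        assert np.isfinite(v)
        assert v == pytest.approx(np.log((1 - 1e-6) / 1e-6), rel=1e-6)

    def test_logit_outside_bounds_rejected(self):
        with pytest.raises(ValueError):
            logit_transform(1.2)

    @pytest.mark.parametrize("theta,expected", [(0.0, 1.0), (90.0, 1.0), (45.0, np.sqrt(2))])
    def test_cos_plus_sin_closed_form(self, theta, expected):
        assert circular_to_linear(theta) == pytest.approx(expected, abs=1e-12)

    def test_axial_doubling_identifies_0_and_180(self):
        assert circular_to_linear(0.0, axial=True) == pytest.approx(
            circular_to_linear(180.0, axial=True), abs=1e-12
        )


class TestShapiroRouting:
    def test_gaussian_groups_route_to_anova(self, rng):
        v = np.concatenate([rng.normal(0, 1, 50), rng.normal(0.2, 1, 50)])
        r = shapiro_route(v, np.repeat(["a", "b"], 50))
        assert r.test_name == "ANOVA"

    def test_heavy_tails_route_to_kruskal(self, rng):
        v = np.concatenate([rng.standard_cauchy(80), rng.standard_cauchy(80)])
        r = shapiro_route(v, np.repeat(["a", "b"], 80))
        assert r.test_name == "Kruskal-Wallis"

    def test_small_groups_rejected(self, rng):
        with pytest.raises(ValueError):
            shapiro_route(np.arange(4.0), np.array(["a", "a", "b", "b"]))


class TestRobustSummary:
    def test_gaussian_consistency(self):
        x = np.random.default_rng(7).normal(0, 2.5, 10_000)
        s = robust_summary(x)
        assert s["sqrt_bwmv"] == pytest.approx(2.5, rel=0.03)

    def test_outlier_resistance(self, rng):
        x = rng.normal(0, 1, 500)
        clean = robust_summary(x)["sqrt_bwmv"]
        dirty = robust_summary(np.append(x, 1e6))["sqrt_bwmv"]
        assert abs(dirty - clean) / clean < 0.05

    def test_constant_vector(self):
        assert robust_summary(np.full(10, 3.0))["sqrt_bwmv"] == 0.0

    def test_tiny_sample_flagged(self):
        s = robust_summary(np.array([1.0, 2.0, 3.0]))
        assert s["flag"] is not None and np.isnan(s["sqrt_bwmv"])


def _table(df: pd.DataFrame, groups, classes=None):
    classes = classes or {c: "linear" for c in df.columns}
    return FeatureTable(df, classes, pd.DataFrame({"grp": groups}))


class TestSelection:
    def test_duplicated_column_keeps_exactly_one(self, rng):
        x = np.concatenate([rng.normal(0, 1, 40), rng.normal(4, 1, 40)])
        df = pd.DataFrame({"a": x, "b": x + rng.normal(0, 1e-9, 80)})
        report, _ = select_variables(_table(df, np.repeat(["g1", "g2"], 40)), "grp")
        assert len(report.retained) == 1

    def test_below_threshold_pair_both_kept(self, rng):
        n = 200
        x = np.concatenate([rng.normal(0, 1, n), rng.normal(3, 1, n)])
        noise = rng.normal(0, 1, 2 * n)
        # corr(a, b) = c / sqrt(c^2 + 1); choose c for R^2 ~ 0.64 < 0.7
        y = 1.35 * x + noise * np.std(x)
        df = pd.DataFrame({"a": x, "b": y})
        report, _ = select_variables(
            _table(df, np.repeat(["g1", "g2"], n)), "grp", r2_threshold=0.7
        )
        r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert r2 < 0.7
        assert len(report.retained) == 2

    def test_three_mutually_correlated_keep_one(self, rng):
        x = np.concatenate([rng.normal(0, 1, 60), rng.normal(5, 1, 60)])
        df = pd.DataFrame(
            {
                "a": x + rng.normal(0, 0.1, 120),
                "b": x + rng.normal(0, 0.1, 120),
                "c": x + rng.normal(0, 0.1, 120),
            }
        )
        report, uni = select_variables(_table(df, np.repeat(["g1", "g2"], 60)), "grp")
        assert len(report.retained) == 1
        # greedy rule: the survivor has the smallest univariate p among a, b, c
        best = min("abc", key=lambda c: uni[c].p_value)
        assert report.retained == [best]

    def test_every_drop_names_one_partner(self, rng):
        x = np.concatenate([rng.normal(0, 1, 60), rng.normal(5, 1, 60)])
        df = pd.DataFrame({"a": x, "b": x + rng.normal(0, 0.05, 120),
                           "c": rng.normal(0, 1, 120) + x})
        report, _ = select_variables(_table(df, np.repeat(["g1", "g2"], 60)), "grp")
        assert (report.dropped["kept_partner"].isin(report.retained)).all()


class TestPca:
    def test_isotropic_gaussian_flat_spectrum(self):
        X = np.random.default_rng(0).normal(0, 1, (3000, 3))
        model = pca(X)
        np.testing.assert_allclose(model.explained_ratio, 1 / 3, atol=0.05)

    def test_rank_one_data(self, rng):
        u = rng.normal(0, 1, 200)
        X = np.outer(u, [1.0, 2.0, -1.0]) + rng.normal(0, 1e-6, (200, 3))
        model = pca(X)
        assert model.explained_ratio[0] > 0.999
        assert model.retained == 1

    def test_full_reconstruction(self, rng):
        X = rng.normal(0, 1, (50, 4))
        model = pca(X, standardize=True)
        Xs = (X - model.mean_) / model.scale_
        back = model.scores @ model.loadings
        np.testing.assert_allclose(back, Xs, atol=1e-9)

    def test_missing_cells_rejected(self):
        X = np.ones((10, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            pca(X)


class TestLda:
    def test_separable_classes_high_accuracy(self, rng):
        n = 120
        X = np.vstack([rng.normal(0, 1, (n, 3)), rng.normal(6, 1, (n, 3))])
        y = np.repeat(["a", "b"], n)
        report = lda_cv(X, y, seed=1)
        assert report.accuracy > 0.95
        assert report.kappa > 0.9
        assert report.ci_low <= report.accuracy <= report.ci_high

    def test_permuted_labels_chance_level(self, rng):
        n = 150
        X = np.vstack([rng.normal(0, 1, (n, 3)), rng.normal(4, 1, (n, 3))])
        y = rng.permutation(np.repeat(["a", "b"], n))
        report = lda_cv(X, y, seed=2)
        assert abs(report.kappa) < 0.15
        assert abs(report.accuracy - report.nir) < 0.15

    def test_kappa_matches_hand_computation(self):
        # constructed 3-class prediction with known confusion matrix
        y_true = np.repeat(["a", "b", "c"], [10, 10, 10])
        y_pred = np.array(
            ["a"] * 8 + ["b"] * 2 + ["b"] * 7 + ["c"] * 3 + ["c"] * 9 + ["a"] * 1
        )
        from sklearn.metrics import cohen_kappa_score

        po = 24 / 30
        marg_true = np.array([10, 10, 10]) / 30
        marg_pred = np.array([9, 9, 12]) / 30
        pe = float(np.sum(marg_true * marg_pred))
        expected = (po - pe) / (1 - pe)
        assert cohen_kappa_score(y_true, y_pred) == pytest.approx(expected, abs=1e-12)

    def test_nir_equals_max_class_share(self, rng):
        X = np.vstack([rng.normal(0, 1, (40, 2)), rng.normal(5, 1, (80, 2))])
        y = np.repeat(["rare", "common"], [40, 80])
        report = lda_cv(X, y, seed=0)
        counts = pd.Series(report.confusion.sum(axis=1))
        assert report.nir == pytest.approx(counts.max() / counts.sum())

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            lda_cv(rng.normal(0, 1, (20, 2)), np.repeat("only", 20))


class TestCva:
    def test_two_classes_one_axis(self, rng):
        X = np.vstack([rng.normal(0, 1, (30, 4)), rng.normal(3, 1, (30, 4))])
        model = cva(X, np.repeat(["a", "b"], 30))
        assert model.axes_.shape == (4, 1)

    def test_separated_classes_cluster_in_loo_scores(self, rng):
        from sklearn.metrics import silhouette_score

        X = np.vstack([rng.normal(0, 1, (25, 3)), rng.normal(8, 1, (25, 3))])
        y = np.repeat(["a", "b"], 25)
        model = cva(X, y)
        assert silhouette_score(model.loo_scores_, y) > 0.5

    def test_cv1_orders_class_means_like_the_informative_variable(self, rng):
        means = {"lo": 0.0, "mid": 3.0, "hi": 6.0}
        X = np.vstack([np.column_stack([rng.normal(m, 1, 30), rng.normal(0, 1, 30)])
                       for m in means.values()])
        y = np.repeat(list(means), 30)
        model = CanonicalVariates().fit(X, y)
        proj = model.transform(X)[:, 0]
        order = sorted(means, key=lambda c: proj[y == c].mean())
        assert order in (["lo", "mid", "hi"], ["hi", "mid", "lo"])


class TestManova:
    def test_lambda_in_unit_interval(self, rng):
        X = rng.normal(0, 1, (40, 2))
        lam = wilks_lambda(X, np.repeat(["a", "b"], 20))
        assert 0.0 < lam <= 1.0

    def test_lambda_matches_statsmodels(self, rng):
        from statsmodels.multivariate.manova import MANOVA

        X = np.vstack([rng.normal(0, 1, (25, 2)), rng.normal(1.5, 1, (25, 2))])
        y = np.repeat([0, 1], 25)
        lam = wilks_lambda(X, y)
        df = pd.DataFrame({"y": y, "v1": X[:, 0], "v2": X[:, 1]})
        fit = MANOVA.from_formula("v1 + v2 ~ C(y)", data=df).mv_test()
        lam_sm = fit.results["C(y)"]["stat"].loc["Wilks' lambda", "Value"]
        assert lam == pytest.approx(lam_sm, rel=1e-6)

    def test_separated_groups_saturate_p(self, rng):
        X = np.vstack([rng.normal(0, 1, (25, 2)), rng.normal(10, 1, (25, 2))])
        r = manova_permutation(X, np.repeat(["a", "b"], 25), n_perm=999, seed=0)
        assert r.p_value == pytest.approx(0.001)

    def test_single_group_rejected(self, rng):
        with pytest.raises(ValueError):
            manova_permutation(rng.normal(0, 1, (20, 2)), np.repeat("g", 20))


class TestPropertyInvariants:
    """Property-based checks of the transform layer."""

    from hypothesis import given, settings, strategies as st

    @given(st.floats(min_value=1e-6, max_value=1 - 1e-6))
    @settings(max_examples=50, deadline=None)
    def test_logit_strictly_monotone(self, p):
        eps = 1e-7
        if p + eps < 1 - 1e-6:
            assert logit_transform(p + eps) > logit_transform(p)

    @given(st.floats(min_value=-1e4, max_value=1e4))
    @settings(max_examples=50, deadline=None)
    def test_cos_plus_sin_bounded_and_periodic(self, theta):
        v = circular_to_linear(theta)
        assert -np.sqrt(2) - 1e-9 <= v <= np.sqrt(2) + 1e-9
        assert v == pytest.approx(circular_to_linear(theta + 360.0), abs=1e-6)

    @given(st.lists(st.floats(min_value=-1e3, max_value=1e3), min_size=4, max_size=40),
           st.floats(min_value=-1e3, max_value=1e3))
    @settings(max_examples=50, deadline=None)
    def test_robust_summary_translation_equivariance(self, xs, shift):
        x = np.asarray(xs)
        a = robust_summary(x)
        b = robust_summary(x + shift)
        assert b["median"] == pytest.approx(a["median"] + shift, abs=1e-6 * (1 + abs(shift)))
        if np.isfinite(a["sqrt_bwmv"]):
            assert b["sqrt_bwmv"] == pytest.approx(a["sqrt_bwmv"], rel=1e-9, abs=1e-9)
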