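"""Size/shape hypothesis tests: ANOVA, Wilks/Rao, permutations, Holm,
allometry, size correction and discriminant analysis."""

import numpy as np
import pytest

import molarmorph as mm
from molarmorph.errors import DesignError
from molarmorph.group_stats import mancova


@pytest.fixture(scope="module")
def study_arrays(medium_fit):
    ds, fit = medium_fit
    space = mm.shape_pca(fit)
    return {
        "groups": ds.labels("group"),
        "sexes": ds.labels("sex"),
        "cs": fit.centroid_sizes,
        "scores": space.scores[:, :20],
        "tangent": fit.tangent_coords,
        "fit": fit,
    }


class TestTwoWayAnova:
    def test_design_degrees_of_freedom(self, study_arrays):
        tab = mm.two_way_anova(
            study_arrays["cs"], study_arrays["groups"], study_arrays["sexes"], True
        )
        assert tab.row("groups")["df"] == 3
        assert tab.row("sex")["df"] == 1
        assert tab.row("groups:sex")["df"] == 3

    def test_matches_statsmodels_type_iii_on_unbalanced_data(self, study_arrays):
        import pandas as pd
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        tab = mm.two_way_anova(
            study_arrays["cs"], study_arrays["groups"], study_arrays["sexes"], True
        )
        df = pd.DataFrame(
            {"y": study_arrays["cs"], "g": study_arrays["groups"], "s": study_arrays["sexes"]}
        )
        fit = smf.ols("y ~ C(g, Sum) * C(s, Sum)", data=df).fit()
        ref = anova_lm(fit, typ=3)
        assert tab.row("groups")["ss"] == pytest.approx(ref.loc["C(g, Sum)", "sum_sq"])
        assert tab.row("sex")["ss"] == pytest.approx(ref.loc["C(s, Sum)", "sum_sq"])
        assert tab.row("groups:sex")["f"] == pytest.approx(
            ref.loc["C(g, Sum):C(s, Sum)", "F"]
        )

    def test_balanced_type_iii_equals_type_i(self):
        rng = np.random.default_rng(4)
        g = np.repeat(["a", "b", "c", "d"], 10)
        s = np.tile(np.repeat(["F", "M"], 5), 4)
        y = rng.normal(size=40) + (g == "a") * 0.5
        tab = mm.two_way_anova(y, g, s, True)
        import pandas as pd
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        ref = anova_lm(
            smf.ols("y ~ C(g, Sum) * C(s, Sum)", data=pd.DataFrame({"y": y, "g": g, "s": s})).fit(),
            typ=1,
        )
        assert tab.row("groups")["ss"] == pytest.approx(ref.loc["C(g, Sum)", "sum_sq"])

    def test_constant_response_gives_zero_ss(self):
        g = np.repeat(["a", "b"], 6)
        s = np.tile(["F", "M"], 6)
        tab = mm.two_way_anova(np.ones(12), g, s, True)
        assert tab.row("groups")["ss"] == pytest.approx(0.0, abs=1e-20)

    def test_empty_cell_with_interaction_rejected(self):
        g = np.array(["a", "a", "b", "b"])
        s = np.array(["F", "F", "F", "F"])
        with pytest.raises(DesignError):
            mm.two_way_anova(np.arange(4.0), g, s, True)


class TestRaoF:
    def test_univariate_reduction(self):
        """With p = 1 the transformation is the ordinary F statistic."""
        lam, q, dfe = 0.8, 3, 36
        f, df1, df2 = mm.rao_f(lam, 1, q, dfe)
        assert (df1, df2) == (q, dfe)
        assert f == pytest.approx((1 - lam) / lam * dfe / q)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mm.rao_f(0.0, 2, 2, 50)
        with pytest.raises(DesignError):
            mm.rao_f(0.5, 20, 3, 15)


class TestManova:
    def test_single_response_equals_univariate_anova(self, study_arrays):
        y = study_arrays["cs"]
        res = mm.manova(y[:, None], study_arrays["groups"], study_arrays["sexes"], True)
        tab = mm.two_way_anova(y, study_arrays["groups"], study_arrays["sexes"], True)
        by_name = {r.effect: r for r in res}
        for eff in ("groups", "sex", "groups:sex"):
            assert by_name[eff].f == pytest.approx(tab.row(eff)["f"], rel=1e-9)
            assert by_name[eff].p == pytest.approx(tab.row(eff)["p"], rel=1e-9)

    def test_matches_statsmodels_manova(self, study_arrays):
        import pandas as pd
        from statsmodels.multivariate.manova import MANOVA

        res = mm.manova(
            study_arrays["scores"], study_arrays["groups"], study_arrays["sexes"], True
        )
        cols = [f"y{i}" for i in range(20)]
        df = pd.DataFrame(study_arrays["scores"], columns=cols)
        df["g"], df["s"] = study_arrays["groups"], study_arrays["sexes"]
        ref = MANOVA.from_formula(
            " + ".join(cols) + " ~ C(g, Sum)*C(s, Sum)", data=df
        ).mv_test().summary_frame
        by_name = {r.effect: r for r in res}
        mapping = {
            "groups": "C(g, Sum)",
            "sex": "C(s, Sum)",
            "groups:sex": "C(g, Sum):C(s, Sum)",
        }
        for eff, sm_name in mapping.items():
            row = ref.loc[(sm_name, "Wilks' lambda")]
            assert by_name[eff].wilks_lambda == pytest.approx(row["Value"], abs=1e-9)
            assert by_name[eff].f == pytest.approx(row["F Value"], rel=1e-6)
            assert by_name[eff].eta_squared == pytest.approx(
                1 - by_name[eff].wilks_lambda
            )

    def test_mancova_with_orthogonal_covariate_is_noop(self, study_arrays):
        """A covariate orthogonal to responses and design leaves the group
        lambda unchanged (only the residual df shifts by one)."""
        Y = study_arrays["scores"][study_arrays["sexes"] == "F"]
        g = study_arrays["groups"][study_arrays["sexes"] == "F"]
        rng = np.random.default_rng(6)
        cov = rng.normal(size=len(Y))
        # orthogonalize against responses, group dummies and intercept
        from molarmorph.group_stats import _sum_code

        M = np.hstack([np.ones((len(Y), 1)), _sum_code(g, sorted(set(g))), Y])
        cov = cov - M @ np.linalg.lstsq(M, cov, rcond=None)[0]
        res_cov = mancova(Y, g, cov + 10.0, include_interaction=False)
        lam_cov = {r.effect: r for r in res_cov}["groups"].wilks_lambda
        # one-way Wilks lambda without any covariate
        lda = mm.lda_crossval(Y, g)
        assert lam_cov == pytest.approx(lda.wilks.wilks_lambda, rel=1e-9)

    def test_mancova_constant_covariate_rejected(self, study_arrays):
        with pytest.raises(DesignError):
            mancova(study_arrays["scores"], study_arrays["groups"], np.ones(153))


class TestPermutationTests:
    def test_separated_groups_reach_minimal_p(self):
        rng = np.random.default_rng(10)
        values = np.concatenate([rng.normal(0, 0.1, 15), rng.normal(50, 0.1, 15)])
        labels = np.repeat(["a", "b"], 15)
        res = mm.pairwise_permutation_tests(
            values, labels, "mean_difference", n_perm=199, seed=1
        )
        assert res.get("a", "b")["p_raw"] == pytest.approx(1 / 200)

    def test_percent_explained_hand_oracle(self):
        """{0,2} vs {1,3}: SSB = 1, SST = 5, so 20% explained."""
        values = np.array([0.0, 2.0, 1.0, 3.0])
        labels = np.array(["a", "a", "b", "b"])
        res = mm.pairwise_permutation_tests(
            values, labels, "mean_difference", n_perm=99, seed=0
        )
        assert res.get("a", "b")["percent_explained"] == pytest.approx(20.0)

    def test_deterministic_under_seed(self, study_arrays):
        sel = study_arrays["sexes"] == "F"
        from molarmorph.pipeline import _subset_fit

        sub = _subset_fit(study_arrays["fit"], sel)
        a = mm.pairwise_permutation_tests(
            sub, study_arrays["groups"][sel], "procrustes_distance", n_perm=99, seed=5
        )
        b = mm.pairwise_permutation_tests(
            sub, study_arrays["groups"][sel], "procrustes_distance", n_perm=99, seed=5
        )
        for pair in a.pairs:
            assert a.pairs[pair]["p_raw"] == b.pairs[pair]["p_raw"]

    def test_singleton_group_rejected(self):
        with pytest.raises(DesignError):
            mm.pairwise_permutation_tests(
                np.arange(4.0), np.array(["a", "b", "b", "b"]), "mean_difference", 99, 0
            )


class TestHolm:
    def test_hand_computed_example(self):
        adj = mm.holm_adjust([0.01, 0.02, 0.04])
        assert np.allclose(adj, [0.03, 0.04, 0.04])

    def test_trivial_cases(self):
        assert mm.holm_adjust([0.2]) == pytest.approx([0.2])
        assert np.allclose(mm.holm_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_statsmodels_and_is_monotone(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(11)
        p = rng.uniform(size=25)
        adj = mm.holm_adjust(p)
        _, ref, _, _ = multipletests(p, method="holm")
        assert np.allclose(adj, ref)
        assert np.all(adj >= p)


class TestAllometry:
    def test_exact_linear_dependence_gives_100_percent(self):
        rng = np.random.default_rng(13)
        cs = rng.uniform(15, 20, 30)
        v = rng.standard_normal(54)
        Y = np.outer(cs, v)
        res = mm.allometry_regression(Y, cs, n_perm=99, seed=0)
        assert res.percent_predicted == pytest.approx(100.0, abs=1e-9)
        assert res.p_permutation <= 0.05

    def test_independent_shape_gives_small_percent(self):
        rng = np.random.default_rng(14)
        Y = rng.standard_normal((40, 54))
        cs = rng.uniform(15, 20, 40)
        res = mm.allometry_regression(Y, cs, n_perm=199, seed=0)
        assert res.percent_predicted < 15.0
        assert res.p_permutation > 0.01

    def test_constant_cs_rejected(self):
        with pytest.raises(DesignError):
            mm.allometry_regression(np.random.default_rng(0).normal(size=(10, 6)), np.ones(10))


class TestSizeCorrect:
    def test_zero_allometry_leaves_shapes_unchanged(self):
        rng = np.random.default_rng(15)
        Y = rng.standard_normal((30, 54)) * 0.01
        cs = rng.uniform(15, 20, 30)
        g = np.repeat(["a", "b", "c"], 10)
        corrected = mm.size_correct(Y, cs, g)
        # slope estimate is O(noise/sqrt(n)); correction must be tiny
        assert np.abs(corrected - Y).max() < 0.02

    def test_common_slope_allometry_fully_removed(self):
        rng = np.random.default_rng(16)
        cs = rng.uniform(15, 20, 60)
        g = np.repeat(["a", "b", "c"], 20)
        v = rng.standard_normal(54)
        offsets = {"a": 0.0, "b": 5.0, "c": -3.0}
        Y = (
            np.outer(cs, v)
            + np.array([offsets[x] for x in g])[:, None]
            + rng.normal(0, 0.1, (60, 54))
        )
        corrected = mm.size_correct(Y, cs, g)
        # pooled within-group covariance of corrected shapes with CS is zero
        pooled = np.zeros(54)
        for grp in "abc":
            rows = g == grp
            xc = cs[rows] - cs[rows].mean()
            Yc = corrected[rows] - corrected[rows].mean(axis=0)
            pooled += xc @ Yc
        assert np.abs(pooled).max() < 1e-8
        # group separation preserved
        assert np.linalg.norm(
            corrected[g == "b"].mean(0) - corrected[g == "a"].mean(0)
        ) > 1.0

    def test_significance_pattern_preserved_under_weak_allometry(self, study_arrays):
        """Size correction does not change which pairs differ."""
        sel = study_arrays["sexes"] == "F"
        from molarmorph.pipeline import _subset_fit, _with_tangent

        g = study_arrays["groups"][sel]
        raw = mm.pairwise_permutation_tests(
            _subset_fit(study_arrays["fit"], sel), g, "procrustes_distance",
            n_perm=299, seed=3,
        )
        corrected = mm.size_correct(
            study_arrays["tangent"][sel], study_arrays["cs"][sel], g
        )
        corr_fit = _with_tangent(_subset_fit(study_arrays["fit"], sel), corrected)
        cor = mm.pairwise_permutation_tests(
            corr_fit, g, "procrustes_distance", n_perm=299, seed=3
        )
        for pair in raw.pairs:
            assert raw.pairs[pair]["significant"] == cor.pairs[pair]["significant"]


class TestDiscriminant:
    def test_well_separated_clusters_classified_perfectly(self):
        rng = np.random.default_rng(17)
        centers = np.eye(4) * 50
        Y = np.vstack([rng.normal(c, 0.5, size=(12, 4)) for c in centers])
        labels = np.repeat(list("abcd"), 12)
        res = mm.lda_crossval(Y, labels)
        assert res.accuracy_loo == pytest.approx(1.0)
        assert res.accuracy_resub == pytest.approx(1.0)
        assert np.all(res.confusion_loo.sum(axis=1) == 12)

    def test_singular_covariance_rejected(self):
        rng = np.random.default_rng(18)
        with pytest.raises(DesignError):
            mm.lda_crossval(rng.normal(size=(12, 10)), np.repeat(list("abcd"), 3))

    def test_wilks_test_matches_mancova_machinery(self, study_arrays):
        """The one-way Wilks lambda agrees with the general design path."""
        sel = study_arrays["sexes"] == "M"
        Y = study_arrays["scores"][sel]
        g = study_arrays["groups"][sel]
        res = mm.lda_crossval(Y, g)
        n, p = Y.shape
        f, df1, df2 = mm.rao_f(res.wilks.wilks_lambda, p, 3, n - 4)
        assert res.wilks.f == pytest.approx(f)
        assert (res.wilks.df1, res.wilks.df2) == (df1, df2)
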