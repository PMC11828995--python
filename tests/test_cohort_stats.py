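import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bonechem.cohort_stats import (
    DEFAULT_DROP,
    correlation_matrix,
    pairwise_wilcoxon,
    pca,
    prune_correlated,
    select_global_test,
    summarise_units,
)

# deterministic three-group fixture; reference statistics computed with
# R 4.3 (wilcox.test exact=FALSE, kruskal.test, shapiro.test,
# oneway.test var.equal=FALSE)
G1 = [8.576175, 11.263728, 9.129338, 9.740827, 9.924657, 9.259115,
      8.632207, 10.648893, 10.361058, 8.047137, 12.34741, 10.968497]
G2 = [9.860919, 12.353297, 10.29957, 10.908966, 12.183267, 9.114998,
      11.863786, 13.098468, 12.983447, 10.550452, 12.354379, 8.567626]
G3 = [9.362612, 11.9388, 5.827334, 9.653543, 19.883614, 28.42485,
      13.611902, 13.893947, 6.796479, 6.148725, 5.669399, 12.386643]


def fixture_table():
    return pd.DataFrame(
        {
            "unit": ["A"] * 12 + ["B"] * 12 + ["C"] * 12,
            "x": G1 + G2 + G3,
        }
    )


class TestReferenceAgreement:
    def test_rank_sum_matches_reference(self):
        res = sps.mannwhitneyu(G1, G2, alternative="two-sided", method="asymptotic")
        assert res.pvalue == pytest.approx(0.0689643333391, abs=1e-9)

    def test_kruskal_matches_reference(self):
        stat, p = sps.kruskal(G1, G2, G3)
        assert stat == pytest.approx(2.20870870871, abs=1e-8)
        assert p == pytest.approx(0.331424796155, abs=1e-9)

    def test_shapiro_matches_reference(self):
        res = sps.shapiro(G3)
        assert res.statistic == pytest.approx(0.847287425836, abs=1e-7)
        assert res.pvalue == pytest.approx(0.033993344723, abs=1e-6)

    def test_welch_anova_matches_reference(self):
        from statsmodels.stats.oneway import anova_oneway

        res = anova_oneway([G1, G2, G3], use_var="unequal", welch_correction=True)
        assert res.statistic == pytest.approx(2.7052467585, abs=1e-8)
        assert res.pvalue == pytest.approx(0.0917075358604, abs=1e-9)


class TestGlobalTestGating:
    def test_non_normal_group_routes_to_rank_test(self):
        name, gating = select_global_test(fixture_table(), "x")
        # G3 is lognormal and fails Shapiro-Wilk at alpha = 0.05
        assert name == "kruskal_wallis"
        assert gating["shapiro_p"]["C"] < 0.05

    def test_all_normal_routes_to_welch(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(
            {
                "unit": np.repeat(list("ABCDE"), 40),
                "x": np.concatenate(
                    [rng.normal(m, s, 40) for m, s in [(0, 1), (1, 2), (2, 1), (3, 3), (4, 1)]]
                ),
            }
        )
        name, _ = select_global_test(df, "x")
        assert name == "welch_anova"

    def test_constant_feature_rejected(self):
        df = fixture_table()
        df["x"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            select_global_test(df, "x")


class TestPairwiseWilcoxon:
    def test_identical_groups_give_unit_p(self):
        df = pd.DataFrame({"unit": ["A"] * 12 + ["B"] * 12, "x": G1 + G1})
        comp = pairwise_wilcoxon(df, "x")
        assert comp.pairwise.loc["A", "B"] == pytest.approx(1.0)

    def test_strong_separation_detected(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 30)
        b = rng.normal(3, 1, 30)  # 3-pooled-SD separation
        df = pd.DataFrame({"unit": ["A"] * 30 + ["B"] * 30, "x": np.r_[a, b]})
        comp = pairwise_wilcoxon(df, "x")
        assert comp.pairwise.loc["A", "B"] < 1e-5

    def test_rank_invariance_under_monotone_transform(self):
        df = fixture_table()
        raw = pairwise_wilcoxon(df, "x").pairwise
        df2 = df.assign(x=np.exp(df["x"] / 3.0))
        transformed = pairwise_wilcoxon(df2, "x").pairwise
        assert np.allclose(raw.fillna(0), transformed.fillna(0))

    def test_adjusted_matrix_symmetric_in_unit_interval(self, cohort):
        comp = pairwise_wilcoxon(cohort, "HCP")
        m = comp.pairwise
        assert np.allclose(m.fillna(0), m.fillna(0).T)
        off = m.values[~np.eye(len(m), dtype=bool)]
        assert ((off >= 0) & (off <= 1)).all()


class TestCorrelationMatrix:
    def test_duplicated_column_perfectly_correlated(self, cohort):
        df = cohort.assign(dup=cohort["HCP"])
        corr = correlation_matrix(df)
        assert corr.loc["HCP", "dup"] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.standard_normal((1500, 2)), columns=["u", "v"])
        assert abs(correlation_matrix(df).loc["u", "v"]) < 0.1

    def test_calibrated_cohort_association(self, cohort):
        corr = correlation_matrix(cohort)
        assert corr.loc["HPO4_1145", "C_C"] == pytest.approx(0.86, abs=0.07)


class TestPruning:
    def test_uncorrelated_table_untouched(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.standard_normal((100, 4)), columns=list("abcd"))
        red, audit = prune_correlated(df, drop=())
        assert list(red.columns) == list("abcd")
        assert audit == []

    def test_study_protocol_survivors(self, cohort):
        red, audit = prune_correlated(cohort)
        survivors = [c for c in red.columns if c not in ("sample_id", "unit")]
        assert sorted(survivors) == sorted(
            ["CellVolume", "HCP", "PCP", "HPO4_1118", "HPO4_1145"]
        )
        assert len([a for a in audit if a["reason"] == "explicit drop list"]) == len(DEFAULT_DROP)

    def test_greedy_rule_hand_trace(self):
        # r(AB)=0.9, r(AC)=0.8, r(BC)=0.1: A has the largest mean absolute
        # correlation and is removed first; B and C survive
        rng = np.random.default_rng(2)
        n = 4000
        a = rng.standard_normal(n)
        b = 0.9 * a + np.sqrt(1 - 0.81) * rng.standard_normal(n)
        c = 0.8 * a - 0.62 * b + rng.standard_normal(n)
        c = (c - c.mean()) / c.std()
        df = pd.DataFrame({"A": a, "B": b, "C": c})
        corr = df.corr().abs()
        assert corr.loc["A", "B"] > 0.75 and corr.loc["B", "C"] < 0.75
        red, audit = prune_correlated(df, drop=())
        assert sorted(red.columns) == ["B", "C"]
        assert audit[0]["removed"] == "A"

    def test_no_surviving_pair_exceeds_threshold(self, cohort):
        red, _ = prune_correlated(cohort, threshold=0.6, drop=())
        feats = [c for c in red.columns if c not in ("sample_id", "unit")]
        corr = red[feats].corr().abs().values
        np.fill_diagonal(corr, 0)
        assert corr.max() < 0.6

    def test_keep_drop_conflict(self, cohort):
        with pytest.raises(ValueError):
            prune_correlated(cohort, keep=("IRSF",), drop=("IRSF",))


class TestPCA:
    def test_two_identical_variables_single_component(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(200)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1})
        res = pca(df)
        assert res.variance_share[0] == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_shares_flat(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.standard_normal((4000, 5)), columns=list("abcde"))
        res = pca(df)
        assert np.allclose(res.variance_share, 0.2, atol=0.02)

    def test_permutation_and_scale_invariance(self, cohort):
        feats = ["HCP", "PCP", "HPO4_1118", "HPO4_1145", "CellVolume"]
        base = pca(cohort, feats).variance_share
        permuted = pca(cohort, feats[::-1]).variance_share
        scaled = pca(cohort.assign(HCP=cohort.HCP * 100), feats).variance_share
        assert np.allclose(base, permuted, atol=1e-10)
        assert np.allclose(base, scaled, atol=1e-10)

    def test_matches_sklearn_on_standardised_data(self, cohort):
        from sklearn.decomposition import PCA as SkPCA

        feats = ["HCP", "PCP", "HPO4_1118", "HPO4_1145", "CellVolume"]
        X = cohort[feats].to_numpy()
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        sk = SkPCA().fit(Z)
        res = pca(cohort, feats)
        assert np.allclose(res.variance_share, sk.explained_variance_ratio_, atol=1e-6)

    def test_loadings_orthonormal(self, cohort):
        res = pca(cohort, ["HCP", "PCP", "HPO4_1118", "HPO4_1145"])
        L = res.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8)


def test_summarise_units_shapes(cohort):
    means, sds = summarise_units(cohort)
    assert means.shape[0] == 5 and sds.shape == means.shape
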