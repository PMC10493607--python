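"""Bray-Curtis, PERMANOVA, SIMPER and PCA against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

import sterolome as st


def euclidean_frame(x):
    d = squareform(pdist(np.asarray(x).reshape(len(x), -1)))
    return pd.DataFrame(d)


class TestBrayCurtis:
    def test_identical_rows_are_zero(self):
        values = pd.DataFrame([[700.0, 300.0], [700.0, 300.0]])
        assert st.bray_curtis(values).iloc[0, 1] == 0.0

    def test_disjoint_supports_are_one(self):
        values = pd.DataFrame([[1000.0, 0.0], [0.0, 1000.0]])
        assert st.bray_curtis(values).iloc[0, 1] == pytest.approx(1.0)

    def test_hand_value(self):
        values = pd.DataFrame([[700.0, 300.0], [300.0, 700.0]])
        # sum|x-y| / sum(x+y) = 800 / 2000
        assert st.bray_curtis(values).iloc[0, 1] == pytest.approx(0.4)

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            st.bray_curtis(pd.DataFrame([[0.0, 0.0], [1.0, 1.0]]))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            st.bray_curtis(pd.DataFrame([[-1.0, 2.0], [1.0, 1.0]]))


class TestPermanova:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_equals_classical_anova_on_univariate_euclidean(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=21)
        groups = np.repeat(["a", "b", "c"], 7)
        res = st.permanova(euclidean_frame(x), groups, n_permutations=10, seed=0)
        f_classic = sps.f_oneway(x[:7], x[7:14], x[14:]).statistic
        assert res.pseudo_f == pytest.approx(f_classic, abs=1e-10)
        assert (res.df_between, res.df_residual) == (2, 18)

    def test_minimal_p_for_separated_groups(self):
        # two groups with a huge gap: no permutation mixing them can reach
        # the observed F, so p hits the add-one floor 1/(1+999)
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(0, 0.01, 10), rng.normal(50, 0.01, 10)])
        groups = np.repeat(["a", "b"], 10)
        res = st.permanova(euclidean_frame(x), groups, n_permutations=999, seed=1)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_invariant_under_sample_reordering(self):
        rng = np.random.default_rng(5)
        values = pd.DataFrame(rng.dirichlet(np.ones(5), size=12) * 1000.0)
        groups = np.array(["a", "b"] * 6)
        d = st.bray_curtis(values)
        base = st.permanova(d, groups, n_permutations=10, seed=0)
        order = rng.permutation(12)
        shuffled = st.permanova(
            d.iloc[order, order], groups[order], n_permutations=10, seed=0
        )
        assert shuffled.pseudo_f == pytest.approx(base.pseudo_f, rel=1e-12)
        assert shuffled.r_squared == pytest.approx(base.r_squared, rel=1e-12)

    def test_matches_reference_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(9)
        values = rng.dirichlet(np.ones(6), size=16) * 1000.0
        ids = [f"s{i}" for i in range(16)]
        d = squareform(pdist(values, metric="braycurtis"))
        groups = list(np.repeat(["a", "b"], 8))
        mine = st.permanova(pd.DataFrame(d, index=ids, columns=ids), groups,
                            n_permutations=99, seed=0)
        ref = sk_permanova(DistanceMatrix(d, ids=ids), grouping=groups,
                           permutations=99)
        assert mine.pseudo_f == pytest.approx(ref["test statistic"], abs=1e-10)

    def test_restricted_permutations_match_exact_enumeration(self):
        # paired design: each stratum holds one sample per group, so the
        # restricted null is exactly the 2^k within-pair swaps
        rng = np.random.default_rng(13)
        k = 6
        base = rng.normal(scale=5.0, size=k)
        effect = 1.5
        x = np.empty(2 * k)
        x[0::2] = base
        x[1::2] = base + effect + rng.normal(scale=0.5, size=k)
        groups = np.array(["leaf", "pollen"] * k)
        strata = np.repeat([f"sp{i}" for i in range(k)], 2)
        d = euclidean_frame(x)

        def f_stat(labels):
            return st.permanova(d, labels, n_permutations=0, seed=0).pseudo_f

        f_obs = f_stat(groups)
        exceed = 0
        for swaps in itertools.product([False, True], repeat=k):
            labels = groups.copy()
            for i, swap in enumerate(swaps):
                if swap:
                    labels[2 * i], labels[2 * i + 1] = labels[2 * i + 1], labels[2 * i]
            if f_stat(labels) >= f_obs - 1e-12:
                exceed += 1
        exact_p = exceed / 2**k

        res = st.permanova(d, groups, n_permutations=2000, seed=3, strata=strata)
        assert res.p_value == pytest.approx(exact_p, abs=0.03)

    def test_confounded_strata_rejected(self):
        d = euclidean_frame(np.arange(6.0))
        groups = np.repeat(["a", "b"], 3)
        with pytest.raises(ValueError, match="stratum"):
            st.permanova(d, groups, strata=groups, n_permutations=10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            st.permanova(euclidean_frame(np.arange(4.0)), ["a"] * 4)


class TestPairwisePermanova:
    def test_pair_count_and_holm_monotonicity(self):
        rng = np.random.default_rng(21)
        values = pd.DataFrame(rng.dirichlet(np.ones(4), size=20) * 1000.0)
        groups = np.repeat(["a", "b", "c", "d"], 5)
        out = st.pairwise_permanova(
            st.bray_curtis(values), groups, n_permutations=99, seed=0
        )
        assert len(out) == 6  # C(4,2)
        assert (out["p_adjusted"] >= out["p_value"] - 1e-12).all()

    def test_null_groups_not_flagged(self):
        rng = np.random.default_rng(22)
        values = pd.DataFrame(rng.dirichlet(np.ones(5), size=24) * 1000.0)
        groups = np.repeat(["a", "b", "c"], 8)
        out = st.pairwise_permanova(
            st.bray_curtis(values), groups, n_permutations=199, seed=1
        )
        assert (out["p_adjusted"] > 0.05).all()

    def test_needs_three_levels(self):
        with pytest.raises(ValueError, match="three"):
            st.pairwise_permanova(
                euclidean_frame(np.arange(4.0)), ["a", "a", "b", "b"]
            )


class TestSimper:
    def test_single_differing_sterol_takes_all(self):
        values = pd.DataFrame(
            [[500.0, 500.0], [500.0, 500.0], [800.0, 500.0], [800.0, 500.0]],
            columns=["x", "y"],
        )
        res = st.simper(values, ["A", "A", "B", "B"], "A", "B")
        assert res.table.loc["x", "percent"] == pytest.approx(100.0)
        assert res.table.loc["y", "percent"] == pytest.approx(0.0)

    def test_contributions_sum_to_mean_cross_group_distance(self):
        rng = np.random.default_rng(31)
        values = pd.DataFrame(rng.dirichlet(np.ones(8), size=14) * 1000.0)
        groups = ["A"] * 6 + ["B"] * 8
        res = st.simper(values, groups, "A", "B")
        d = st.bray_curtis(values)
        cross = d.iloc[:6, 6:].to_numpy().mean()
        assert res.mean_dissimilarity == pytest.approx(cross, abs=1e-9)
        assert res.table["percent"].sum() == pytest.approx(100.0, abs=1e-6)
        assert res.table["cumulative_percent"].is_monotonic_increasing

    def test_two_by_two_toy_against_enumeration(self):
        a = np.array([[700.0, 300.0], [650.0, 350.0]])
        b = np.array([[300.0, 700.0], [350.0, 650.0]])
        values = pd.DataFrame(np.vstack([a, b]), columns=["s1", "s2"])
        res = st.simper(values, ["A", "A", "B", "B"], "A", "B")
        contrib = np.zeros(2)
        for x in a:
            for y in b:
                contrib += np.abs(x - y) / (x + y).sum()
        contrib /= 4
        np.testing.assert_allclose(
            res.table.loc[["s1", "s2"], "contribution"], contrib, atol=1e-12
        )

    def test_empty_group_rejected(self):
        values = pd.DataFrame([[1.0, 2.0]])
        with pytest.raises(ValueError, match="empty"):
            st.simper(values, ["A"], "A", "B")


class TestPca:
    def test_rank_one_data(self):
        t = np.linspace(0, 1, 8)
        values = pd.DataFrame(np.outer(t, [3.0, -1.0, 2.0]))
        res = st.pca(values)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_two_variable_analytic_eigenvectors(self):
        rng = np.random.default_rng(41)
        x = rng.normal(size=200)
        values = pd.DataFrame({"u": 3 * x, "v": x + rng.normal(0, 0.1, 200)})
        res = st.pca(values)
        cov = np.cov(values.T)
        eigvals, eigvecs = np.linalg.eigh(cov)
        lead = eigvecs[:, np.argmax(eigvals)]
        lead = lead if lead[np.argmax(np.abs(lead))] > 0 else -lead
        np.testing.assert_allclose(res.loadings["PC1"], lead, atol=1e-10)

    def test_total_variance_preserved(self):
        rng = np.random.default_rng(42)
        values = pd.DataFrame(rng.normal(size=(30, 5)))
        res = st.pca(values)
        assert res.explained_variance.sum() == pytest.approx(
            values.var(ddof=1).sum()
        )
        assert np.all(np.diff(res.explained_variance_ratio) <= 1e-12)

    def test_loadings_orthonormal_and_sign_convention(self):
        rng = np.random.default_rng(43)
        values = pd.DataFrame(rng.dirichlet(np.ones(6), size=25) * 1000.0)
        res = st.pca(values)
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)
        for j in range(L.shape[1]):
            assert L[np.argmax(np.abs(L[:, j])), j] > 0

    def test_matches_reference_implementation(self):
        sklearn = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(44)
        values = pd.DataFrame(rng.normal(size=(20, 4)))
        res = st.pca(values, n_components=3)
        ref = sklearn.PCA(n_components=3).fit(values.to_numpy())
        np.testing.assert_allclose(
            np.abs(res.loadings.to_numpy().T), np.abs(ref.components_), atol=1e-8
        )
        np.testing.assert_allclose(
            res.explained_variance_ratio, ref.explained_variance_ratio_, atol=1e-10
        )

    def test_constant_matrix_has_zero_explained_variance(self):
        values = pd.DataFrame(np.full((5, 3), 7.0))
        res = st.pca(values)
        assert np.all(res.explained_variance_ratio == 0)

    def test_needs_two_samples(self):
        with pytest.raises(ValueError, match="two samples"):
            st.pca(pd.DataFrame([[1.0, 2.0]]))
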