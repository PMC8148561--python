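"""Clustering, ordination, Mantel, discriminant and MANOVA checks against
independent oracles (scipy statistics, density evaluation, null simulation)."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from droughtscreen import group_validation as gv


def line_points(values):
    return pd.DataFrame({"x": values}, index=[f"p{i}" for i in range(len(values))])


class TestDistances:
    def test_three_four_five(self):
        scores = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=["a", "b"])
        d = gv.euclidean_distances(scores)
        assert d.loc["a", "b"] == pytest.approx(5.0)
        assert d.loc["a", "a"] == 0.0

    def test_matches_double_loop_oracle(self, rng):
        scores = pd.DataFrame(rng.normal(size=(5, 3)))
        d = gv.euclidean_distances(scores)
        for i in range(5):
            for j in range(5):
                expect = np.sqrt(
                    sum(
                        (scores.iloc[i, k] - scores.iloc[j, k]) ** 2
                        for k in range(3)
                    )
                )
                assert d.iloc[i, j] == pytest.approx(expect, abs=1e-12)

    def test_missing_values_rejected(self):
        scores = pd.DataFrame([[0.0, np.nan], [1.0, 2.0]])
        with pytest.raises(ValueError, match="non-finite"):
            gv.euclidean_distances(scores)


class TestClustering:
    def test_two_separated_clouds(self, rng):
        a = rng.normal(size=(6, 2)) * 0.2
        b = rng.normal(size=(6, 2)) * 0.2 + 50
        scores = pd.DataFrame(np.vstack([a, b]))
        d = gv.euclidean_distances(scores)
        for method in ("ward", "upgma"):
            dend = gv.hierarchical_cluster(d, method=method, k=2)
            left = set(dend.assignments.iloc[:6])
            right = set(dend.assignments.iloc[6:])
            assert len(left) == len(right) == 1 and left != right

    def test_upgma_line_split(self):
        d = gv.euclidean_distances(line_points([0.0, 1.0, 10.0, 11.0]))
        dend = gv.hierarchical_cluster(d, method="upgma", k=2)
        assert dend.assignments["p0"] == dend.assignments["p1"]
        assert dend.assignments["p2"] == dend.assignments["p3"]
        assert dend.assignments["p0"] != dend.assignments["p2"]

    def test_upgma_merge_heights_hand_computed(self):
        # points 0,2,10,13,30,31: successive average-linkage heights
        d = gv.euclidean_distances(line_points([0.0, 2.0, 10.0, 13.0, 30.0, 31.0]))
        dend = gv.hierarchical_cluster(d, method="upgma")
        assert np.allclose(sorted(dend.merge_heights), [1.0, 2.0, 3.0, 10.5, 24.25])

    def test_merge_heights_monotone(self, rng):
        scores = pd.DataFrame(rng.normal(size=(12, 3)))
        d = gv.euclidean_distances(scores)
        for method in ("ward", "upgma"):
            h = gv.hierarchical_cluster(d, method=method).merge_heights
            assert (np.diff(h) >= -1e-12).all()

    def test_cut_produces_exactly_k_groups(self, rng):
        d = gv.euclidean_distances(pd.DataFrame(rng.normal(size=(10, 2))))
        for k in (1, 3, 5, 10):
            dend = gv.hierarchical_cluster(d, method="ward", k=k)
            assert dend.assignments.nunique() == k

    def test_invalid_linkage_rejected(self, rng):
        d = gv.euclidean_distances(pd.DataFrame(rng.normal(size=(4, 2))))
        with pytest.raises(ValueError, match="linkage"):
            gv.hierarchical_cluster(d, method="complete")

    def test_newick_round_trips_leaf_names(self, rng):
        scores = pd.DataFrame(
            rng.normal(size=(5, 2)), index=[f"G{i}" for i in range(5)]
        )
        dend = gv.hierarchical_cluster(gv.euclidean_distances(scores), "upgma")
        nwk = dend.to_newick()
        assert nwk.endswith(";")
        for label in scores.index:
            assert label in nwk


class TestPcoa:
    def test_two_points(self):
        d = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=["a", "b"], columns=["a", "b"])
        coords, explained = gv.pcoa(d)
        assert np.allclose(np.abs(coords.iloc[:, 0]), 0.5)
        assert explained[0] == pytest.approx(100.0)

    def test_recovers_planar_configuration(self, rng):
        from scipy.spatial import procrustes

        x = rng.normal(size=(8, 2))
        d = gv.euclidean_distances(pd.DataFrame(x))
        coords, explained = gv.pcoa(d)
        _, _, disparity = procrustes(x, coords.to_numpy()[:, :2])
        assert disparity == pytest.approx(0.0, abs=1e-12)
        assert explained.sum() == pytest.approx(100.0)

    def test_eigenvalues_match_centered_pca(self, rng):
        """PCoA of Euclidean distances == PCA of the centered data matrix."""
        x = rng.normal(size=(10, 4))
        d = gv.euclidean_distances(pd.DataFrame(x))
        coords, explained = gv.pcoa(d)
        xc = x - x.mean(axis=0)
        sv = np.linalg.svd(xc, compute_uv=False)
        pca_eigs = sv**2  # eigenvalues of Xc Xc'
        pcoa_eigs = (coords.to_numpy() ** 2).sum(axis=0)
        assert np.allclose(
            np.sort(pcoa_eigs)[::-1][: len(pca_eigs)],
            np.sort(pca_eigs)[::-1][: pcoa_eigs.size],
            atol=1e-8,
        )

    def test_all_zero_distances_rejected(self):
        d = pd.DataFrame(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="zero"):
            gv.pcoa(d)


class TestMantel:
    def test_self_correlation_is_one(self, rng):
        d = gv.euclidean_distances(pd.DataFrame(rng.normal(size=(8, 3))))
        r, p = gv.mantel_test(d, d, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p >= 1 / 100

    def test_affine_transform_preserves_r(self, rng):
        d = gv.euclidean_distances(pd.DataFrame(rng.normal(size=(8, 3))))
        d2 = 3.0 * d + 1.0
        np.fill_diagonal(d2.values, 0.0)
        r, _ = gv.mantel_test(d, d2, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_null_type_one_error_calibrated(self):
        """Rejection rate at alpha=0.05 within 0.05 +/- 0.02 over 500 null sims."""
        rng = np.random.default_rng(123)
        rejections = 0
        n_sims = 500
        for _ in range(n_sims):
            x1 = pd.DataFrame(rng.normal(size=(10, 3)))
            x2 = pd.DataFrame(rng.normal(size=(10, 3)))
            d1 = gv.euclidean_distances(x1)
            d2 = gv.euclidean_distances(x2)
            _, p = gv.mantel_test(d1, d2, n_perm=99, seed=int(rng.integers(2**31)))
            rejections += p <= 0.05
        assert abs(rejections / n_sims - 0.05) <= 0.02

    def test_statistic_matches_scikit_bio(self, rng):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        x1 = pd.DataFrame(rng.normal(size=(9, 3)))
        x2 = x1 + rng.normal(size=(9, 3)) * 0.5
        d1 = gv.euclidean_distances(x1)
        d2 = gv.euclidean_distances(x2)
        r, _ = gv.mantel_test(d1, d2, n_perm=99, seed=0)
        ref_r, _, _ = skbio_distance.mantel(
            skbio_distance.DistanceMatrix(d1.to_numpy()),
            skbio_distance.DistanceMatrix(d2.to_numpy()),
            permutations=0,
        )
        assert r == pytest.approx(ref_r, abs=1e-10)

    def test_constant_matrix_rejected(self):
        d1 = pd.DataFrame(1.0 - np.eye(5))
        np.fill_diagonal(d1.values, 0)
        d2 = d1.copy()
        with pytest.raises(ValueError, match="constant"):
            gv.mantel_test(d1, d2, n_perm=9)


class TestCanonicalDiscriminant:
    def test_identical_group_means_zero_eigenvalues(self, rng):
        base = rng.normal(size=(6, 2))
        scores = pd.DataFrame(np.vstack([base, base]), columns=["a", "b"])
        groups = pd.Series(["x"] * 6 + ["y"] * 6, index=scores.index)
        model = gv.canonical_discriminant(scores, groups)
        assert np.allclose(model.eigenvalues, 0.0, atol=1e-10)

    def test_single_trait_relates_to_t_statistic(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(size=12) + 1.5
        scores = pd.DataFrame({"t": np.concatenate([a, b])})
        groups = pd.Series(["a"] * 12 + ["b"] * 12, index=scores.index)
        model = gv.canonical_discriminant(scores, groups)
        t_stat, _ = stats.ttest_ind(a, b)
        # single-trait eigenvalue = SSB/SSW = t^2 / (n - 2)
        assert model.eigenvalues[0] == pytest.approx(t_stat**2 / 22, rel=1e-9)

    def test_collinear_centroids_single_function(self, rng):
        centers = {"a": [0, 0], "b": [2, 2], "c": [4, 4]}
        rows, labels = [], []
        for lab, c in centers.items():
            rows.append(rng.normal(size=(8, 2)) * 0.1 + np.array(c))
            labels += [lab] * 8
        scores = pd.DataFrame(np.vstack(rows), columns=["x", "y"])
        model = gv.canonical_discriminant(scores, pd.Series(labels, index=scores.index))
        assert model.explained_pct[0] == pytest.approx(100.0, abs=0.5)

    def test_small_groups_rejected(self, rng):
        scores = pd.DataFrame(rng.normal(size=(3, 2)))
        groups = pd.Series(["a", "a", "b"], index=scores.index)
        with pytest.raises(ValueError, match="members"):
            gv.canonical_discriminant(scores, groups)


class TestBoxMAndClassification:
    def test_homogeneous_covariances_choose_lda(self, rng, grouped_gaussians):
        scores, groups = grouped_gaussians
        model = gv.box_m_and_classify(scores, groups)
        assert model.box_m_p > 0.05
        assert model.classifier == "lda"

    def test_separated_groups_zero_resubstitution_error(self, grouped_gaussians):
        scores, groups = grouped_gaussians
        model = gv.box_m_and_classify(scores, groups)
        assert model.resubstitution_error_pct == 0.0

    def test_heterogeneous_covariances_choose_qda(self, rng):
        a = rng.normal(size=(40, 2)) * 0.2
        b = rng.normal(size=(40, 2)) * 4.0 + 1
        scores = pd.DataFrame(np.vstack([a, b]), columns=["x", "y"])
        groups = pd.Series(["a"] * 40 + ["b"] * 40, index=scores.index)
        model = gv.box_m_and_classify(scores, groups)
        assert model.box_m_p < 0.05
        assert model.classifier == "qda"

    def test_box_m_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = rng.normal(size=(30, 2))
        x[15:] = x[15:] * 2 + 1
        data = pd.DataFrame(x, columns=["u", "v"])
        data["grp"] = ["a"] * 15 + ["b"] * 15
        expected = pingouin.box_m(data, dvs=["u", "v"], group="grp")
        chi2, df, p = gv.box_m(data[["u", "v"]], data["grp"])
        assert chi2 == pytest.approx(float(expected["Chi2"].iloc[0]), rel=1e-6)
        assert p == pytest.approx(float(expected["pval"].iloc[0]), rel=1e-6)

    def test_classifier_matches_scikit_learn(self, rng, grouped_gaussians):
        sklearn_da = pytest.importorskip("sklearn.discriminant_analysis")
        scores, groups = grouped_gaussians
        model = gv.box_m_and_classify(scores, groups)
        if model.classifier == "lda":
            ref = sklearn_da.LinearDiscriminantAnalysis(priors=[1 / 3] * 3)
        else:
            ref = sklearn_da.QuadraticDiscriminantAnalysis(priors=[1 / 3] * 3)
        ref.fit(scores.to_numpy(), groups.to_numpy())
        assert (model.predictions.to_numpy() == ref.predict(scores.to_numpy())).all()

    def test_decisions_match_density_oracle(self, rng):
        """Classifier equals argmax of scipy multivariate-normal log-pdfs."""
        a = rng.normal(size=(5, 2)) + [0, 0]
        b = rng.normal(size=(5, 2)) + [2.5, 1.0]
        scores = pd.DataFrame(np.vstack([a, b]), columns=["x", "y"])
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=scores.index)
        model = gv.box_m_and_classify(scores, groups)

        mu = {g: scores[groups == g].mean().to_numpy() for g in ("a", "b")}
        if model.classifier == "qda":
            cov = {g: np.cov(scores[groups == g], rowvar=False) for g in ("a", "b")}
        else:
            w, _, _, sizes = gv._sscp(scores, groups)
            pooled = w / (len(scores) - 2)
            cov = {"a": pooled, "b": pooled}
        for idx in scores.index:
            x = scores.loc[idx].to_numpy()
            ll = {
                g: stats.multivariate_normal.logpdf(x, mu[g], cov[g])
                for g in ("a", "b")
            }
            assert model.predictions[idx] == max(ll, key=ll.get)


class TestManova:
    def test_single_trait_equals_oneway_anova_f(self, rng):
        groups_data = [rng.normal(size=10) + shift for shift in (0, 0.5, 1.5)]
        scores = pd.DataFrame({"t": np.concatenate(groups_data)})
        groups = pd.Series(
            ["a"] * 10 + ["b"] * 10 + ["c"] * 10, index=scores.index
        )
        res = gv.manova(scores, groups)
        f_expect, p_expect = stats.f_oneway(*groups_data)
        assert res.f_stat == pytest.approx(f_expect, rel=1e-9)
        assert res.p_value == pytest.approx(p_expect, rel=1e-9)

    def test_identical_group_means_lambda_one(self, rng):
        base = rng.normal(size=(8, 2))
        scores = pd.DataFrame(np.vstack([base, base]), columns=["a", "b"])
        groups = pd.Series(["x"] * 8 + ["y"] * 8, index=scores.index)
        res = gv.manova(scores, groups)
        assert res.wilks_lambda == pytest.approx(1.0, abs=1e-10)

    def test_lambda_product_identity_with_canonical_eigenvalues(
        self, grouped_gaussians
    ):
        scores, groups = grouped_gaussians
        res = gv.manova(scores, groups)
        model = gv.canonical_discriminant(scores, groups)
        expect = np.prod(1.0 / (1.0 + model.eigenvalues))
        assert res.wilks_lambda == pytest.approx(expect, rel=1e-9)

    def test_matches_statsmodels_wilks(self, grouped_gaussians):
        from statsmodels.multivariate.manova import MANOVA

        scores, groups = grouped_gaussians
        res = gv.manova(scores, groups)
        frame = scores.copy()
        frame["grp"] = groups
        sm_res = MANOVA.from_formula("t1 + t2 ~ C(grp)", data=frame)
        table = sm_res.mv_test().results["C(grp)"]["stat"]
        assert res.wilks_lambda == pytest.approx(
            float(table.loc["Wilks' lambda", "Value"]), rel=1e-9
        )

    def test_null_type_one_error_calibrated(self):
        """Wilks p-values reject at ~alpha under the null (500 sims)."""
        rng = np.random.default_rng(77)
        rejections = 0
        n_sims = 500
        for _ in range(n_sims):
            scores = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
            groups = pd.Series(["a"] * 10 + ["b"] * 10 + ["c"] * 10,
                               index=scores.index)
            rejections += gv.manova(scores, groups).p_value <= 0.05
        assert abs(rejections / n_sims - 0.05) <= 0.025

    def test_pairwise_contrasts_reported(self, grouped_gaussians):
        scores, groups = grouped_gaussians
        res = gv.manova(scores, groups)
        assert set(res.pairwise["trait"]) == {"t1", "t2"}
        # centers: g0=(0,0), g1=(8,0), g2=(0,8) -- contrasts along the axis
        # where the centers differ must be significant, coincident ones not
        pw = res.pairwise.set_index(["trait", "group_a", "group_b"])
        assert pw.loc[("t1", "g0", "g1"), "significant"]
        assert pw.loc[("t2", "g0", "g2"), "significant"]
        assert not pw.loc[("t1", "g0", "g2"), "significant"]
        assert res.ls_means.shape == (3, 2)
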