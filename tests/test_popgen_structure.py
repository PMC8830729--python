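"""Relatedness, PCA, admixture EM/CV, cluster assignment, F_ST, MAF tests."""

import numpy as np
import pandas as pd
import pytest

from migragen.popgen import (
    AdmixtureModel,
    align_q_columns,
    assign_clusters,
    compute_grm,
    cross_validate_k,
    fit_admixture,
    fst_between,
    maf_by_cluster,
    pca,
)
from migragen.simulate import (
    simulate_ancestral_freqs,
    simulate_admixture_q,
    simulate_genotypes,
)
from conftest import make_genotype_matrix, two_population_genotypes


class TestGRM:
    def test_hand_example(self):
        # g = [[0,2],[1,1],[2,0]]: f = 0.5 at both loci, X = g - 1,
        # denominator sum(2 f (1-f)) = 1 -> K = X X^T
        gm = make_genotype_matrix([[0, 2], [1, 1], [2, 0]])
        k = compute_grm(gm)
        np.testing.assert_allclose(
            k, [[2.0, 0.0, -2.0], [0.0, 0.0, 0.0], [-2.0, 0.0, 2.0]], atol=1e-12
        )

    def test_identical_individuals_share_rows(self):
        rng = np.random.default_rng(0)
        g = rng.binomial(2, 0.4, size=(4, 200)).astype(float)
        g[1] = g[0]
        k = compute_grm(make_genotype_matrix(g))
        np.testing.assert_allclose(k[0], k[1], atol=1e-12)
        assert k[0, 0] == pytest.approx(k[0, 1], abs=1e-12)

    def test_diagonal_mean_near_one_under_hwe(self):
        rng = np.random.default_rng(1)
        f = rng.uniform(0.1, 0.9, size=5000)
        g = rng.binomial(2, f, size=(200, 5000)).astype(float)
        k = compute_grm(make_genotype_matrix(g))
        assert np.diag(k).mean() == pytest.approx(1.0, abs=0.03)

    def test_psd_and_symmetric(self):
        rng = np.random.default_rng(2)
        g = rng.binomial(2, 0.3, size=(50, 500)).astype(float)
        k = compute_grm(make_genotype_matrix(g))
        np.testing.assert_allclose(k, k.T, atol=1e-10)
        assert np.linalg.eigvalsh(k).min() > -1e-8


class TestPCA:
    def test_two_populations_separate_on_pc1(self):
        gm, labels = two_population_genotypes(n_per_group=60, m=2000, fst=0.2,
                                              seed=3)
        vecs, vals = pca(gm)
        signs = vecs[:, 0] > np.median(vecs[:, 0])
        purity = max((signs == labels.astype(bool)).mean(),
                     (signs != labels.astype(bool)).mean())
        assert purity > 0.99

    def test_eigenvalues_non_increasing(self):
        gm, _ = two_population_genotypes(n_per_group=30, m=500, fst=0.1, seed=4)
        _, vals = pca(gm)
        assert np.all(np.diff(vals) <= 1e-9)

    def test_scree_gap_matches_cluster_count(self):
        # K=3 discrete clusters: two dominant axes then a sharp drop
        freqs = simulate_ancestral_freqs(3000, 3, 0.2, seed=5)
        q = np.zeros((90, 3))
        for k in range(3):
            q[30 * k:30 * (k + 1), k] = 1.0
        g = simulate_genotypes(freqs, q, seed=6).astype(float)
        _, vals = pca(make_genotype_matrix(g))
        assert vals[1] / vals[2] > 5.0


class TestAdmixture:
    def test_k1_closed_form(self):
        rng = np.random.default_rng(7)
        g = rng.binomial(2, 0.4, size=(30, 200)).astype(float)
        res = AdmixtureModel(g, 1).fit()
        np.testing.assert_allclose(res.q, 1.0)
        np.testing.assert_allclose(res.f[0], g.mean(axis=0) / 2.0, atol=1e-9)
        # closed-form binomial log-likelihood at the MLE
        p = np.clip(g.mean(axis=0) / 2.0, 1e-6, 1 - 1e-6)
        ll = (g * np.log(p) + (2 - g) * np.log1p(-p)).sum()
        assert res.loglik == pytest.approx(ll, rel=1e-5)

    def test_fixed_differences_recover_labels_exactly(self):
        m = 300
        freqs = np.vstack([np.full(m, 0.02), np.full(m, 0.98)])
        q = np.zeros((40, 2))
        q[:20, 0] = 1.0
        q[20:, 1] = 1.0
        g = simulate_genotypes(freqs, q, seed=8).astype(float)
        res = AdmixtureModel(g, 2).fit(seed=0, n_restarts=2, tol=1e-6,
                                       max_iter=500)
        qa = align_q_columns(res.q, q)
        labels = qa.argmax(axis=1)
        assert (labels == q.argmax(axis=1)).all()
        assert np.abs(qa - q).mean() < 0.02

    def test_loglik_path_monotone(self):
        gm, _ = two_population_genotypes(n_per_group=25, m=400, fst=0.1, seed=9)
        res = AdmixtureModel(gm.g, 2).fit(seed=1, n_restarts=1, tol=1e-6,
                                          max_iter=300, check_every=5)
        assert np.all(np.diff(res.loglik_path) >= -1e-3)

    def test_missing_entries_supported(self):
        gm, _ = two_population_genotypes(n_per_group=20, m=300, fst=0.2, seed=10)
        g = gm.g.copy()
        rng = np.random.default_rng(11)
        g[rng.uniform(size=g.shape) < 0.1] = np.nan
        res = AdmixtureModel(g, 2).fit(seed=2, n_restarts=1, max_iter=300,
                                       tol=1e-4)
        assert np.isfinite(res.loglik)
        np.testing.assert_allclose(res.q.sum(axis=1), 1.0, atol=1e-6)


class TestCrossValidation:
    def test_masking_fraction_respected(self):
        rng = np.random.default_rng(12)
        g = rng.binomial(2, 0.5, size=(20, 100)).astype(float)
        obs = (~np.isnan(g)).sum()
        perm = np.random.default_rng(0).permutation(obs)
        parts = np.array_split(perm, 5)
        assert all(abs(len(p) - obs / 5) <= 1 for p in parts)

    def test_panmictic_data_prefers_k1(self):
        rng = np.random.default_rng(13)
        g = rng.binomial(2, rng.uniform(0.2, 0.8, 600), size=(60, 600)).astype(float)
        cv, selected = cross_validate_k(g, [1, 2], folds=5, seed=3,
                                        n_restarts=1, tol=1e-3, max_iter=200)
        assert selected == 1

    def test_structured_data_prefers_k2(self):
        gm, _ = two_population_genotypes(n_per_group=40, m=800, fst=0.15, seed=14)
        cv, selected = cross_validate_k(gm.g, [1, 2, 3], folds=5, seed=4,
                                        n_restarts=1, tol=1e-3, max_iter=200)
        assert selected == 2


class TestClusterAssignment:
    def test_argmax_and_ties(self):
        q = np.array([[0.9, 0.1], [0.5, 0.5], [0.2, 0.8]])
        labels, max_q, ties = assign_clusters(q)
        np.testing.assert_array_equal(labels, [0, 0, 1])
        assert ties[1] and not ties[0] and not ties[2]
        np.testing.assert_allclose(max_q, [0.9, 0.5, 0.8])

    def test_per_cluster_mean_q_matches_group_means(self):
        rng = np.random.default_rng(15)
        q1 = rng.uniform(size=50)
        q = np.column_stack([q1, 1 - q1])
        labels, _, _ = assign_clusters(q)
        for k in (0, 1):
            expected = q[labels == k, k].mean()
            assert expected == pytest.approx(
                np.mean([q[i, k] for i in range(50) if labels[i] == k]))


class TestFst:
    def test_null_split_of_one_population_near_zero(self):
        rng = np.random.default_rng(16)
        f = rng.uniform(0.1, 0.9, size=10_000)
        g = rng.binomial(2, f, size=(200, 10_000)).astype(float)
        labels = np.repeat([0, 1], 100)
        res = fst_between(make_genotype_matrix(g), labels, n_boot=200, seed=0)
        assert abs(res.estimate) < 0.005
        assert res.ci_low <= res.estimate <= res.ci_high

    def test_fully_fixed_differences_give_one(self):
        g = np.zeros((40, 50))
        g[20:, :] = 2.0
        labels = np.repeat([0, 1], 20)
        res = fst_between(make_genotype_matrix(g), labels, n_boot=100, seed=1)
        assert res.estimate == pytest.approx(1.0, abs=1e-9)

    def test_small_group_rejected(self):
        gm = make_genotype_matrix(np.ones((3, 10)))
        with pytest.raises(ValueError, match="< 2"):
            fst_between(gm, np.array([0, 1, 1]))


class TestMafByCluster:
    def test_identical_clusters_all_ties_p_one(self):
        g = np.tile([0.0, 1.0, 2.0, 1.0], (20, 5)).T[:20].T
        g = np.tile(np.array([[0, 1, 2, 1, 0]] * 20, dtype=float), (1, 1))
        labels = np.repeat([0, 1], 10)
        freq, kw_p, pw = maf_by_cluster(make_genotype_matrix(g), labels,
                                        np.arange(5))
        assert kw_p == 1.0
        assert pw.iloc[0, 1] == 1.0

    def test_shifted_frequencies_detected(self):
        rng = np.random.default_rng(17)
        m = 50
        f0 = rng.uniform(0.1, 0.3, size=m)
        g_a = rng.binomial(2, f0, size=(100, m)).astype(float)
        g_b = rng.binomial(2, f0 + 0.2, size=(100, m)).astype(float)
        g = np.vstack([g_a, g_b])
        labels = np.repeat([0, 1], 100)
        freq, kw_p, pw = maf_by_cluster(make_genotype_matrix(g), labels,
                                        np.arange(m))
        assert kw_p < 0.001
        assert pw.iloc[0, 1] < 0.001

    def test_two_group_kruskal_equals_wilcoxon_squared(self):
        # chi2(z^2, 1) identity between the two rank tests, tie-free data
        from scipy import stats

        rng = np.random.default_rng(18)
        a, b = rng.normal(size=30), rng.normal(0.5, 1, size=30)
        kw = stats.kruskal(a, b)
        mw = stats.mannwhitneyu(a, b, alternative="two-sided",
                                method="asymptotic", use_continuity=False)
        assert kw.pvalue == pytest.approx(mw.pvalue, abs=1e-6)
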