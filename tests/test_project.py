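"""NNLS and PCA projection: exactness, KKT optimality, permutation test."""

import itertools

import numpy as np
import pytest
from scipy.stats import pearsonr, spearmanr

from stempatterns import (ExpressionStudy, SampleMeta, SimulationConfig,
                          StudyError, pca_fit, pca_project, project_nnls,
                          projection_permutation_test, simulate_study)
from stempatterns.decompose import PatternDecomposition
from stempatterns.simulate import truth_decomposition


def make_decomp(A, intercept=None):
    A = np.asarray(A, float)
    K = A.shape[1]
    return PatternDecomposition(
        A=A, P=np.ones((K, 3)), K=K,
        gene_ids=[f"g{i}" for i in range(A.shape[0])],
        sample_ids=["s0", "s1", "s2"],
        row_scaling=np.ones(A.shape[0]), objective_trace=[0.0],
        restart_stability=np.ones(K), seed=0, intercept=intercept)


def make_new_study(values, gene_ids):
    values = np.asarray(values, float)
    samples = [SampleMeta(f"n{j}", f"X{j}", f"X{j}", "other", 0)
               for j in range(values.shape[1])]
    return ExpressionStudy(values, gene_ids, samples, scale="other")


def brute_force_nnls(A, x, grid=120):
    """Exhaustive support-enumeration NNLS oracle for tiny instances."""
    best = (np.inf, None)
    K = A.shape[1]
    for r in range(K + 1):
        for support in itertools.combinations(range(K), r):
            sub = A[:, list(support)]
            if support:
                w_s, *_ = np.linalg.lstsq(sub, x, rcond=None)
                if np.any(w_s < -1e-12):
                    continue
            else:
                w_s = np.zeros(0)
            w = np.zeros(K)
            w[list(support)] = np.clip(w_s, 0, None)
            err = float(np.linalg.norm(x - A @ w) ** 2)
            if err < best[0] - 1e-15:
                best = (err, w)
    return best[1]


class TestProjectNnls:
    def test_basis_vector_recovery(self):
        rng = np.random.default_rng(0)
        A = rng.random((60, 4)) + 0.05
        d = make_decomp(A)
        new = make_new_study(3.0 * A[:, [2]], d.gene_ids)
        res = project_nnls(d, new)
        w = res.weights[:, 0]
        assert w[2] == pytest.approx(3.0, rel=1e-6)
        assert np.all(np.delete(w, 2) < 1e-8)

    def test_self_projection_recovers_weights(self):
        """Projecting the noiseless training matrix returns its P columns."""
        cfg = SimulationConfig(seed=4, n_genes=400, noise_sigma=0.0)
        study, truth = simulate_study(cfg)
        d = truth_decomposition(truth, study)
        res = project_nnls(d, ExpressionStudy(
            study.values, study.gene_ids, study.samples, scale="other"))
        for j in range(study.n_samples):
            r, _ = pearsonr(res.weights[:, j], truth.P_true[:, j])
            assert r >= 0.99

    def test_matches_brute_force_kkt_oracle_on_tiny_instances(self):
        rng = np.random.default_rng(7)
        for trial in range(20):
            A = rng.random((5, 2)) + 0.05
            x = rng.standard_normal(5) + 1.0
            d = make_decomp(A)
            res = project_nnls(d, make_new_study(x[:, None], d.gene_ids),
                               min_genes=1)
            w_oracle = brute_force_nnls(A, x)
            np.testing.assert_allclose(res.weights[:, 0], w_oracle,
                                       atol=1e-6)

    def test_kkt_conditions_hold(self, truth_decomp, default_study):
        study, truth = default_study
        from stempatterns import simulate_external_dataset
        from stempatterns.project import _matched_arrays, _project_matrix

        ext = simulate_external_dataset(truth, "tissue-like", 6, seed=9)
        A, X = _matched_arrays(truth_decomp, ext, 50, False)
        W, _ = _project_matrix(A, X)
        for j in range(X.shape[1]):
            grad = A.T @ (A @ W[:, j] - X[:, j])
            assert np.all(grad >= -1e-6 * np.abs(X[:, j]).max())
            active = W[:, j] > 1e-10
            assert np.all(np.abs(grad[active]) < 1e-6 * max(
                1.0, np.abs(A.T @ X[:, j]).max()))

    def test_equivariant_to_gene_reordering(self):
        rng = np.random.default_rng(1)
        A = rng.random((40, 3))
        x = rng.random((40, 2)) + 0.1
        d = make_decomp(A)
        res = project_nnls(d, make_new_study(x, d.gene_ids), min_genes=10)
        perm = rng.permutation(40)
        d2 = make_decomp(A[perm])
        d2 = PatternDecomposition(
            A=A[perm], P=d.P, K=3,
            gene_ids=[d.gene_ids[i] for i in perm], sample_ids=d.sample_ids,
            row_scaling=np.ones(40), objective_trace=[0.0],
            restart_stability=np.ones(3), seed=0)
        res2 = project_nnls(d2, make_new_study(x[perm],
                                               [d.gene_ids[i] for i in perm]),
                            min_genes=10)
        np.testing.assert_allclose(res.weights, res2.weights, atol=1e-9)

    def test_intersection_threshold_enforced(self):
        d = make_decomp(np.random.default_rng(0).random((20, 2)))
        new = make_new_study(np.ones((20, 1)), d.gene_ids)
        with pytest.raises(StudyError, match="below threshold"):
            project_nnls(d, new, min_genes=100)

    def test_all_zero_sample_rejected(self):
        d = make_decomp(np.random.default_rng(0).random((20, 2)))
        new = make_new_study(np.zeros((20, 1)), d.gene_ids)
        with pytest.raises(StudyError, match="all-zero"):
            project_nnls(d, new, min_genes=5)


class TestPermutationTest:
    def test_p_floor(self, truth_decomp, default_study):
        from stempatterns import simulate_external_dataset

        _, truth = default_study
        ext = simulate_external_dataset(truth, "tissue-like", 8, seed=0)
        focal = [s.donor_id == "D1" for s in ext.samples]
        with pytest.warns(UserWarning, match="n_perm"):
            res = projection_permutation_test(
                truth_decomp, ext, focal, 0, n_perm=19, seed=0,
                row_zscore=True)
        assert res.p_perm >= 1 / 20
        assert res.p_perm <= 1.0

    def test_planted_donor_signature_detected(self, truth_decomp,
                                              default_study):
        from stempatterns import simulate_external_dataset

        _, truth = default_study
        donor_mod = truth.modules_of_class("donor")[0]
        ext = simulate_external_dataset(truth, "tissue-like", 12, seed=21)
        focal = [s.donor_id == "D1" for s in ext.samples]
        res = projection_permutation_test(
            truth_decomp, ext, focal, donor_mod, n_perm=199, seed=0,
            row_zscore=True)
        assert res.p_perm < 0.01

    def test_empty_focal_group_rejected(self, truth_decomp, default_study):
        from stempatterns import simulate_external_dataset

        _, truth = default_study
        ext = simulate_external_dataset(truth, "tissue-like", 4, seed=0)
        with pytest.raises(StudyError, match="focal"):
            projection_permutation_test(truth_decomp, ext, [False] * 4, 0,
                                        n_perm=100)


class TestPca:
    def test_single_varying_gene_dominates_pc1(self):
        X = np.full((10, 6), 2.0)
        X[3] = [0, 2, 4, 6, 8, 10]
        study = make_new_study(X, [f"g{i}" for i in range(10)])
        model, scores = pca_fit(study, 2)
        assert model.explained_variance_fraction[0] > 0.999

    def test_self_projection_equals_fit_scores(self, small_study):
        study, _ = small_study
        model, scores = pca_fit(study, 3)
        proj = pca_project(model, study)
        np.testing.assert_allclose(proj, scores, atol=1e-10)

    def test_offset_shifts_scores_linearly(self, small_study):
        study, _ = small_study
        model, scores = pca_fit(study, 2)
        offset = np.random.default_rng(0).random(study.n_genes)
        shifted = ExpressionStudy(study.values + offset[:, None],
                                  study.gene_ids, study.samples, study.scale)
        proj = pca_project(model, shifted)
        np.testing.assert_allclose(proj - scores,
                                   (model.loadings.T @ offset)[:, None]
                                   * np.ones((1, study.n_samples)),
                                   atol=1e-8)

    def test_planted_two_factor_subspace_angle(self):
        rng = np.random.default_rng(5)
        L = rng.random((300, 2))
        S = rng.standard_normal((2, 40))
        X = L @ S + 5.0 + 0.01 * rng.standard_normal((300, 40))
        study = make_new_study(np.clip(X, 0, None),
                               [f"g{i}" for i in range(300)])
        model, _ = pca_fit(study, 2)
        # principal angles between estimated and planted subspaces
        Q1, _ = np.linalg.qr(model.loadings)
        Q2, _ = np.linalg.qr(L)
        s = np.linalg.svd(Q1.T @ Q2, compute_uv=False)
        angles = np.degrees(np.arccos(np.clip(s, -1, 1)))
        assert angles.max() < 5.0

    def test_explained_fractions_non_increasing(self, small_study):
        study, _ = small_study
        model, _ = pca_fit(study, 4)
        frac = model.explained_variance_fraction
        assert np.all(np.diff(frac) <= 1e-12) and np.all(frac >= 0)

    def test_sr_projection_preserves_line_ranking(self, default_study):
        """Line ordering fit on one condition persists when projecting
        another, because line signatures are condition-invariant."""
        study, truth = default_study
        is_nsb = [s.condition == "NSB" for s in study.samples]
        is_sr = [s.condition == "SR" for s in study.samples]
        nsb = study.subset_samples(is_nsb)
        sr = study.subset_samples(is_sr)
        model, scores = pca_fit(nsb, 4)
        proj = pca_project(model, sr)
        lines = sorted({s.line_id for s in study.samples})

        def line_means(scores_mat, samples, c):
            return [np.mean([scores_mat[c, j] for j, s in enumerate(samples)
                             if s.line_id == l]) for l in lines]

        # pick the component with the strongest between-line separation
        ratios = []
        for c in range(4):
            means = line_means(scores, nsb.samples, c)
            ratios.append(np.var(means) / max(np.var(scores[c]), 1e-12))
        c = int(np.argmax(ratios))
        rho, _ = spearmanr(line_means(scores, nsb.samples, c),
                           line_means(proj, sr.samples, c))
        assert abs(rho) >= 0.8

    def test_too_many_components_rejected(self, tiny_study):
        with pytest.raises(StudyError):
            pca_fit(tiny_study, 4)


class TestLabelPermutationScheme:
    def test_label_scheme_detects_group_difference(self, truth_decomp,
                                                   default_study):
        from stempatterns import simulate_external_dataset

        _, truth = default_study
        donor_mod = truth.modules_of_class("donor")[0]
        # 48 samples cycle twice through the kinship panel: two focal
        # samples, enough label assignments for p below 0.05
        ext = simulate_external_dataset(truth, "tissue-like", 48, seed=33)
        focal = [s.donor_id == "D1" for s in ext.samples]
        res = projection_permutation_test(
            truth_decomp, ext, focal, donor_mod, n_perm=199, seed=0,
            row_zscore=True, scheme="labels")
        assert res.p_perm < 0.05

    def test_unknown_scheme_rejected(self, truth_decomp, default_study):
        from stempatterns import simulate_external_dataset

        _, truth = default_study
        ext = simulate_external_dataset(truth, "tissue-like", 4, seed=0)
        with pytest.raises(StudyError, match="scheme"):
            projection_permutation_test(truth_decomp, ext,
                                        [True, False, True, False], 0,
                                        n_perm=100, scheme="bogus")
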