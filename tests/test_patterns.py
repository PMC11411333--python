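"""Pattern classification, clustering, MDS embedding, score correlations."""

import numpy as np
import pandas as pd
import pytest

from stempatterns import (SampleMeta, SimulationConfig, StudyError,
                          classify_patterns, cluster_patterns,
                          correlate_weights_with_scores, mds_amplitudes,
                          simulate_study)
from stempatterns.decompose import PatternDecomposition
from stempatterns.simulate import truth_decomposition


def decomp_from_P(P, n_genes=40, A=None, seed=0, sample_ids=None):
    P = np.asarray(P, float)
    rng = np.random.default_rng(seed)
    if A is None:
        A = rng.random((n_genes, P.shape[0]))
    return PatternDecomposition(
        A=A, P=P, K=P.shape[0],
        gene_ids=[f"g{i}" for i in range(A.shape[0])],
        sample_ids=(list(sample_ids) if sample_ids is not None
                    else [f"s{j}" for j in range(P.shape[1])]),
        row_scaling=np.ones(A.shape[0]), objective_trace=[0.0],
        restart_stability=np.ones(P.shape[0]), seed=0)


@pytest.fixture(scope="module")
def design_meta():
    """6 lines x 3 conditions x 3 days grid (54 samples)."""
    cfg = SimulationConfig(n_genes=10)
    samples = []
    for line, donor in cfg.lines:
        for cond in cfg.conditions:
            for day in cfg.days:
                samples.append(SampleMeta(f"{line}_{cond}_{day}", line,
                                          donor, cond, day))
    return samples


class TestClassify:
    def _weights(self, samples, fn, noise=0.05, seed=0):
        rng = np.random.default_rng(seed)
        w = np.array([fn(s) for s in samples], float)
        return np.clip(w + noise * rng.standard_normal(len(w)), 0, None)

    def test_planted_line_module_labeled_with_owner(self, design_meta):
        w = self._weights(design_meta, lambda s: 1.0 if s.line_id == "L6"
                          else 0.0)
        d = decomp_from_P(np.vstack([w, np.linspace(0, 1, 54)]),
                          sample_ids=[s.sample_id for s in design_meta])
        cls = classify_patterns(d, design_meta)
        assert cls.patterns[0].label == "line-specific"
        assert cls.patterns[0].owner == "L6"

    def test_planted_donor_module_promoted(self, design_meta):
        w = self._weights(design_meta, lambda s: 1.0 if s.donor_id == "D1"
                          else 0.0)
        d = decomp_from_P(np.vstack([w, np.linspace(0, 1, 54)]),
                          sample_ids=[s.sample_id for s in design_meta])
        cls = classify_patterns(d, design_meta)
        assert cls.patterns[0].label == "donor-specific"
        assert cls.patterns[0].owner == "D1"

    def test_planted_pluripotency_decay_is_dynamic(self, design_meta):
        decay = {2: 1.0, 4: 0.5, 6: 0.2}
        w = self._weights(design_meta, lambda s: decay[s.day])
        d = decomp_from_P(np.vstack([w, np.linspace(0, 1, 54)]),
                          sample_ids=[s.sample_id for s in design_meta])
        cls = classify_patterns(d, design_meta)
        p = cls.patterns[0]
        assert p.label == "dynamic"
        assert p.eta2_day > max(p.eta2_line, p.eta2_condition)

    def test_constant_weights_unresolved(self, design_meta):
        d = decomp_from_P(np.vstack([np.ones(54), np.linspace(0, 1, 54)]),
                          sample_ids=[s.sample_id for s in design_meta])
        cls = classify_patterns(d, design_meta)
        assert cls.patterns[0].label == "unresolved"
        assert cls.patterns[0].p_line == 1.0

    def test_single_level_factor_dropped_with_warning(self):
        samples = [SampleMeta(f"s{j}", f"L{j % 2}", f"D{j % 2}", "SR",
                              2 + 2 * (j % 3)) for j in range(12)]
        w = np.array([1.0 if s.line_id == "L0" else 0.0 for s in samples])
        d = decomp_from_P(np.vstack([w, np.linspace(0, 1, 12)]),
                          sample_ids=[s.sample_id for s in samples])
        with pytest.warns(UserWarning, match="condition"):
            classify_patterns(d, samples)

    def test_anova_p_matches_permutation_null(self, design_meta):
        """Parametric line p agrees with a brute-force permutation F-null."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(3)
        w = np.clip(0.4 * np.array([s.line_id == "L2" for s in design_meta],
                                    float)
                    + 0.3 * rng.standard_normal(54) + 0.5, 0, None)
        meta = pd.DataFrame({
            "line_id": [s.line_id for s in design_meta],
            "day": [s.day for s in design_meta],
            "condition": [s.condition for s in design_meta]})

        def line_F(vals):
            df = meta.assign(w=vals)
            fit = smf.ols("w ~ C(line_id) + C(day) + C(condition)",
                          data=df).fit()
            return float(sm.stats.anova_lm(fit, typ=2).loc["C(line_id)", "F"])

        obs = line_F(w)
        null = [line_F(rng.permutation(w)) for _ in range(400)]
        p_perm = (1 + sum(f >= obs for f in null)) / 401
        d = decomp_from_P(w[None, :],
                          sample_ids=[s.sample_id for s in design_meta])
        p_param = classify_patterns(d, design_meta).patterns[0].p_line
        # agree within Monte-Carlo error of 400 permutations
        assert abs(p_param - p_perm) < 3 * np.sqrt(p_perm * (1 - p_perm)
                                                   / 400) + 0.01


class TestCluster:
    def test_duplicate_rows_merge_at_zero(self):
        P = np.vstack([np.linspace(0, 1, 8)] * 2 + [np.linspace(1, 0, 8)])
        Z, order = cluster_patterns(decomp_from_P(P))
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert set(map(int, Z[0, :2])) == {0, 1}

    def test_anticorrelated_pair_merges_last(self):
        up = np.linspace(0, 1, 9)
        orth = np.zeros(9)
        orth[::2] = 1.0
        P = np.vstack([up, 1 - up, orth])
        Z, _ = cluster_patterns(decomp_from_P(P))
        # distance between up and 1-up is 1-(-1)=2: the final merge
        assert Z[-1, 2] > Z[0, 2]
        assert Z[-1, 2] == pytest.approx(
            max(Z[:, 2]), rel=1e-12)

    def test_two_patterns_trivial_dendrogram(self):
        P = np.vstack([np.linspace(0, 1, 5), np.linspace(1, 0, 5)])
        Z, order = cluster_patterns(decomp_from_P(P))
        assert Z.shape == (1, 4)
        assert sorted(order) == [0, 1]

    def test_zero_variance_row_flagged(self):
        P = np.vstack([np.ones(6), np.linspace(0, 1, 6)])
        with pytest.warns(UserWarning, match="zero-variance"):
            Z, _ = cluster_patterns(decomp_from_P(P))
        assert Z[0, 2] == pytest.approx(1.0)


class TestMds:
    def test_identical_columns_identical_coordinates(self):
        rng = np.random.default_rng(0)
        a = rng.random(30)
        A = np.column_stack([a, a, rng.random(30)])
        coords, _ = mds_amplitudes(decomp_from_P(np.ones((3, 5)), A=A))
        np.testing.assert_allclose(coords[0], coords[1], atol=1e-8)

    def test_three_patterns_embed_exactly_in_2d(self):
        rng = np.random.default_rng(1)
        A = rng.random((50, 3))
        d = decomp_from_P(np.ones((3, 5)), A=A)
        coords, _ = mds_amplitudes(d, dims=2)
        C = np.corrcoef(A.T)
        D = 1 - C
        for i in range(3):
            for j in range(i + 1, 3):
                got = np.linalg.norm(coords[i] - coords[j])
                assert got == pytest.approx(D[i, j], abs=1e-8)

    def test_dimension_one_separates_dynamic_from_specific(self,
                                                           default_study):
        """Planted dynamic vs line-specific patterns split along MDS axis 1."""
        study, truth = default_study
        d = truth_decomposition(truth, study)
        coords, _ = mds_amplitudes(d, dims=2)
        dyn = truth.modules_of_class("dynamic")
        spec = truth.modules_of_class("donor", "line", "private")
        lo, hi = coords[dyn, 0], coords[spec, 0]
        if lo.mean() > hi.mean():
            lo, hi = hi, lo
        assert lo.max() < hi.min()      # clean separation => silhouette > 0

    def test_needs_enough_patterns(self):
        with pytest.raises(StudyError):
            mds_amplitudes(decomp_from_P(np.ones((2, 4))), dims=2)


class TestScoreCorrelation:
    def test_self_correlation_is_one(self, small_decomp):
        scores = {g: small_decomp.A[i, 2]
                  for i, g in enumerate(small_decomp.gene_ids)}
        out = correlate_weights_with_scores(small_decomp, scores)
        assert out.r.iloc[2] == pytest.approx(1.0)

    def test_independent_scores_within_null_band(self, small_decomp):
        rng = np.random.default_rng(0)
        scores = {g: float(rng.standard_normal())
                  for g in small_decomp.gene_ids}
        out = correlate_weights_with_scores(small_decomp, scores)
        G = len(small_decomp.gene_ids)
        assert np.all(np.abs(out.r) < 3 / np.sqrt(G))

    def test_planted_module_scores_peak_at_module(self, truth_decomp,
                                                  default_study):
        _, truth = default_study
        rng = np.random.default_rng(2)
        k = truth.modules_of_class("dynamic")[1]
        scores = {g: truth_decomp.A[i, k] + 0.1 * rng.standard_normal()
                  for i, g in enumerate(truth_decomp.gene_ids)}
        out = correlate_weights_with_scores(truth_decomp, scores)
        assert int(out.r.idxmax()) == k

    def test_constant_scores_rejected(self, small_decomp):
        with pytest.raises(StudyError, match="constant"):
            correlate_weights_with_scores(
                small_decomp, {g: 1.0 for g in small_decomp.gene_ids})

    def test_too_few_shared_genes_rejected(self, small_decomp):
        with pytest.raises(StudyError, match="shared genes"):
            correlate_weights_with_scores(
                small_decomp, {small_decomp.gene_ids[0]: 1.0})
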