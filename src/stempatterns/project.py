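"""Transfer learning: project external data into a fixed pattern space.

New samples are mapped into a learned decomposition by solving, per
sample, the nonnegative least-squares problem min ||x - A w||^2 with
w >= 0 against the fixed amplitude matrix A (genes restricted to the
identifier intersection and scaled by the decomposition's stored per-gene
scaling).  Significance of a projected signature in a focal sample group
is assessed by permuting the gene identifiers of the projected dataset.
A fixed-loadings PCA projection is provided for the same purpose in
principal-component space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .decompose import PatternDecomposition
from .io import ExpressionStudy, StudyError, match_genes


@dataclass
class ProjectionResult:
    """Pattern weights of external samples in a fixed amplitude space."""

    weights: np.ndarray          # K x n_new, nonnegative
    residual_fraction: np.ndarray  # per-sample ||x - A w||^2 / ||x||^2
    genes_used: int
    sample_ids: list[str]
    pattern_ids: list[str]
    p_perm: float | None = None
    observed_stat: float | None = None
    n_perm: int = 0
    seed: int | None = None


@dataclass
class PCAModel:
    """Gene-centered PCA loadings reusable on external data."""

    loadings: np.ndarray         # genes x n_components, orthonormal columns
    center: np.ndarray           # per-gene mean
    explained_variance_fraction: np.ndarray
    gene_ids: list[str]


def _project_matrix(A: np.ndarray, X: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    from scipy.optimize import nnls

    K = A.shape[1]
    n = X.shape[1]
    W = np.zeros((K, n))
    resid = np.zeros(n)
    for j in range(n):
        w, rnorm = nnls(A, X[:, j])
        W[:, j] = w
        denom = float(X[:, j] @ X[:, j])
        resid[j] = (rnorm**2 / denom) if denom > 0 else 0.0
    return W, resid


def _matched_arrays(decomp: PatternDecomposition, new_study: ExpressionStudy,
                    min_genes: int, row_zscore: bool
                    ) -> tuple[np.ndarray, np.ndarray]:
    ref = ExpressionStudy(
        values=np.zeros((len(decomp.gene_ids), 0)),
        gene_ids=list(decomp.gene_ids), samples=[], scale="other")
    ref_m, new_m = match_genes(ref, new_study)
    if new_m.n_genes < min_genes:
        raise StudyError(
            f"gene intersection {new_m.n_genes} below threshold {min_genes}")
    pos = {g: i for i, g in enumerate(decomp.gene_ids)}
    idx = [pos[g] for g in new_m.gene_ids]
    A = decomp.A[idx]
    if decomp.intercept is not None:
        # trailing column: the decomposition's flat expression-floor pattern;
        # its weight is fit per sample but not reported
        A = np.column_stack([A, decomp.intercept[idx]])
    X = new_m.values
    if row_zscore:
        sd = X.std(axis=1, ddof=0)
        X = (X - X.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)[:, None]
    else:
        X = X / decomp.row_scaling[idx][:, None]
    return A, X


def project_nnls(decomp: PatternDecomposition, new_study: ExpressionStudy,
                 min_genes: int = 50, row_zscore: bool = False
                 ) -> ProjectionResult:
    """Exact NNLS projection of new samples into the amplitude space.

    ``row_zscore=True`` replaces the decomposition's row scaling with
    per-gene z-scoring of the external matrix, for cross-platform inputs
    (microarray intensities, promoter-level ChIP/methylation signal).
    """
    A, X = _matched_arrays(decomp, new_study, min_genes, row_zscore)
    if not row_zscore:
        zero = np.flatnonzero(~X.any(axis=0))
        if zero.size:
            raise StudyError(
                f"all-zero sample(s): {[new_study.sample_ids[i] for i in zero]}")
    W, resid = _project_matrix(A, X)
    return ProjectionResult(
        weights=W[:decomp.K], residual_fraction=np.clip(resid, 0.0, 1.0),
        genes_used=A.shape[0], sample_ids=new_study.sample_ids,
        pattern_ids=decomp.pattern_ids)


def projection_permutation_test(decomp: PatternDecomposition,
                                new_study: ExpressionStudy,
                                group_labels: list[bool] | np.ndarray,
                                target_pattern: int | str,
                                n_perm: int = 10000, seed: int = 0,
                                min_genes: int = 50,
                                row_zscore: bool = False,
                                scheme: str = "genes"
                                ) -> ProjectionResult:
    """Permutation test for a projected signature in a focal sample group.

    The statistic is the mean projected weight of ``target_pattern`` in
    focal samples minus background samples.  With ``scheme="genes"``
    (default) the null permutes the gene identifiers of the projected
    dataset's rows before projection, testing the signature's specific
    gene alignment; ``scheme="labels"`` permutes the focal/background
    labels instead, testing only the group difference.
    ``p = (1 + #{null >= observed}) / (n_perm + 1)``.
    """
    if scheme not in ("genes", "labels"):
        raise StudyError(f"unknown permutation scheme {scheme!r}")
    focal = np.asarray(group_labels, dtype=bool)
    if focal.shape[0] != new_study.n_samples:
        raise StudyError("group_labels length must match new samples")
    if not focal.any():
        raise StudyError("empty focal group")
    if not (~focal).any():
        raise StudyError("empty background group")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} < 100: p-value resolution is coarse")
    if isinstance(target_pattern, str):
        target = decomp.pattern_ids.index(target_pattern)
    else:
        target = int(target_pattern)

    A, X = _matched_arrays(decomp, new_study, min_genes, row_zscore)
    rng = np.random.default_rng(seed)

    def stat(Xm: np.ndarray, labels: np.ndarray) -> float:
        W, _ = _project_matrix(A, Xm)
        return float(W[target, labels].mean() - W[target, ~labels].mean())

    observed = stat(X, focal)
    hits = 0
    if scheme == "labels":
        W0, _ = _project_matrix(A, X)
        row = W0[target]
        for _ in range(n_perm):
            lab = rng.permutation(focal)
            if row[lab].mean() - row[~lab].mean() >= observed:
                hits += 1
    else:
        for _ in range(n_perm):
            perm = rng.permutation(X.shape[0])
            if stat(X[perm], focal) >= observed:
                hits += 1
    p = (1 + hits) / (n_perm + 1)
    W, resid = _project_matrix(A, X)
    return ProjectionResult(
        weights=W[:decomp.K], residual_fraction=np.clip(resid, 0.0, 1.0),
        genes_used=A.shape[0], sample_ids=new_study.sample_ids,
        pattern_ids=decomp.pattern_ids, p_perm=p, observed_stat=observed,
        n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# PCA fit / project
# ---------------------------------------------------------------------------


def pca_fit(study: ExpressionStudy, n_components: int
            ) -> tuple[PCAModel, np.ndarray]:
    """Gene-centered SVD; returns the model and component x sample scores."""
    if study.n_samples < 2:
        raise StudyError("PCA needs >= 2 samples")
    if n_components > min(study.n_genes, study.n_samples - 1):
        raise StudyError(f"n_components={n_components} too large")
    center = study.values.mean(axis=1)
    Xc = study.values - center[:, None]
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|loading| gene positive per component
    for d in range(n_components):
        i = int(np.argmax(np.abs(U[:, d])))
        if U[i, d] < 0:
            U[:, d] *= -1
            Vt[d] *= -1
    total = float((s**2).sum())
    frac = (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    model = PCAModel(
        loadings=U[:, :n_components], center=center,
        explained_variance_fraction=frac, gene_ids=list(study.gene_ids))
    scores = model.loadings.T @ Xc
    return model, scores


def pca_project(model: PCAModel, new_study: ExpressionStudy,
                min_genes: int = 50) -> np.ndarray:
    """Project new samples onto fixed PCA loadings.

    Genes are matched by identifier; the stored center (restricted to the
    intersection) is subtracted and raw loading inner products are
    returned without re-orthonormalization.  The intersection fraction is
    reported via a warning when genes are dropped.
    """
    in_new = {g: i for i, g in enumerate(new_study.gene_ids)}
    shared = [g for g in model.gene_ids if g in in_new]
    if len(shared) < min_genes:
        raise StudyError(
            f"gene intersection {len(shared)} below threshold {min_genes}")
    if len(shared) < len(model.gene_ids):
        warnings.warn(
            f"projecting on {len(shared)}/{len(model.gene_ids)} model genes")
    pos = {g: i for i, g in enumerate(model.gene_ids)}
    midx = [pos[g] for g in shared]
    nidx = [in_new[g] for g in shared]
    Xc = new_study.values[nidx] - model.center[midx][:, None]
    return model.loadings[midx].T @ Xc
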