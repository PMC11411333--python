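"""Consensus nonnegative matrix factorization of an expression study.

Factors a genes x samples matrix X (after per-gene scaling) into
nonnegative gene amplitudes A (genes x K) and pattern weights P
(K x samples), X ~ A @ P.  Single runs use Frobenius-loss multiplicative
updates; the consensus wrapper pools patterns from many seeded restarts,
clusters the pooled pattern-weight vectors by correlation, keeps the K
best-supported clusters, and refits amplitudes by nonnegative least
squares against the consensus weights.  Restart support is reported as a
per-pattern stability score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import nnls
from scipy.spatial.distance import squareform

from .io import ExpressionStudy, StudyError

_EPS = 1e-10
#: restarts whose pattern correlates at or above this level are pooled
CONSENSUS_CORR = 0.7


@dataclass
class PatternDecomposition:
    """Result of a (consensus) NMF run.

    ``A`` lives in the row-scaled gene space; ``row_scaling`` holds the
    per-gene divisor applied before factorization so external data can be
    placed on the same scale at projection time.  Each row of ``P`` is
    normalized to max 1, with the compensating scale folded into ``A`` so
    ``A @ P`` is unchanged.
    """

    A: np.ndarray
    P: np.ndarray
    K: int
    gene_ids: list[str]
    sample_ids: list[str]
    row_scaling: np.ndarray
    objective_trace: list[float]
    restart_stability: np.ndarray
    seed: int
    converged: bool = True
    intercept: np.ndarray | None = None  # per-gene amplitude of a fixed flat pattern
    restart_objectives: list[float] | None = None  # final loss of each restart

    def __post_init__(self) -> None:
        if np.any(self.A < 0) or np.any(self.P < 0):
            raise ValueError("factors must be nonnegative")

    @property
    def pattern_ids(self) -> list[str]:
        return [f"P{k + 1}" for k in range(self.K)]

    def reconstruction(self) -> np.ndarray:
        rec = self.A @ self.P
        if self.intercept is not None:
            rec = rec + self.intercept[:, None]
        return rec


def _scale_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sd = values.std(axis=1, ddof=0)
    scaling = np.where(sd > 0, sd, 1.0)
    return values / scaling[:, None], scaling


def _normalize_and_order(A: np.ndarray, P: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scale each P row to max 1 (scale into A); order rows by variance."""
    A = A.copy()
    P = P.copy()
    for k in range(P.shape[0]):
        m = P[k].max()
        if m > 0:
            P[k] /= m
            A[:, k] *= m
    var = P.var(axis=1)
    first = P[:, 0] if P.shape[1] else np.zeros(P.shape[0])
    order = sorted(range(P.shape[0]), key=lambda k: (-var[k], -first[k], k))
    order = np.asarray(order)
    return A[:, order], P[order], order


def nmf_factorize(study: ExpressionStudy, K: int, seed: int,
                  max_iter: int = 2000, tol: float = 1e-6,
                  fit_intercept: bool = True) -> PatternDecomposition:
    """Single multiplicative-update NMF run on the row-scaled matrix.

    Minimizes ``||X - A P - a0 1^T||_F^2`` with ``A, P, a0 >= 0``; the
    intercept ``a0`` is a per-gene amplitude on a fixed all-ones pattern
    row that absorbs each gene's expression floor (row scaling preserves
    the mean, and a rank-K model cannot also carry a constant offset).
    The objective is recorded every iteration and is non-increasing by
    construction of the updates.  ``fit_intercept=False`` gives plain
    rank-K NMF.
    """
    if not 1 <= K <= min(study.n_genes, study.n_samples):
        raise StudyError(f"K={K} out of range for shape "
                         f"{(study.n_genes, study.n_samples)}")
    if not np.all(np.isfinite(study.values)):
        raise StudyError("NaN/inf in input")
    X, scaling = _scale_rows(study.values)
    if np.any(X < 0):
        raise StudyError("negative values after row scaling")
    rng = np.random.default_rng(seed)
    if not X.any():
        return PatternDecomposition(
            A=np.zeros((study.n_genes, K)), P=np.zeros((K, study.n_samples)),
            K=K, gene_ids=list(study.gene_ids), sample_ids=study.sample_ids,
            row_scaling=scaling, objective_trace=[0.0],
            restart_stability=np.ones(K), seed=seed,
            intercept=np.zeros(study.n_genes) if fit_intercept else None)

    kf = K + 1 if fit_intercept else K  # trailing column = intercept
    scale0 = np.sqrt(X.mean() / kf)
    A = scale0 * rng.random((study.n_genes, kf)) + _EPS
    P = scale0 * rng.random((kf, study.n_samples)) + _EPS
    if fit_intercept:
        P[-1] = 1.0
    trace: list[float] = []
    prev = np.inf
    converged = False
    for _ in range(max_iter):
        A *= (X @ P.T) / (A @ (P @ P.T) + _EPS)
        num = A.T @ X
        den = (A.T @ A) @ P + _EPS
        if fit_intercept:
            P[:-1] *= num[:-1] / den[:-1]
        else:
            P *= num / den
        obj = float(np.linalg.norm(X - A @ P) ** 2)
        trace.append(obj)
        if np.isfinite(prev) and prev - obj <= tol * max(prev, _EPS):
            converged = True
            break
        prev = obj
    intercept = None
    if fit_intercept:
        intercept = A[:, -1].copy()
        A, P = A[:, :-1], P[:-1]
    A, P, _ = _normalize_and_order(A, P)
    return PatternDecomposition(
        A=A, P=P, K=K, gene_ids=list(study.gene_ids),
        sample_ids=study.sample_ids, row_scaling=scaling,
        objective_trace=trace, restart_stability=np.ones(K), seed=seed,
        converged=converged, intercept=intercept)


def _refit_amplitudes(X: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Per-gene NNLS refit of amplitudes against fixed pattern weights."""
    design = P.T  # samples x K
    A = np.zeros((X.shape[0], P.shape[0]))
    for g in range(X.shape[0]):
        A[g], _ = nnls(design, X[g])
    return A


def _safe_corr(M: np.ndarray) -> np.ndarray:
    sd = M.std(axis=1)
    Z = (M - M.mean(axis=1, keepdims=True))
    Z = Z / np.where(sd > 0, sd, 1.0)[:, None]
    C = (Z @ Z.T) / M.shape[1]
    C[sd == 0, :] = 0.0
    C[:, sd == 0] = 0.0
    np.fill_diagonal(C, 1.0)
    return np.clip(C, -1.0, 1.0)


def consensus_decompose(study: ExpressionStudy, K: int, n_restarts: int = 30,
                        seed: int = 0, max_iter: int = 2000,
                        tol: float = 1e-6,
                        sub_seeds: list[int] | None = None,
                        fit_intercept: bool = True
                        ) -> PatternDecomposition:
    """Multi-restart consensus NMF.

    Runs ``n_restarts`` seeded factorizations, pools every restart's
    pattern-weight vectors, clusters them by average-linkage correlation
    (patterns agreeing at r >= 0.7 merge), keeps the K clusters supported
    by the most restarts, takes cluster medians as consensus P, and refits
    A by NNLS.  ``restart_stability[k]`` is the fraction of restarts
    contributing a pattern to consensus cluster k.
    """
    if n_restarts < 1:
        raise StudyError("n_restarts must be >= 1")
    if sub_seeds is None:
        sub_seeds = [int(s) for s in
                     np.random.SeedSequence(seed).generate_state(n_restarts)
                     % (2**31 - 1)]
    elif len(sub_seeds) != n_restarts:
        raise StudyError("sub_seeds length must equal n_restarts")
    if n_restarts == 1:
        return nmf_factorize(study, K, sub_seeds[0], max_iter, tol,
                             fit_intercept)

    runs = [nmf_factorize(study, K, s, max_iter, tol, fit_intercept)
            for s in sub_seeds]
    pooled = np.vstack([r.P for r in runs])            # (R*K) x samples
    restart_of = np.repeat(np.arange(n_restarts), K)

    C = _safe_corr(pooled)
    D = np.clip(1.0 - C, 0.0, 2.0)
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    labels = fcluster(Z, t=1.0 - CONSENSUS_CORR, criterion="distance")
    if len(np.unique(labels)) < K:
        labels = fcluster(Z, t=K, criterion="maxclust")

    clusters = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        support = len(np.unique(restart_of[idx]))
        clusters.append((support, len(idx), int(idx.min()), idx))
    clusters.sort(key=lambda c: (-c[0], -c[1], c[2]))
    kept = clusters[:K]

    P = np.vstack([np.median(pooled[idx], axis=0) for *_, idx in kept])
    stability = np.array([sup / n_restarts for sup, *_ in kept], dtype=float)

    X, scaling = _scale_rows(study.values)
    if fit_intercept:
        A_full = _refit_amplitudes(X, np.vstack([P, np.ones(P.shape[1])]))
        A, intercept = A_full[:, :-1], A_full[:, -1].copy()
    else:
        A = _refit_amplitudes(X, P)
        intercept = None
    A, P, order = _normalize_and_order(A, P)
    stability = stability[order]
    rec = A @ P if intercept is None else A @ P + intercept[:, None]
    obj = float(np.linalg.norm(X - rec) ** 2)
    return PatternDecomposition(
        A=A, P=P, K=P.shape[0], gene_ids=list(study.gene_ids),
        sample_ids=study.sample_ids, row_scaling=scaling,
        objective_trace=[obj], restart_stability=stability, seed=seed,
        converged=all(r.converged for r in runs), intercept=intercept,
        restart_objectives=[r.objective_trace[-1] for r in runs])


def select_rank(study: ExpressionStudy, K_range, n_restarts: int = 30,
                seed: int = 0, stability_threshold: float = 0.9,
                max_iter: int = 2000, tol: float = 1e-6):
    """Per-K diagnostics (relative reconstruction error, mean stability).

    The recommended rank is the largest K whose mean restart stability
    stays at or above ``stability_threshold``: past the true rank,
    restarts split modules inconsistently and stability collapses.
    """
    import pandas as pd

    K_range = list(K_range)
    if not K_range:
        raise StudyError("K_range must be nonempty")
    norm = float(np.linalg.norm(_scale_rows(study.values)[0]) ** 2)
    rows = []
    for K in K_range:
        d = consensus_decompose(study, K, n_restarts=n_restarts, seed=seed,
                                max_iter=max_iter, tol=tol)
        # best single-restart loss: the usual rank diagnostic (the consensus
        # median refit is not guaranteed monotone in K)
        err = (min(d.restart_objectives) if d.restart_objectives
               else d.objective_trace[-1])
        rows.append({
            "K": K,
            "relative_error": err / max(norm, _EPS),
            "mean_stability": float(d.restart_stability.mean()),
        })
    table = pd.DataFrame(rows)
    ok = table[table.mean_stability >= stability_threshold]
    recommended = int(ok.K.max()) if len(ok) else int(table.K.min())
    table.attrs["recommended_K"] = recommended
    return table
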