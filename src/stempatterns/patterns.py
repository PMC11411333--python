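"""Pattern-level statistics: ANOVA classification, clustering, embedding.

A decomposed pattern is *dynamic* when its sample weights track the
differentiation design (day and/or condition) across all lines, and
*line-* or *donor-specific* when its weights are stably elevated in one
line (or in every replicate line of one donor) regardless of day and
condition.  Classification runs a main-effects ANOVA of each pattern's
weights on line + day + condition with type II sums of squares and labels
patterns by the dominant, significant factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

from .decompose import PatternDecomposition
from .io import SampleMeta, StudyError

LABELS = ("dynamic", "line-specific", "donor-specific", "unresolved")


@dataclass
class PatternClass:
    pattern: str
    p_line: float
    p_day: float
    p_condition: float
    eta2_line: float
    eta2_day: float
    eta2_condition: float
    label: str
    owner: str | None = None


@dataclass
class PatternClassification:
    patterns: list[PatternClass]
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.patterns])

    def label_of(self, pattern: str) -> str:
        for p in self.patterns:
            if p.pattern == pattern:
                return p.label
        raise KeyError(pattern)


def _anova_one_pattern(w: np.ndarray, meta: pd.DataFrame,
                       factors: dict[str, str]
                       ) -> tuple[dict[str, float], dict[str, float]]:
    df = meta.copy()
    df["w"] = w
    formula = "w ~ " + " + ".join(f"C({col})" for col in factors.values())
    fit = smf.ols(formula, data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = sm.stats.anova_lm(fit, typ=2)
    ss_resid = float(table.loc["Residual", "sum_sq"])
    ps, etas = {}, {}
    for f, col in factors.items():
        row = table.loc[f"C({col})"]
        ss = float(row["sum_sq"])
        ps[f] = float(row["PR(>F)"])
        etas[f] = ss / (ss + ss_resid) if (ss + ss_resid) > 0 else 0.0
    return ps, etas


def classify_patterns(decomp: PatternDecomposition,
                      metadata: list[SampleMeta] | pd.DataFrame,
                      alpha: float = 0.01,
                      dominance_ratio: float = 0.6) -> PatternClassification:
    """Label each pattern dynamic / line-specific / donor-specific / unresolved.

    The dominant factor (largest partial eta^2) must be significant at the
    Bonferroni level ``alpha / K``, and every competing factor that is
    itself significant must stay below ``dominance_ratio`` times the
    dominant partial eta^2 — a pure significance gate on competitors is
    fragile because estimated pattern weights carry small but highly
    significant cross-factor leakage, and partial eta^2 of a minor factor
    inflates whenever the dominant factor leaves almost no residual.
    A line-dominant pattern is promoted from line- to donor-specific when
    the owner donor has at least two replicate lines and each of their
    mean weights exceeds the 90th percentile of non-owner-line sample
    weights.
    """
    if isinstance(metadata, pd.DataFrame):
        meta = metadata.copy()
    else:
        meta = pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in metadata],
                "line_id": [s.line_id for s in metadata],
                "donor_id": [s.donor_id for s in metadata],
                "condition": [s.condition for s in metadata],
                "day": [s.day for s in metadata],
            }
        )
    meta = meta.set_index("sample_id").loc[decomp.sample_ids].reset_index()
    factor_col = {"line": "line_id", "day": "day", "condition": "condition"}
    factors: dict[str, str] = {}
    for f, col in factor_col.items():
        if meta[col].nunique() < 2:
            warnings.warn(f"factor {f!r} has a single level and was dropped")
        else:
            factors[f] = col
    if not factors:
        raise StudyError("no factor with >= 2 levels")

    donor_lines: dict[str, list[str]] = {}
    for _, row in meta.drop_duplicates("line_id").iterrows():
        donor_lines.setdefault(row["donor_id"], []).append(row["line_id"])

    gate = alpha / decomp.K
    out = []
    for k, pid in enumerate(decomp.pattern_ids):
        w = decomp.P[k]
        if w.std() < 1e-12:
            out.append(PatternClass(pid, 1.0, 1.0, 1.0, 0.0, 0.0, 0.0,
                                    "unresolved"))
            continue
        ps, etas = _anova_one_pattern(w, meta, factors)
        ps = {f: ps.get(f, 1.0) for f in factor_col}
        etas = {f: etas.get(f, 0.0) for f in factor_col}
        sig = {f: ps[f] < gate for f in factor_col}
        dominant = max(etas, key=lambda f: etas[f])
        rivals_weak = all(
            (not sig[f]) or etas[f] < dominance_ratio * etas[dominant]
            for f in factor_col if f != dominant)

        label, owner = "unresolved", None
        if dominant == "line" and sig["line"] and rivals_weak:
            label = "line-specific"
            line_means = meta.assign(w=w).groupby("line_id")["w"].mean()
            owner = str(line_means.idxmax())
            owner_donor = meta.loc[meta.line_id == owner, "donor_id"].iloc[0]
            sibs = donor_lines.get(owner_donor, [])
            if len(sibs) >= 2:
                non_owner = w[~meta.line_id.isin(sibs).to_numpy()]
                cut = np.percentile(non_owner, 90) if non_owner.size else -np.inf
                if all(line_means[l] > cut for l in sibs):
                    label, owner = "donor-specific", str(owner_donor)
        elif dominant in ("day", "condition") and sig[dominant] and (
                (not sig["line"])
                or etas["line"] < dominance_ratio * etas[dominant]):
            label = "dynamic"
        out.append(PatternClass(
            pid, ps["line"], ps["day"], ps["condition"],
            etas["line"], etas["day"], etas["condition"], label, owner))
    return PatternClassification(out, alpha)


def cluster_patterns(decomp: PatternDecomposition, method: str = "average"
                     ) -> tuple[np.ndarray, list[int]]:
    """Hierarchically cluster P rows at distance 1 - Pearson r.

    Returns the scipy linkage matrix and a deterministic leaf order.
    Zero-variance pattern rows get distance 1 to everything (with a
    warning).
    """
    if decomp.K < 2:
        raise StudyError("clustering needs K >= 2")
    P = decomp.P
    sd = P.std(axis=1)
    if np.any(sd == 0):
        warnings.warn("zero-variance pattern row; distance to it set to 1")
    Z0 = (P - P.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)[:, None]
    C = np.clip((Z0 @ Z0.T) / P.shape[1], -1.0, 1.0)
    D = 1.0 - C
    D[sd == 0, :] = 1.0
    D[:, sd == 0] = 1.0
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method=method)
    return Z, [int(i) for i in leaves_list(Z)]


def mds_amplitudes(decomp: PatternDecomposition, dims: int = 2
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Classical (Torgerson) MDS of the patterns' gene-amplitude profiles.

    Distance is 1 - Pearson r between amplitude columns; returns
    (K x dims coordinates centered at the origin, eigenvalues).  If the
    double-centered matrix has fewer than ``dims`` positive eigenvalues
    the surplus coordinates are zero and a warning is issued.
    """
    if decomp.K < dims + 1:
        raise StudyError(f"need K >= dims+1 (K={decomp.K}, dims={dims})")
    A = decomp.A
    sd = A.std(axis=0)
    Z0 = (A - A.mean(axis=0, keepdims=True)) / np.where(sd > 0, sd, 1.0)[None, :]
    C = np.clip((Z0.T @ Z0) / A.shape[0], -1.0, 1.0)
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    n = decomp.K
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    coords = np.zeros((n, dims))
    informative = 0
    for d in range(dims):
        if evals[d] > 1e-10:
            coords[:, d] = evecs[:, d] * np.sqrt(evals[d])
            informative += 1
    if informative < dims:
        warnings.warn(f"only {informative} informative MDS dimensions")
    # deterministic sign: largest-|coordinate| entry positive per axis
    for d in range(dims):
        i = int(np.argmax(np.abs(coords[:, d])))
        if coords[i, d] < 0:
            coords[:, d] *= -1
    return coords, evals


def correlate_weights_with_scores(decomp: PatternDecomposition,
                                  gene_scores: dict[str, float]
                                  ) -> pd.DataFrame:
    """Pearson correlation of each pattern's gene amplitudes with a score vector.

    Used e.g. to relate patterns to a per-gene differential-expression
    statistic from a knockout contrast.
    """
    shared = [g for g in decomp.gene_ids if g in gene_scores]
    if len(shared) < 10:
        raise StudyError(f"only {len(shared)} shared genes (< 10)")
    pos = {g: i for i, g in enumerate(decomp.gene_ids)}
    idx = [pos[g] for g in shared]
    scores = np.array([gene_scores[g] for g in shared], dtype=float)
    if scores.std() == 0:
        raise StudyError("constant score vector: correlation undefined")
    rows = []
    for k, pid in enumerate(decomp.pattern_ids):
        a = decomp.A[idx, k]
        if a.std() == 0:
            rows.append({"pattern": pid, "r": np.nan, "p": np.nan})
            continue
        r, p = pearsonr(a, scores)
        rows.append({"pattern": pid, "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)
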