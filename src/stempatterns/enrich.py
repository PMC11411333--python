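"""Gene-set and annotation statistics over pattern gene weights.

The workhorse is a rank-based (Wilcoxon rank-sum / Mann-Whitney)
enrichment of a gene set's amplitudes against the complement within one
pattern, summarized as an AUC (probability that a random set gene
outranks a random background gene).  List-vs-list overlaps use the
one-sided hypergeometric test.  Evolutionary-era contributions and
dosage-sensitivity (pHaplo) summaries profile how gene age and
haploinsufficiency load onto dynamic versus line-specific patterns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, mannwhitneyu

from .decompose import PatternDecomposition
from .io import StudyError


@dataclass
class EnrichmentResult:
    pattern: str
    set_name: str
    auc: float
    p_one_sided: float
    p_adjusted: float
    n_set: int
    n_background: int


def _amplitude_split(decomp: PatternDecomposition, gene_set, pattern_index: int
                     ) -> tuple[np.ndarray, np.ndarray, int]:
    members = set(gene_set)
    in_set = np.array([g in members for g in decomp.gene_ids])
    n_set = int(in_set.sum())
    if n_set < 5:
        raise StudyError(f"only {n_set} set genes present (< 5)")
    if n_set == len(decomp.gene_ids):
        raise StudyError("set covers every gene: no background")
    a = decomp.A[:, pattern_index]
    return a[in_set], a[~in_set], n_set


def _mwu(x: np.ndarray, y: np.ndarray, alternative: str
         ) -> tuple[float, float]:
    n, m = len(x), len(y)
    # exact enumeration for small samples without ties, normal
    # approximation with continuity correction otherwise
    has_ties = len(np.unique(np.concatenate([x, y]))) < n + m
    method = "exact" if (max(n, m) <= 50 and not has_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def rank_enrichment(decomp: PatternDecomposition, gene_set,
                    pattern: int | str, set_name: str = "set"
                    ) -> EnrichmentResult:
    """One-sided rank-sum enrichment of a gene set in one pattern.

    Tests whether set genes have higher amplitudes than the complement;
    AUC = U / (n_set * n_background).  ``p_adjusted`` is Bonferroni
    across the decomposition's K patterns.
    """
    k = decomp.pattern_ids.index(pattern) if isinstance(pattern, str) else int(pattern)
    x, y, n_set = _amplitude_split(decomp, gene_set, k)
    u, p = _mwu(x, y, "greater")
    auc = u / (len(x) * len(y))
    return EnrichmentResult(
        pattern=decomp.pattern_ids[k], set_name=set_name, auc=float(auc),
        p_one_sided=p, p_adjusted=min(1.0, decomp.K * p),
        n_set=n_set, n_background=len(y))


def enrichment_profile(decomp: PatternDecomposition, gene_set,
                       set_name: str = "set") -> pd.DataFrame:
    """Rank enrichment of one set in every pattern, sorted by AUC."""
    rows = [vars(rank_enrichment(decomp, gene_set, k, set_name))
            for k in range(decomp.K)]
    return (pd.DataFrame(rows)
            .sort_values("auc", ascending=False, kind="mergesort")
            .reset_index(drop=True))


def overlap_enrichment(top_genes, annotation_set, universe
                       ) -> tuple[float, float]:
    """Upper-tail hypergeometric overlap test; returns (p, fold).

    ``fold`` is observed over expected overlap given the universe size.
    """
    universe = list(dict.fromkeys(universe))
    if not universe or not top_genes:
        raise StudyError("empty universe or top-gene list")
    uni = set(universe)
    top = set(top_genes) & uni
    ann = set(annotation_set) & uni
    if top != set(top_genes) or ann != set(annotation_set):
        raise StudyError("top_genes and annotation_set must be in the universe")
    M, n, N = len(uni), len(ann), len(top)
    k = len(top & ann)
    p = float(hypergeom.sf(k - 1, M, n, N))
    expected = N * n / M
    fold = k / expected if expected > 0 else math.inf
    return p, float(fold)


def era_contribution(decomp: PatternDecomposition, era_map: dict[str, int],
                     min_per_stratum: int = 5) -> pd.DataFrame:
    """Per-pattern amplitude summaries per evolutionary era (1 ancient .. 5 recent).

    For each pattern, reports the mean amplitude per era and a two-sided
    Wilcoxon rank-sum comparison of era-1 versus era-5 amplitudes, with
    the direction of the difference (positive = ancient genes heavier).
    """
    eras = np.array([era_map.get(g, 0) for g in decomp.gene_ids])
    counts = {e: int((eras == e).sum()) for e in range(1, 6)}
    present = [e for e, c in counts.items() if c >= min_per_stratum]
    if len(present) < 2 or not {1, 5} <= set(present):
        raise StudyError(
            f"need >= {min_per_stratum} genes in eras 1 and 5; have {counts}")
    rows = []
    for k, pid in enumerate(decomp.pattern_ids):
        a = decomp.A[:, k]
        row: dict = {"pattern": pid}
        for e in range(1, 6):
            row[f"mean_era{e}"] = float(a[eras == e].mean()) if counts[e] else np.nan
        x1, x5 = a[eras == 1], a[eras == 5]
        _, p = _mwu(x1, x5, "two-sided")
        row["era1_minus_era5"] = float(x1.mean() - x5.mean())
        row["p_era1_vs_era5"] = p
        rows.append(row)
    return pd.DataFrame(rows)


def dosage_sensitivity_summary(decomp: PatternDecomposition,
                               phaplo_map: dict[str, float],
                               top_frac: float = 0.01) -> pd.DataFrame:
    """Mean haploinsufficiency score of each pattern's top-amplitude genes.

    Selects the top ``ceil(top_frac * G)`` genes per pattern by amplitude
    and averages pHaplo over those with a score, counting exclusions.
    """
    scored = [g in phaplo_map for g in decomp.gene_ids]
    if sum(scored) < len(decomp.gene_ids) / 2:
        raise StudyError("pHaplo must be defined for at least half the genes")
    G = len(decomp.gene_ids)
    n_top = math.ceil(top_frac * G)
    gene_arr = np.array(decomp.gene_ids)
    rows = []
    for k, pid in enumerate(decomp.pattern_ids):
        order = np.argsort(-decomp.A[:, k], kind="stable")[:n_top]
        top = gene_arr[order]
        vals = [phaplo_map[g] for g in top if g in phaplo_map]
        if not vals:
            raise StudyError(f"no scored genes among top of {pid}")
        rows.append({
            "pattern": pid, "n_top": n_top, "n_scored": len(vals),
            "n_excluded": n_top - len(vals),
            "mean_phaplo": float(np.mean(vals)),
        })
    return pd.DataFrame(rows)
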