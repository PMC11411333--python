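"""Phenotype, donor-structure and kinship associations of pattern statistics.

Links the transcriptomic layer to phenotype and genetics: per-line
pattern enrichment versus a lineage-bias phenotype (e.g. the proportion
of hindbrain-marker-high cells after retinoic acid), the intraclass
correlation of per-sample scores across donors (how much across-line
variation is attributable to donor of origin), and the correlation of a
projected donor signature's strength with genetic similarity to the
reference donor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import linregress, pearsonr

from .io import StudyError


@dataclass
class AssociationResult:
    r: float
    r_squared: float
    p_two_sided: float
    n: int
    slope: float
    intercept: float
    p_perm: float | None = None


@dataclass
class ICCResult:
    """One-way random-effects ICC(1): share of variance between groups."""

    icc: float
    ms_between: float
    ms_within: float
    n_groups: int
    group_sizes: list[int]


def phenotype_association(per_line_scores: Mapping[str, float],
                          phenotypes: Mapping[str, float]
                          ) -> AssociationResult:
    """Pearson correlation and least-squares line of phenotype on score."""
    lines = [l for l in per_line_scores if l in phenotypes]
    if len(lines) < 3:
        raise StudyError(f"need >= 3 lines with both values, have {len(lines)}")
    x = np.array([per_line_scores[l] for l in lines], dtype=float)
    y = np.array([phenotypes[l] for l in lines], dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise StudyError("constant scores or phenotypes: correlation undefined")
    r, p = pearsonr(x, y)
    fit = linregress(x, y)
    return AssociationResult(
        r=float(r), r_squared=float(r) ** 2, p_two_sided=float(p),
        n=len(lines), slope=float(fit.slope), intercept=float(fit.intercept))


def donor_icc(scores, donor_labels) -> ICCResult:
    """ICC(1) of per-sample scores grouped by donor.

    One-way random-effects, method of moments:
    ``(MSB - MSW) / (MSB + (k0 - 1) MSW)`` with the standard
    unbalanced-design ``k0 = (N - sum(k_i^2)/N) / (G - 1)``.
    """
    scores = np.asarray(scores, dtype=float)
    donors = np.asarray(donor_labels)
    if scores.shape[0] != donors.shape[0]:
        raise StudyError("scores and donor labels must align")
    groups = [scores[donors == d] for d in pd.unique(donors)]
    sizes = [len(g) for g in groups]
    G, N = len(groups), sum(sizes)
    if G < 2:
        raise StudyError("need >= 2 donors")
    if max(sizes) < 2:
        raise StudyError("need at least one donor with >= 2 lines")
    grand = scores.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    msb = ssb / (G - 1)
    msw = ssw / (N - G)
    k0 = (N - sum(s**2 for s in sizes) / N) / (G - 1)
    if msw == 0:
        icc = 1.0
    else:
        icc = (msb - msw) / (msb + (k0 - 1) * msw)
    return ICCResult(icc=float(icc), ms_between=float(msb),
                     ms_within=float(msw), n_groups=G, group_sizes=sizes)


def kinship_signature_correlation(kinship: pd.DataFrame, reference_donor: str,
                                  signature_strengths: Mapping[str, float],
                                  n_perm: int = 10000, seed: int = 0
                                  ) -> AssociationResult:
    """Correlate a projected signature's per-individual strength with kinship.

    ``r`` is the Pearson correlation between each individual's kinship to
    the reference donor (reference excluded) and the signature strength;
    the permutation p (one-sided, positive association) shuffles
    individual labels.  A genetically driven donor signature should
    correlate; an epigenetic private-line signature should not.
    """
    if reference_donor not in kinship.index:
        raise StudyError(f"reference donor {reference_donor!r} not in kinship")
    inds = [i for i in signature_strengths
            if i in kinship.index and i != reference_donor]
    if len(inds) < 3:
        raise StudyError(f"need >= 3 individuals, have {len(inds)}")
    k = kinship.loc[reference_donor, inds].to_numpy(dtype=float)
    s = np.array([signature_strengths[i] for i in inds], dtype=float)
    if k.std() == 0 or s.std() == 0:
        raise StudyError("constant kinship or strengths: correlation undefined")
    r, p = pearsonr(k, s)
    fit = linregress(k, s)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if np.corrcoef(k, rng.permutation(s))[0, 1] >= r:
            hits += 1
    p_perm = (1 + hits) / (n_perm + 1)
    return AssociationResult(
        r=float(r), r_squared=float(r) ** 2, p_two_sided=float(p),
        n=len(inds), slope=float(fit.slope), intercept=float(fit.intercept),
        p_perm=float(p_perm))


def donor_r_squared(scores, donor_labels) -> float:
    """Variance explained by a fixed donor factor (SSB / SST).

    Alternative reading of "proportion of variation attributable to
    donor" to the random-effects ICC(1); always >= the ICC on the same
    data because it does not discount within-donor sampling noise.
    """
    scores = np.asarray(scores, dtype=float)
    donors = np.asarray(donor_labels)
    grand = scores.mean()
    sst = ((scores - grand) ** 2).sum()
    if sst == 0:
        raise StudyError("constant scores: variance ratio undefined")
    ssb = sum(len(scores[donors == d]) * (scores[donors == d].mean()
                                          - grand) ** 2
              for d in pd.unique(donors))
    return float(ssb / sst)


def mantel_kinship_test(kinship: pd.DataFrame,
                        signature_strengths: Mapping[str, float],
                        n_perm: int = 10000, seed: int = 0
                        ) -> AssociationResult:
    """Mantel test: kinship vs pairwise signature similarity.

    Correlates the off-diagonal kinship entries with the negative
    absolute strength differences (similar strengths in related
    individuals give positive r); significance by permuting individuals
    jointly in rows and columns.
    """
    inds = [i for i in signature_strengths if i in kinship.index]
    if len(inds) < 4:
        raise StudyError(f"need >= 4 individuals, have {len(inds)}")
    K = kinship.loc[inds, inds].to_numpy(dtype=float)
    s = np.array([signature_strengths[i] for i in inds], dtype=float)
    iu = np.triu_indices(len(inds), k=1)
    sim = -np.abs(s[:, None] - s[None, :])
    k_vec, sim_vec = K[iu], sim[iu]
    if k_vec.std() == 0 or sim_vec.std() == 0:
        raise StudyError("degenerate kinship or strengths")
    r, p = pearsonr(k_vec, sim_vec)
    fit = linregress(k_vec, sim_vec)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(inds))
        if np.corrcoef(k_vec, sim[perm][:, perm][iu])[0, 1] >= r:
            hits += 1
    return AssociationResult(
        r=float(r), r_squared=float(r) ** 2, p_two_sided=float(p),
        n=len(inds), slope=float(fit.slope), intercept=float(fit.intercept),
        p_perm=(1 + hits) / (n_perm + 1))
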