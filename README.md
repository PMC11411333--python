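# stempatterns

Pattern decomposition and transfer analysis of pluripotent stem cell
differentiation transcriptomics.

Human pluripotent stem cell (hPSC) lines differ in how readily they
adopt particular fates — for example anterior (forebrain) versus
posterior (hindbrain) neural identity under retinoic acid (RA)
signaling. When many lines from several donors are profiled by bulk
RNA-seq across differentiation conditions and time points, that
variation separates into two kinds of latent structure: *dynamic*
expression programs shared by all lines that track differentiation
itself, and *line/donor-specific* programs that stay constant across
conditions and time but mark an individual line or donor. This package
implements that analysis end to end for computational biologists working
with multi-line, multi-condition expression designs.

## The model

The expression matrix X (genes × samples) is factored by multi-restart
consensus nonnegative matrix factorization with an explicit
expression-floor intercept,

    X ≈ A P + a₀1ᵀ,   A, P, a₀ ≥ 0,

where A holds per-gene amplitudes ("gene weights") of K patterns and P
the per-sample pattern weights. Downstream stages operate on A and P:

- **Classification** — per-pattern ANOVA of weights on line + day +
  condition (type II), labeling patterns dynamic, line-specific,
  donor-specific, or unresolved, with the owning line/donor.
- **Projection (transfer learning)** — exact nonnegative least squares
  of external samples (other studies, tissue, promoter-level signal)
  against the fixed A, with gene-permutation significance testing; plus
  fixed-loadings PCA projection.
- **Enrichment** — Wilcoxon rank-sum AUC of gene sets (e.g.
  RA-responsive, KRAB-ZNF) over pattern gene weights, hypergeometric
  list overlap, evolutionary-era contributions, and mean pHaplo
  (dosage-sensitivity) of top-weighted genes.
- **Association** — per-line enrichment vs phenotype (Pearson r/R²),
  one-way random-effects ICC(1) of scores across donors, and correlation
  of projected signature strength with kinship to a reference donor.
- **Synthetic data** — a first-class generator that plants all of the
  above structure (trajectory modules, donor/line/private modules,
  enriched gene sets, era/pHaplo stratification, phenotype link,
  kinship) so every stage is verifiable without downloads.

See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
import numpy as np
from scipy.optimize import linear_sum_assignment
from stempatterns import (SimulationConfig, simulate_study,
                          consensus_decompose, classify_patterns)

study, truth = simulate_study(SimulationConfig(seed=1))
decomp = consensus_decompose(study, K=truth.k_true, n_restarts=30, seed=1)

A_est = decomp.A * decomp.row_scaling[:, None]
C = (truth.A_true.T @ A_est) / np.outer(
    np.linalg.norm(truth.A_true, axis=0), np.linalg.norm(A_est, axis=0))
rows, cols = linear_sum_assignment(-C)
print(np.round(C[rows, cols], 3))

table = classify_patterns(decomp, study.samples).to_frame()
print(table[["pattern", "label", "owner"]].to_string(index=False))
```

prints (pattern order may differ):

```
[0.959 0.912 0.918 0.91  0.93  0.98  0.964 0.97 ]
pattern          label owner
     P1 donor-specific    D1
     P2        dynamic  None
     P3        dynamic  None
     P4        dynamic  None
     P5  line-specific    L4
     P6  line-specific    L6
     P7        dynamic  None
     P8        dynamic  None
```

The first line is the cosine similarity between each planted module's
gene amplitudes and its best-matched recovered pattern (values near 1 =
near-exact recovery of the planted gene programs). The classification
finds the three planted specific modules — the donor-shared module of
donor D1, the private module of discordant line L4, and the line module
of L6 — and labels the five trajectory modules dynamic.

The `examples/` directory has one short script per capability
(decomposition, classification/embedding, projection with permutation
significance, enrichment + phenotype association, donor ICC + kinship
contrast), each printing the numbers it computes with a line on what
they mean. A thin CLI (`stempatterns simulate|decompose|classify|embed|
project|pca-fit|pca-project|enrich|associate|icc|kinship-assoc`) wraps
the same functions for shell pipelines; every stage is byte-reproducible
given a config and seed.

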