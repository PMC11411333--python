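# Methods

`stempatterns` analyses multi-line pluripotent stem cell differentiation
transcriptomics by decomposing a genes x samples expression matrix into
nonnegative latent patterns, separating patterns that track the
differentiation design (*dynamic*) from patterns that mark an individual
line or donor (*line/donor-specific*), and then relating those patterns
to external datasets, gene annotations, phenotypes and donor genetics.
This note records the models, the parameters that matter, and the design
choices made where more than one reasonable option existed.

## Consensus NMF with an expression-floor intercept

Each gene row is divided by its standard deviation before factorization
(the divisor is retained as `row_scaling` and reused when projecting
external data), preventing highly expressed genes from dominating the
Frobenius loss. The model fitted is

    X ≈ A P + a0 1ᵀ,   A, P, a0 ≥ 0,

by multiplicative updates on ||X − A P − a0 1ᵀ||²_F. The intercept
column `a0` is a per-gene amplitude on a fixed all-ones pattern row. It
is there because row scaling preserves each gene's mean, so every gene —
including genes with no module membership — carries a large constant
component after scaling; a rank-K model without an intercept must spend
pattern capacity on that constant, which measurably corrupts amplitude
recovery. With the intercept, the K reported patterns describe
*variation*, and the floor is reported separately. `fit_intercept=False`
gives plain NMF.

Numerical choices: ε = 1e-10 in update denominators; convergence when
the relative objective decrease falls below `tol` (default 1e-6; the
objective is non-increasing by construction); an all-zero input returns
zero factors with objective 0. Each P row is rescaled to max 1 with the
compensating factor folded into A, leaving A·P unchanged; patterns are
ordered by descending weight variance (ties by first-sample weight, then
index) for reproducible labeling.

Consensus: `n_restarts` seeded runs (sub-seeds derived from the master
seed via `numpy.random.SeedSequence`) are pooled; pooled pattern-weight
rows are clustered by average-linkage on 1 − Pearson r, cut at r = 0.7
(falling back to a forced K-cluster cut if fewer clusters emerge); the K
clusters supported by the most restarts are kept; cluster medians become
the consensus P; A and a0 are refit per gene by exact NNLS. Per-pattern
`restart_stability` is the fraction of restarts contributing to the
cluster. A single restart returns the plain run unchanged (clustering
one run's patterns could merge correlated patterns and silently change
the contract).

Rank selection reports, per K, the best single-restart relative
reconstruction error (the consensus-median refit is not guaranteed
monotone in K) and mean stability; the recommended rank is the largest K
with mean stability ≥ 0.9. Stability-based selection is reliable when
the planted modules are the only low-rank structure; a strong shared
expression floor combined with multiplicative noise can itself produce a
stable extra component, which is one reason the floor is modelled
explicitly.

## Pattern classification

Each pattern's weight vector is analysed by a main-effects OLS ANOVA on
line + day + condition (type II sums of squares; interactions are
deliberately excluded — with one replicate per design cell they are not
estimable). A factor with a single level is dropped with a warning.
Significance is gated at Bonferroni `alpha / K` (default alpha 0.01).

The label is decided by dominance: the factor with the largest partial
η² must pass the gate, and any *competing* significant factor must stay
below 0.6 × the dominant partial η². A pure "competitors must be
non-significant" gate fails in practice: estimated pattern weights carry
small but highly significant cross-factor leakage, and the partial η² of
a minor factor inflates arbitrarily once the dominant factor leaves
almost no residual. The 0.6 ratio is a deliberate, documented threshold;
it trades a small risk of labeling genuinely mixed patterns by their
dominant factor against systematically discarding clean specific
patterns as "unresolved".

Line-dominant patterns are owned by the line with the highest mean
weight and promoted to *donor-specific* when the owner donor has at
least two replicate lines whose per-line mean weights all exceed the
90th percentile of non-owner-line sample weights; singleton-donor lines
stay line-specific. Constant-weight patterns are unresolved with p = 1.

Hierarchical clustering of patterns uses 1 − Pearson r on P rows
(zero-variance rows get distance 1, flagged); the pattern map uses
classical (Torgerson) MDS on 1 − Pearson r between amplitude columns,
with eigendecomposition of the double-centered squared-distance matrix,
surplus non-informative axes zeroed with a warning, and a deterministic
sign convention (largest-magnitude coordinate positive per axis).

## Projection (transfer learning)

External samples are mapped into a fixed amplitude space by exact
Lawson–Hanson NNLS per sample against [A, a0], after restricting to the
gene-identifier intersection (exact, case-sensitive matching; minimum 50
shared genes by default). Same-platform data are scaled by the stored
`row_scaling`; cross-platform matrices (microarray, promoter-level
ChIP/methylation signal) are per-gene z-scored instead
(`row_zscore=True`). The intercept weight is fitted but not reported.
Per-sample residual fraction ||x − Âw||²/||x||² is returned, and KKT
optimality of every solution is asserted in tests.

The permutation test for a projected signature compares the mean target-
pattern weight in a focal sample group against the background group; the
null permutes the gene identifiers of the projected dataset before
projection, p = (1 + #{null ≥ observed}) / (n_perm + 1). Permuting
sample labels is available as an alternative reading
(``scheme="labels"``), but gene permutation is the default because the claim being tested is that the
*specific gene alignment* of the signature, not merely some group
difference, drives the elevation. Calibration note: with
`row_zscore=True` the external rows are exchangeable under the null and
the test's type-I rate sits at its nominal level; with raw row scaling
the permutation redistributes heterogeneous row magnitudes and the test
becomes conservative. The z-scored path is therefore the recommended and
tested configuration for permutation inference.

PCA: gene-centered SVD with a deterministic sign convention; projection
of new data subtracts the stored center restricted to the matched genes
and takes raw loading inner products, without re-orthonormalizing the
truncated loadings — the matched-gene fraction is reported so users can
judge comparability.

## Enrichment statistics

Pattern-weight enrichment of a gene set is a one-sided Wilcoxon rank-sum
(Mann–Whitney) of set-gene amplitudes against the complement, summarized
as AUC = U/(n_set · n_bg); exact enumeration is used for sample sizes up
to 50 without ties, the continuity-corrected normal approximation
otherwise; ties get midranks. Bonferroni correction is applied across
the K patterns (conservative, documented). List-vs-list overlap (eQTL-
or KRAB-ZNF-style membership questions) uses the upper-tail
hypergeometric test with fold = observed/expected. Both are exposed; the
rank statistic is the default for gene weights because weights are
continuous and thresholding them would discard information.

Evolutionary-era contributions report per-pattern mean amplitudes per
era stratum (1 = ancient … 5 = primate-specific) and a two-sided
rank-sum comparison of era-1 vs era-5 amplitudes with the signed
difference. Dosage-sensitivity summaries take the top ⌈top_frac·G⌉ genes
per pattern (default 1%) and average pHaplo over those with scores,
counting exclusions.

## Associations

Phenotype association is a Pearson correlation / least-squares line of
per-line phenotype on per-line pattern scores (≥3 lines; constant
vectors are an explicit error). With ~6 lines the parametric p is
approximate at best; the simulation tests quantify estimator behavior at
that n rather than trusting asymptotics.

Donor ICC is the one-way random-effects ICC(1) by method of moments,
(MSB − MSW)/(MSB + (k0 − 1)·MSW), with the standard unbalanced-design
k0 = (N − Σk_i²/N)/(G − 1); balanced designs reduce to the textbook
formula exactly. `donor_r_squared` exposes the alternative
fixed-donor-factor reading (SSB/SST) of the same quantity; it upper-
bounds the ICC because it does not discount within-donor noise.

Kinship–signature correlation takes the kinship-to-reference vector
(reference excluded) against per-individual projected signature
strengths (raw NNLS weights; z-scores optional), with a one-sided
label-permutation p. A genetically driven donor signature correlates;
an epigenetically private line signature should not — the simulation
plants exactly this contrast.

## The synthetic-data generator

The generator emulates the reference design: 2000 genes; six lines from
four donors — one donor with two concordant replicate lines (donor
module), one donor with a discordant pair in which one line carries a
*private* module (modelling an epigenetically divergent replicate line),
one singleton-donor line with its own line module, one unmarked line;
3 conditions (SR self-renewal, NSB neuroectoderm induction, BMP4
mesendoderm induction) × days 2/4/6 × 1 replicate = 54 samples; K_true =
8 modules (5 dynamic + donor + line + private).

Dynamic modules follow a five-curve parametric library over the day axis
(pluripotency-decay across all conditions; early-peaking and late-rising
curves within NSB and within BMP4; off-target conditions at a 0.04
floor). A fifth curve was added to the natural four-shape library
because the reference conditions call for five separable dynamic
modules and duplicating a curve would make the factorization
unidentifiable by construction; the early/late curves within a condition
are deliberately non-collinear (peak-then-fall vs monotone rise) so that
recovery failure signals an algorithmic defect rather than an
ill-posed instance. Specific modules have weight 1 on the owning
line/donor samples and 0 elsewhere.

Amplitudes: each module loads (1 − sparsity)·G genes (default sparsity
0.9) with Gamma(2, 1) amplitudes. Planted sets (RA-like and KRAB-like,
100 genes each, disjoint) receive an additive amplitude boost of
set_shift·U(0.5, 1.5) (default shift 2.0, comparable to a typical
loading) in their target modules — RA-like in the private module (the
hindbrain-biased discordant line), KRAB-like in every specific module.
Gene era is drawn per gene from stratum-specific probabilities keyed to
the gene's primary (argmax-amplitude) module: dynamic-primary genes skew
ancient, specific-primary genes skew recent, unassigned genes uniform.
pHaplo is Beta-distributed with mean 0.62 / 0.38 / 0.50 for those strata
(concentration 14), matching the reported contrast that specific-pattern
genes are less dosage-sensitive.

Expression is `baseline + A_true @ P_true` perturbed by mean-1
multiplicative lognormal noise (default σ = 0.25; a negative-binomial
count path with dispersion 10 and mean scale 50 serves the RPKM
pipeline). The scalar `baseline` (default 0.5, about a quarter of a
typical loaded-gene signal) is the expression floor every gene shares;
genes with no module membership are pure floor + noise, so their mean
equals the configured baseline — this is what the decomposition's
intercept column absorbs. With `baseline=0` and `noise_sigma=0` the
matrix reconstructs the planted factors exactly.

Phenotype: each line's planted RA enrichment score is the mean RA-gene
amplitude over the modules it owns, z-scored across lines; phenotype =
intercept + slope·z + σ·N(0,1) with defaults slope 0.12, intercept 0.30,
σ 0.06, i.e. a population R² of 0.8 on the unit-variance score — a
deliberate mid-range between weak and deterministic coupling, and values
that keep a proportion-type phenotype inside [0, 1]. Kinship is a block
design: the four study donors plus 20 simulated external individuals,
off-diagonal entries N(0.15, 0.10) clipped to [0, 0.6], unit diagonal;
no realistic population genetics is attempted.

External datasets share the study's gene space. *Tissue-like* samples
carry each genetically driven specific-module signal scaled by the
sampled individual's kinship to the owning donor — and never the private
module, so the genetic/epigenetic contrast is planted. *Celltype-like*
samples express random subsets of the dynamic modules. *Promoter-signal*
matrices model a repressive chromatin mark: the marked sibling line's
signal is anticorrelated with the private module's amplitudes (high
signal where the discordant line does *not* overexpress), its sibling's
is flat.

What the generator does not emulate: read-level sequencing noise,
gene–gene correlation beyond module co-membership, batch effects,
single-cell sampling, realistic linkage/kinship structure, or
platform-specific biases of microarray/ChIP data. Passing tests
therefore demonstrate that the pipeline's statistics recover the
structure they target under a faithful low-rank generative model — not
that they are robust to every artefact of real data.

## Problem sizes used in tests and the acceptance script

Factor recovery and classification run the full reference design
(2000 × 54, K = 8, 30 restarts) across five seeds. Projection fidelity
uses a two-replicate design (108 samples), training on replicate 1 and
projecting replicate 2. Permutation calibration uses a 600-gene study
with 200 null datasets × 199 permutations (12 tissue samples each);
power uses 40 signal datasets. Enrichment, era, pHaplo, phenotype and
ICC behavior are measured over 100 simulated studies each, with
enrichment applied to the planted amplitude matrix wrapped as a
decomposition — those checks target the statistics, not the factorizer,
whose recovery is measured separately. ICC recovery uses a 40-donor ×
3-line panel, mirroring a many-donor reference collection at a size
where the estimator's sampling error is the quantity of interest.

## Known limitations

- Multiplicative-update NMF finds local optima; consensus across
  restarts mitigates but does not eliminate this, and highly correlated
  planted modules (|r| ≳ 0.8 between weight rows) may merge.
- The dominance-ratio classification gate (0.6) is a heuristic; studies
  with genuinely mixed line-by-condition patterns will be labeled by
  their dominant factor rather than flagged.
- Permutation inference is calibrated for the z-scored projection path;
  on raw-scaled data it is conservative.
- The donor-specific promotion rule needs ≥2 replicate lines per donor;
  designs without replicate lines cannot distinguish line from donor
  effects.
- Bonferroni corrections throughout are conservative for correlated
  patterns.
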