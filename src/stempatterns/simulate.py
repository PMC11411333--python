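"""Synthetic study generator with known planted structure.

Emulates a multi-line pluripotent stem cell differentiation experiment:
several hPSC lines (some sharing a donor, one "discordant" replicate line
carrying a private epigenetic-like signature) profiled under self-renewal
(SR), neuroectoderm-inducing (NSB) and mesendoderm-inducing (BMP4)
conditions at days 2, 4 and 6.  Expression is built from planted
nonnegative modules: dynamic trajectory modules shared across lines and
stable line/donor-specific modules, with retinoic-acid-responsive-like
(RA-like) and KRAB-ZNF-like gene sets loaded into specific modules,
era-stratified gene ages, haploinsufficiency scores, a lineage-bias
phenotype linearly linked to the planted RA enrichment, and a donor
kinship matrix extended with simulated unrelated/related individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import ExpressionStudy, SampleMeta, StudyError

DYNAMIC_SHAPES = (
    "pluripotency-decay",
    "NSB-early",
    "NSB-late",
    "BMP4-rising",
    "BMP4-early",
)

#: day-course of each dynamic shape, keyed by condition; days are mapped to
#: curve positions in order (first day -> first value).  Off-target
#: conditions sit at a small floor so the module is near-silent there.
_SHAPE_CURVES: dict[str, dict[str, tuple[float, float, float]]] = {
    "pluripotency-decay": {
        "SR": (1.0, 0.92, 0.85),
        "NSB": (1.0, 0.40, 0.15),
        "BMP4": (1.0, 0.33, 0.10),
    },
    "NSB-early": {"NSB": (0.90, 1.0, 0.40)},
    "NSB-late": {"NSB": (0.05, 0.45, 1.0)},
    "BMP4-rising": {"BMP4": (0.10, 0.55, 1.0)},
    "BMP4-early": {"BMP4": (0.90, 1.0, 0.35)},
}
_OFF_CONDITION_FLOOR = 0.04

DEFAULT_LINES = (
    ("L1", "D1"),
    ("L2", "D1"),
    ("L3", "D2"),
    ("L4", "D2"),
    ("L5", "D3"),
    ("L6", "D4"),
)


class ConfigError(ValueError):
    """Raised on an inconsistent simulation configuration."""


@dataclass
class PhenotypeLink:
    """Linear link from planted per-line RA enrichment (z-scored) to phenotype."""

    slope: float = 0.12
    intercept: float = 0.30
    sigma: float = 0.06

    @property
    def population_r_squared(self) -> float:
        """R^2 of the link when the enrichment score has unit variance."""
        v = self.slope**2
        return v / (v + self.sigma**2)


@dataclass
class SimulationConfig:
    """Study design and effect sizes for :func:`simulate_study`.

    Defaults reproduce the reference design: 2000 genes, six lines from
    four donors (one donor with two concordant replicate lines, one with a
    discordant pair), 3 conditions x 3 days x 1 replicate = 54 samples,
    and K_true = 8 modules (5 dynamic + donor + line + private).
    """

    n_genes: int = 2000
    lines: Sequence[tuple[str, str]] = DEFAULT_LINES
    n_replicates: int = 1
    conditions: Sequence[str] = ("SR", "NSB", "BMP4")
    days: Sequence[int] = (2, 4, 6)
    k_dynamic: int = 5
    dynamic_shapes: Sequence[str] = DYNAMIC_SHAPES
    k_line: int = 3
    discordant_line: str | None = "L4"
    singleton_line: str = "L6"
    amplitude_sparsity: float = 0.9
    amplitude_scale: float = 1.0
    baseline: float = 0.5
    set_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"RA-like": 100, "KRAB-like": 100}
    )
    set_target_modules: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "RA-like": ("private",),
            "KRAB-like": ("donor", "line", "private"),
        }
    )
    set_shift: float = 2.0
    era_probs: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {
            "dynamic": (0.45, 0.25, 0.15, 0.10, 0.05),
            "specific": (0.05, 0.10, 0.15, 0.25, 0.45),
            "background": (0.2, 0.2, 0.2, 0.2, 0.2),
        }
    )
    noise_family: str = "lognormal"
    noise_sigma: float = 0.25
    nb_dispersion: float = 10.0
    count_scale: float = 50.0
    phenotype_link: PhenotypeLink = field(default_factory=PhenotypeLink)
    kinship_mean: float = 0.15
    kinship_sd: float = 0.10
    n_external_individuals: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_replicates < 1:
            raise ConfigError("counts must be >= 1")
        if not 0 <= self.amplitude_sparsity < 1:
            raise ConfigError("amplitude_sparsity must be in [0, 1)")
        if self.noise_family not in ("lognormal", "negative-binomial"):
            raise ConfigError(f"unknown noise family {self.noise_family!r}")
        if self.phenotype_link.sigma < 0:
            raise ConfigError("phenotype sigma must be >= 0")
        line_ids = [l for l, _ in self.lines]
        if len(set(line_ids)) != len(line_ids):
            raise ConfigError("duplicate line ids")
        if self.discordant_line is not None and self.discordant_line not in line_ids:
            raise ConfigError(
                f"discordant_line {self.discordant_line!r} not among lines"
            )
        for name, probs in self.era_probs.items():
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigError(f"era_probs[{name!r}] must sum to 1")
        unknown = set(self.dynamic_shapes[: self.k_dynamic]) - set(_SHAPE_CURVES)
        if unknown:
            raise ConfigError(f"unknown dynamic shapes {sorted(unknown)}")

    @property
    def donor_of(self) -> dict[str, str]:
        return {l: d for l, d in self.lines}


@dataclass
class GroundTruth:
    """Planted factors, memberships, phenotypes and kinship for one study."""

    A_true: np.ndarray              # genes x K_true, nonnegative
    P_true: np.ndarray              # K_true x samples, nonnegative
    module_class: list[str]         # per module: dynamic / donor / line / private
    module_owner: list[str | None]  # donor or line id for specific modules
    module_shape: list[str | None]  # dynamic-shape label for dynamic modules
    set_membership: dict[str, list[str]]   # set name -> gene ids
    era: dict[str, int]
    phaplo: dict[str, float]
    phenotype: dict[str, float]            # line -> phenotype value
    line_enrichment: dict[str, float]      # line -> planted RA score (z)
    kinship: "np.ndarray"
    kinship_ids: list[str]
    donor_of: dict[str, str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        if np.any(self.A_true < 0) or np.any(self.P_true < 0):
            raise ConfigError("planted factors must be nonnegative")
        if not np.allclose(self.kinship, self.kinship.T):
            raise ConfigError("kinship must be symmetric")
        if not np.allclose(np.diag(self.kinship), 1.0):
            raise ConfigError("kinship diagonal must be 1")

    @property
    def k_true(self) -> int:
        return self.A_true.shape[1]

    def modules_of_class(self, *classes: str) -> list[int]:
        return [i for i, c in enumerate(self.module_class) if c in classes]

    def kinship_frame(self):
        import pandas as pd

        return pd.DataFrame(self.kinship, index=self.kinship_ids,
                            columns=self.kinship_ids)


# ---------------------------------------------------------------------------
# study simulation
# ---------------------------------------------------------------------------


def _design_grid(cfg: SimulationConfig) -> list[SampleMeta]:
    donor = cfg.donor_of
    out = []
    for line, _ in cfg.lines:
        for cond in cfg.conditions:
            for day in cfg.days:
                for rep in range(1, cfg.n_replicates + 1):
                    out.append(SampleMeta(
                        sample_id=f"{line}_{cond}_d{day}_r{rep}",
                        line_id=line,
                        donor_id=donor[line],
                        condition=cond,
                        day=int(day),
                        replicate=f"r{rep}",
                    ))
    return out


def _dynamic_weight(shape: str, cond: str, day_index: int) -> float:
    curve = _SHAPE_CURVES[shape].get(cond)
    if curve is None:
        return _OFF_CONDITION_FLOOR
    return curve[day_index]


def _specific_module_plan(cfg: SimulationConfig) -> list[tuple[str, str]]:
    """Return (class, owner) for each specific module.

    Default plan: one donor-shared module (first donor with >= 2 concordant
    lines), one line module for a singleton-donor line, one private module
    for the discordant replicate line.  Further modules (k_line > 3) become
    line modules of remaining lines.
    """
    donor = cfg.donor_of
    lines = [l for l, _ in cfg.lines]
    by_donor: dict[str, list[str]] = {}
    for l, d in cfg.lines:
        by_donor.setdefault(d, []).append(l)
    plan: list[tuple[str, str]] = []
    used_lines: set[str] = set()
    if cfg.k_line >= 1:
        shared = next(
            (d for d, ls in by_donor.items()
             if len(ls) >= 2 and cfg.discordant_line not in ls),
            None,
        )
        if shared is not None:
            plan.append(("donor", shared))
            used_lines.update(by_donor[shared])
    if cfg.k_line >= 2 and cfg.singleton_line in lines:
        plan.append(("line", cfg.singleton_line))
        used_lines.add(cfg.singleton_line)
    if cfg.discordant_line is not None and len(plan) < cfg.k_line:
        plan.append(("private", cfg.discordant_line))
        used_lines.add(cfg.discordant_line)
    for l in lines:
        if len(plan) >= cfg.k_line:
            break
        if l not in used_lines:
            plan.append(("line", l))
            used_lines.add(l)
    return plan[: cfg.k_line]


def _apply_noise(clean: np.ndarray, cfg: SimulationConfig,
                 rng: np.random.Generator) -> tuple[np.ndarray, str]:
    if cfg.noise_family == "lognormal":
        if cfg.noise_sigma == 0:
            return clean.copy(), "rpkm"
        s = cfg.noise_sigma
        noise = rng.lognormal(mean=-0.5 * s * s, sigma=s, size=clean.shape)
        return clean * noise, "rpkm"
    # negative binomial via gamma-Poisson mixture; mean = clean * count_scale
    mu = clean * cfg.count_scale
    theta = cfg.nb_dispersion
    lam = rng.gamma(shape=theta, scale=np.maximum(mu, 1e-12) / theta)
    return rng.poisson(lam).astype(float), "counts"


def simulate_study(cfg: SimulationConfig
                   ) -> tuple[ExpressionStudy, GroundTruth]:
    """Simulate an expression study and its ground truth.

    Expression is ``baseline + A_true @ P_true`` perturbed by the
    configured noise family (multiplicative mean-1 lognormal by default, or
    negative-binomial counts).  Reproducible for a fixed ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    samples = _design_grid(cfg)
    n_s = len(samples)
    day_index = {int(d): i for i, d in enumerate(cfg.days)}

    plan = _specific_module_plan(cfg)
    module_class = ["dynamic"] * cfg.k_dynamic + [c for c, _ in plan]
    module_owner: list[str | None] = [None] * cfg.k_dynamic + [o for _, o in plan]
    module_shape: list[str | None] = list(cfg.dynamic_shapes[: cfg.k_dynamic])
    module_shape += [None] * len(plan)
    k_true = len(module_class)

    # --- pattern weights ---------------------------------------------------
    P = np.zeros((k_true, n_s))
    donor = cfg.donor_of
    for k in range(k_true):
        for j, s in enumerate(samples):
            if module_class[k] == "dynamic":
                P[k, j] = _dynamic_weight(module_shape[k], s.condition,
                                          day_index[s.day])
            else:
                owner = module_owner[k]
                owned = (s.donor_id == owner if module_class[k] == "donor"
                         else s.line_id == owner)
                P[k, j] = 1.0 if owned else 0.0

    # --- gene amplitudes ---------------------------------------------------
    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    n_loaded = max(1, int(round((1 - cfg.amplitude_sparsity) * cfg.n_genes)))
    A = np.zeros((cfg.n_genes, k_true))
    for k in range(k_true):
        idx = rng.choice(cfg.n_genes, size=n_loaded, replace=False)
        A[idx, k] = cfg.amplitude_scale * rng.gamma(2.0, 1.0, size=n_loaded)

    # --- planted gene sets -------------------------------------------------
    class_to_modules: dict[str, list[int]] = {}
    for i, c in enumerate(module_class):
        class_to_modules.setdefault(c, []).append(i)
    set_membership: dict[str, list[str]] = {}
    taken: set[int] = set()
    for set_name, size in cfg.set_sizes.items():
        free = np.array(sorted(set(range(cfg.n_genes)) - taken))
        members = rng.choice(free, size=min(size, free.size), replace=False)
        taken.update(int(m) for m in members)
        set_membership[set_name] = [gene_ids[m] for m in sorted(members)]
        for target_class in cfg.set_target_modules.get(set_name, ()):
            for m in class_to_modules.get(target_class, []):
                A[sorted(members), m] += cfg.set_shift * (
                    0.5 + rng.random(len(members))
                )

    # --- era and pHaplo, stratified by each gene's primary module ----------
    primary = np.where(A.max(axis=1) > 0, A.argmax(axis=1), -1)
    era: dict[str, int] = {}
    phaplo: dict[str, float] = {}
    for g in range(cfg.n_genes):
        if primary[g] < 0:
            stratum = "background"
        elif module_class[primary[g]] == "dynamic":
            stratum = "dynamic"
        else:
            stratum = "specific"
        probs = np.asarray(cfg.era_probs[stratum], dtype=float)
        era[gene_ids[g]] = int(rng.choice(5, p=probs)) + 1
        mean = {"dynamic": 0.62, "specific": 0.38, "background": 0.50}[stratum]
        conc = 14.0
        phaplo[gene_ids[g]] = float(
            rng.beta(mean * conc, (1 - mean) * conc)
        )

    # --- phenotype linked to planted RA enrichment -------------------------
    ra_genes = [gene_ids.index(g) for g in set_membership.get("RA-like", [])]
    line_ids = [l for l, _ in cfg.lines]
    raw = np.zeros(len(line_ids))
    for i, l in enumerate(line_ids):
        owned = [
            k for k in range(k_true)
            if (module_class[k] == "donor" and donor[l] == module_owner[k])
            or (module_class[k] in ("line", "private") and l == module_owner[k])
        ]
        if owned and ra_genes:
            raw[i] = np.mean([A[ra_genes, k].mean() for k in owned])
    sd = raw.std(ddof=0)
    z = (raw - raw.mean()) / sd if sd > 0 else raw * 0.0
    link = cfg.phenotype_link
    pheno = link.intercept + link.slope * z + link.sigma * rng.standard_normal(
        len(line_ids)
    )
    phenotype = dict(zip(line_ids, pheno.tolist()))
    line_enrichment = dict(zip(line_ids, z.tolist()))

    # --- kinship over study donors + simulated external individuals --------
    donors = sorted(set(donor.values()))
    ext = [f"EXT{i:02d}" for i in range(1, cfg.n_external_individuals + 1)]
    ids = donors + ext
    n_ind = len(ids)
    K = np.zeros((n_ind, n_ind))
    tri = np.triu_indices(n_ind, k=1)
    vals = np.clip(rng.normal(cfg.kinship_mean, cfg.kinship_sd,
                              size=len(tri[0])), 0.0, 0.6)
    K[tri] = vals
    K = K + K.T
    np.fill_diagonal(K, 1.0)

    # --- expression --------------------------------------------------------
    clean = cfg.baseline + A @ P
    values, scale = _apply_noise(clean, cfg, rng)

    study = ExpressionStudy(values, gene_ids, samples, scale=scale)
    truth = GroundTruth(
        A_true=A, P_true=P,
        module_class=module_class, module_owner=module_owner,
        module_shape=module_shape,
        set_membership=set_membership, era=era, phaplo=phaplo,
        phenotype=phenotype, line_enrichment=line_enrichment,
        kinship=K, kinship_ids=ids, donor_of=dict(donor),
        gene_ids=gene_ids,
    )
    return study, truth


# ---------------------------------------------------------------------------
# external datasets for projection
# ---------------------------------------------------------------------------

EXTERNAL_KINDS = ("tissue-like", "celltype-like", "promoter-signal")


def simulate_external_dataset(truth: GroundTruth, kind: str, n_samples: int,
                              seed: int, *, noise_sigma: float = 0.25,
                              signal_scale: float = 1.0,
                              baseline: float = 0.5) -> ExpressionStudy:
    """Simulate an external dataset sharing the study's gene space.

    ``tissue-like``
        Bulk samples from individuals in the kinship panel; each carries
        the genetically-driven specific-module signal of every study donor
        scaled by its kinship to that donor.  The private (epigenetic)
        module is carried by no tissue sample.
    ``celltype-like``
        Samples expressing random subsets of the dynamic modules.
    ``promoter-signal``
        Promoter-level repressive-mark signal for a pair of replicate
        lines: the marked line's signal is anticorrelated with the private
        module's amplitudes (repression of genes the discordant line
        overexpresses), the other line's is flat.
    """
    if kind not in EXTERNAL_KINDS:
        raise StudyError(f"unknown external dataset kind {kind!r}")
    rng = np.random.default_rng(seed)
    n_genes = len(truth.gene_ids)
    genetic = truth.modules_of_class("donor", "line")
    dynamic = truth.modules_of_class("dynamic")
    private = truth.modules_of_class("private")
    kin = truth.kinship_frame()

    values = np.zeros((n_genes, n_samples))
    samples: list[SampleMeta] = []

    if kind == "tissue-like":
        for j in range(n_samples):
            ind = truth.kinship_ids[j % len(truth.kinship_ids)]
            x = np.full(n_genes, baseline)
            for k in genetic:
                owner_donor = truth.module_owner[k]
                if truth.module_class[k] == "line":
                    owner_donor = truth.donor_of[truth.module_owner[k]]
                x = x + signal_scale * kin.loc[ind, owner_donor] * truth.A_true[:, k]
            values[:, j] = x
            samples.append(SampleMeta(
                sample_id=f"tissue_{ind}_s{j}", line_id=ind, donor_id=ind,
                condition="other", day=0))
    elif kind == "celltype-like":
        for j in range(n_samples):
            active = [k for k in dynamic if rng.random() < 0.5] or dynamic[:1]
            x = np.full(n_genes, baseline)
            for k in active:
                x = x + signal_scale * rng.uniform(0.5, 1.5) * truth.A_true[:, k]
            values[:, j] = x
            samples.append(SampleMeta(
                sample_id=f"celltype_s{j}", line_id=f"ct{j}",
                donor_id=f"ct{j}", condition="other", day=0))
    else:  # promoter-signal
        m = private[0] if private else genetic[0]
        amp = truth.A_true[:, m]
        top = baseline + signal_scale * (amp.max() - amp)  # repressed in marked line
        owner = truth.module_owner[m]
        for j in range(n_samples):
            marked = j % 2 == 0
            line = f"{owner}_sibling" if marked else owner
            values[:, j] = top if marked else baseline + signal_scale * amp.mean()
            samples.append(SampleMeta(
                sample_id=f"chip_{line}_s{j}", line_id=line, donor_id=line,
                condition="other", day=0))

    if noise_sigma > 0 and n_samples > 0:
        values = values * rng.lognormal(-0.5 * noise_sigma**2, noise_sigma,
                                        size=values.shape)
    return ExpressionStudy(values, list(truth.gene_ids), samples, scale="rpkm")


def simulate_donor_scores(n_donors: int, lines_per_donor: int,
                          donor_variance_fraction: float, seed: int
                          ) -> tuple[np.ndarray, list[str]]:
    """Per-line scores with a planted donor variance fraction (for ICC checks)."""
    rng = np.random.default_rng(seed)
    f = donor_variance_fraction
    effects = np.sqrt(f) * rng.standard_normal(n_donors)
    scores = np.repeat(effects, lines_per_donor) + np.sqrt(1 - f) * (
        rng.standard_normal(n_donors * lines_per_donor)
    )
    donors = [f"D{i}" for i in range(n_donors) for _ in range(lines_per_donor)]
    return scores, donors


def truth_decomposition(truth: GroundTruth, study: ExpressionStudy):
    """Wrap the planted factors as a :class:`PatternDecomposition`.

    Produces what an ideal factorization of ``study`` would return: the
    planted amplitudes in the row-scaled gene space, the planted weights,
    and the study's per-gene scaling — useful for exercising downstream
    stages independently of factorization error.
    """
    from .decompose import PatternDecomposition, _scale_rows

    _, scaling = _scale_rows(study.values)
    A = truth.A_true / scaling[:, None]
    # per-gene expression floor left after removing the planted modules
    floor = np.clip(
        (study.values - truth.A_true @ truth.P_true).mean(axis=1), 0.0, None)
    return PatternDecomposition(
        A=A, P=truth.P_true.copy(), K=truth.k_true,
        gene_ids=list(truth.gene_ids), sample_ids=study.sample_ids,
        row_scaling=scaling, objective_trace=[0.0],
        restart_stability=np.ones(truth.k_true), seed=0,
        intercept=floor / scaling)
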