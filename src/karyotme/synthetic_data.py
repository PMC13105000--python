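"""Seeded simulator of linked copy-number / expression / immune / survival
cohorts with planted effects.

The generator emulates the statistical structure the association framework
assumes, not real genomes: per-arm log2 copy number is a mixture of a
copy-neutral state (Gaussian around 0) and an altered state (uniform
magnitude 0.2-0.8 with the arm's dominant sign); gene copy number inherits
its arm value plus focal noise; gene expression follows a linear
dosage-response on copy number with Gaussian noise on the log scale. A
latent immune-activity variable with standard-logistic noise carries the
planted immune effects — so a planted arm effect corresponds exactly to a
logistic model on the cold/hot indicator — and drives the expression of the
seven cytotoxic signature genes. Cell-type scores are linear in copy number
with planted slopes. Survival times are exponential proportional-hazards
with planted per-feature log hazard ratios and random fractional censoring.

Effect-size units: planted immune effects are log-odds on the cold class
per *typical alteration* (a log2 CN excursion of 0.4, the mean altered
magnitude); cell-type slopes are score units per unit log2 CN; survival
effects are log hazard ratios for carrying the alteration.

Everything is reproducible from the mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import ARM_NAMES, CopyNumberProfile, ExpressionMatrix
from .errors import ConfigError
from .immune_scoring import CELL_TYPES, CYTOTOXIC_SIGNATURE, CellTypeScoreTable

#: log2 CN excursion of a "typical" alteration; planted immune log-odds
#: effects are expressed per this excursion.
TYPICAL_ALTERATION = 0.4


@dataclass(frozen=True)
class PlantedGene:
    """A planted iOG/TiSG-style gene: dosage slope and immune coupling.

    ``focal_sd`` is the gene's own copy-number variability on top of its arm
    (default 0.3, a focal event). Without it the driver's copy number would
    be near-identical to every neighbor on the arm and per-gene recovery
    would be ill-posed.
    """

    gene_id: str
    dna_rna_slope: float
    rna_is_slope: float
    focal_sd: float = 0.3


@dataclass
class SimulationConfig:
    """Parameters of one simulated cohort. ``seed`` is mandatory."""

    seed: int
    n_samples: int = 300
    n_arms: int = 10
    n_genes_per_arm: int = 20
    altered_fraction: float = 0.3
    magnitude_range: tuple = (0.2, 0.8)
    neutral_sd: float = 0.05
    gene_focal_sd: float = 0.05
    dna_rna_slope: float = 1.0
    expr_noise_sd: float = 0.5
    signature_noise_sd: float = 0.3
    celltype_noise_sd: float = 1.0
    #: (feature, direction, log-odds effect on cold per typical alteration)
    planted_is_effects: list = field(default_factory=list)
    #: (feature, cell_type, slope per unit log2 CN)
    planted_celltype_effects: list = field(default_factory=list)
    #: planted genes (see PlantedGene); gene ids must be ``<arm>G<nnn>``
    planted_genes: list = field(default_factory=list)
    #: (feature, direction, log hazard ratio for carriers)
    planted_survival_effects: list = field(default_factory=list)
    median_survival: float = 24.0  # months, baseline
    censoring_rate: float = 0.3
    survival_distribution: str = "exponential"  # or "weibull"
    weibull_shape: float = 1.5
    arm_directions: dict = field(default_factory=dict)
    tumor_type: str = "SIM"

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if not (0 <= self.censoring_rate < 1):
            raise ConfigError("censoring_rate must lie in [0, 1)")
        if self.survival_distribution not in ("exponential", "weibull"):
            raise ConfigError("survival_distribution must be exponential|weibull")
        self.arms = list(ARM_NAMES[: self.n_arms])
        # default dominant direction alternates gain/loss along arms
        for i, arm in enumerate(self.arms):
            self.arm_directions.setdefault(arm, "gain" if i % 2 == 0 else "loss")
        declared = set(self.arms)
        for feature, direction, _ in self.planted_is_effects:
            if feature not in declared:
                raise ConfigError(f"planted IS effect on undeclared feature {feature!r}")
            if direction not in ("gain", "loss"):
                raise ConfigError(f"bad direction {direction!r}")
        for feature, _, _ in self.planted_celltype_effects:
            if feature not in declared:
                raise ConfigError(
                    f"planted cell-type effect on undeclared feature {feature!r}"
                )
        for feature, direction, _ in self.planted_survival_effects:
            if feature not in declared:
                raise ConfigError(
                    f"planted survival effect on undeclared feature {feature!r}"
                )
        for pg in self.planted_genes:
            arm = pg.gene_id.split("G")[0]
            if arm not in declared:
                raise ConfigError(f"planted gene {pg.gene_id!r} on undeclared arm")


@dataclass
class SimulatedCohort:
    """One simulated cohort plus its ground truth."""

    config: SimulationConfig
    arm_profile: CopyNumberProfile
    gene_profile: CopyNumberProfile
    expression: ExpressionMatrix
    celltypes: CellTypeScoreTable
    clinical: pd.DataFrame  # indexed by sample_id
    altered: pd.DataFrame   # samples x arms, {-1, 0, +1} true alteration state
    gene_arms: pd.Series    # gene -> arm


def gene_ids_for_arm(arm: str, n: int) -> list[str]:
    return [f"{arm}G{i:03d}" for i in range(n)]


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Draw one cohort from the generative model described in the module
    docstring. Identical configs (same seed) give bitwise-identical output."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    samples = [f"S{i:04d}" for i in range(n)]
    lo, hi = config.magnitude_range

    # --- arm-level copy number -------------------------------------------
    arm_cn = np.empty((n, len(config.arms)))
    altered = np.zeros((n, len(config.arms)), dtype=int)
    for j, arm in enumerate(config.arms):
        sign = 1.0 if config.arm_directions[arm] == "gain" else -1.0
        carrier = rng.random(n) < config.altered_fraction
        cn = rng.normal(0.0, config.neutral_sd, n)
        cn[carrier] = sign * rng.uniform(lo, hi, carrier.sum())
        arm_cn[:, j] = cn
        altered[:, j] = np.where(carrier, int(sign), 0)
    arm_values = pd.DataFrame(arm_cn, index=samples, columns=config.arms)

    # --- gene-level copy number ------------------------------------------
    gene_arms = {}
    for arm in config.arms:
        for g in gene_ids_for_arm(arm, config.n_genes_per_arm):
            gene_arms[g] = arm
    genes = list(gene_arms)
    focal_sd = {pg.gene_id: pg.focal_sd for pg in config.planted_genes}
    gene_cn = np.column_stack([
        arm_values[gene_arms[g]].to_numpy()
        + rng.normal(0.0, focal_sd.get(g, config.gene_focal_sd), n)
        for g in genes
    ])
    gene_values = pd.DataFrame(gene_cn, index=samples, columns=genes)

    # --- gene expression (log-scale dosage response) ----------------------
    planted_by_gene = {pg.gene_id: pg for pg in config.planted_genes}
    expr = {}
    for g in genes:
        slope = planted_by_gene[g].dna_rna_slope if g in planted_by_gene \
            else config.dna_rna_slope
        baseline = rng.uniform(3.0, 7.0)
        expr[g] = np.clip(
            baseline + slope * gene_values[g].to_numpy()
            + rng.normal(0.0, config.expr_noise_sd, n),
            0.0, None,
        )

    # --- latent immune activity ------------------------------------------
    activity = rng.logistic(0.0, 1.0, n)
    for feature, direction, effect in config.planted_is_effects:
        s = 1.0 if direction == "gain" else -1.0
        activity -= (effect / TYPICAL_ALTERATION) * s * arm_values[feature].to_numpy()
    for pg in config.planted_genes:
        e = expr[pg.gene_id]
        sd = e.std()
        if sd > 0:
            activity += pg.rna_is_slope * (e - e.mean()) / sd
    for g in CYTOTOXIC_SIGNATURE:
        expr[g] = np.clip(
            8.0 + activity + rng.normal(0.0, config.signature_noise_sd, n),
            0.0, None,
        )
    expression = ExpressionMatrix(pd.DataFrame(expr, index=samples))

    # --- cell-type scores --------------------------------------------------
    ct_effects: dict = {}
    for feature, cell_type, slope in config.planted_celltype_effects:
        ct_effects.setdefault(cell_type, []).append((feature, slope))
    ct = {}
    for cell_type in CELL_TYPES:
        score = 5.0 + rng.normal(0.0, config.celltype_noise_sd, n)
        for feature, slope in ct_effects.get(cell_type, []):
            score += slope * arm_values[feature].to_numpy()
        ct[cell_type] = np.clip(score, 0.0, None)
    celltypes = CellTypeScoreTable(pd.DataFrame(ct, index=samples))

    # --- survival ----------------------------------------------------------
    log_hr = np.zeros(n)
    for feature, direction, lhr in config.planted_survival_effects:
        s = 1 if direction == "gain" else -1
        carrier = altered[:, config.arms.index(feature)] == s
        log_hr[carrier] += lhr
    lam0 = np.log(2.0) / config.median_survival
    rate = lam0 * np.exp(log_hr)
    if config.survival_distribution == "exponential":
        times = rng.exponential(1.0 / rate)
    else:
        k = config.weibull_shape
        times = rng.weibull(k, n) / np.power(rate, 1.0 / k)
    censored = rng.random(n) < config.censoring_rate
    os_time = np.where(censored, times * rng.uniform(0.0, 1.0, n), times)

    clinical = pd.DataFrame({
        "tumor_type": config.tumor_type,
        "os_time": os_time,
        "os_event": ~censored,
        "tmb": np.exp(rng.normal(1.5, 1.0, n)),
        "pdl1_positive": rng.random(n) < 0.4,
        "cd8_fraction": rng.beta(2.0, 8.0, n),
        "b_fraction": rng.beta(2.0, 12.0, n),
        "purity": 1.0,
        "ploidy": 2.0,
    }, index=pd.Index(samples, name="sample_id"))

    return SimulatedCohort(
        config=config,
        arm_profile=CopyNumberProfile(level="arm", values=arm_values,
                                      metadata={"seed": config.seed}),
        gene_profile=CopyNumberProfile(level="gene", values=gene_values,
                                       metadata={"seed": config.seed}),
        expression=expression,
        celltypes=celltypes,
        clinical=clinical,
        altered=pd.DataFrame(altered, index=samples, columns=config.arms),
        gene_arms=pd.Series(gene_arms, name="arm"),
    )


def simulate_gold_standard(
    n_genes: int = 400,
    n_positives: int = 40,
    n_features: int = 6,
    separation: float = 2.0,
    seed: int = 0,
):
    """Per-gene feature table plus a positive gene list for classifier tests.

    Positives have their first ``ceil(n_features/2)`` feature means shifted
    by ``separation`` standard deviations; ``separation=0`` gives a pure
    null. Returns ``(features, positives)``.
    """
    if separation < 0:
        raise ConfigError("separation must be nonnegative")
    if n_positives < 10:
        raise ConfigError("need at least 10 positives")
    rng = np.random.default_rng(seed)
    genes = [f"GS{i:04d}" for i in range(n_genes)]
    X = rng.normal(0.0, 1.0, (n_genes, n_features))
    positives = list(rng.choice(genes, size=n_positives, replace=False))
    pos_idx = [genes.index(g) for g in positives]
    n_informative = (n_features + 1) // 2
    X[pos_idx, :n_informative] += separation
    features = pd.DataFrame(
        X, index=pd.Index(genes, name="gene_id"),
        columns=[f"f{i}" for i in range(n_features)],
    )
    return features, positives


def simulate_concordant_genes(
    n_genes: int = 200,
    n_samples: int = 100,
    arm: str = "1q",
    concordant_fraction: float = 1.0,
    dosage_slope: float = 2.0,
    expr_noise_sd: float = 0.3,
    seed: int = 0,
):
    """Matched gene-level copy-number and expression for panel selection.

    The first ``concordant_fraction`` of genes follow a linear dosage
    response (high DNA-RNA concordance); the rest are expression noise.
    Returns ``(cn_profile, expression)`` with genes named ``<arm>G<nnn>``.
    """
    rng = np.random.default_rng(seed)
    samples = [f"S{i}" for i in range(n_samples)]
    genes = gene_ids_for_arm(arm, n_genes)
    n_conc = int(round(concordant_fraction * n_genes))
    cn, expr = {}, {}
    for i, g in enumerate(genes):
        dosage = rng.normal(0.0, 0.4, n_samples)
        cn[g] = dosage
        slope = dosage_slope if i < n_conc else 0.0
        expr[g] = np.clip(
            5.0 + slope * dosage + rng.normal(0.0, expr_noise_sd, n_samples),
            0.0, None,
        )
    return (
        CopyNumberProfile(level="gene",
                          values=pd.DataFrame(cn, index=samples)),
        ExpressionMatrix(pd.DataFrame(expr, index=samples)),
    )


def simulate_proportions(
    n_patients: int = 20,
    cell_types=("cd8_t", "nk", "b_cell"),
    altered_fraction: float = 0.5,
    effect: float = -0.1,
    affected_cell_type: str = "cd8_t",
    seed: int = 0,
):
    """Per-patient cell-type proportion table with a planted SCNA effect.

    Returns ``(proportions, status)``: fractions in [0, 1] per patient and a
    boolean altered-status series; altered patients have the affected cell
    type's mean fraction shifted by ``effect``.
    """
    rng = np.random.default_rng(seed)
    patients = [f"P{i:02d}" for i in range(n_patients)]
    status = pd.Series(rng.random(n_patients) < altered_fraction, index=patients)
    base = {ct: np.clip(rng.normal(0.25, 0.05, n_patients), 0.01, 0.99)
            for ct in cell_types}
    base[affected_cell_type] = np.clip(
        base[affected_cell_type] + effect * status.to_numpy(), 0.005, 0.995
    )
    return pd.DataFrame(base, index=patients), status
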