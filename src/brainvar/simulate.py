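"""Synthetic genotype / phenotype / expression / motif fixtures.

Every downstream stage of the pipeline is exercised desk-scale on data from
these generators: LD-blocked genotypes in Hardy-Weinberg proportions,
ROI phenotypes with additive per-allele effects and covariate structure,
multi-region expression with a planted eQTL and a TF->target correlation,
and position weight matrices with controllable column information content.
All generators are deterministic given their seed.

LD is induced through a Gaussian copula: haplotypes within a block share a
latent exchangeable-correlation normal vector thresholded at each SNP's
allele-frequency quantile, so the target pairwise correlation is set by
``within_block_r`` while marginal allele frequencies are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "ExpressionSimConfig",
    "simulate_genotypes",
    "simulate_roi_phenotypes",
    "simulate_expression",
    "simulate_pwm_and_flanks",
]

VOLUME_ROIS = ["lh.insula", "rh.ACC", "CC", "lh.tempWM", "lh.SMG"]
CORTICAL_ROIS = ["lh.insula", "rh.ACC", "lh.SMG"]
TRAITS = ("volume", "surface_area", "thickness")

#: covariate columns every simulated cohort table carries
COVARIATE_LEVELS = {
    "sex": ["female", "male"],
    "ethnicity": ["african", "asian", "european"],
    "handedness": ["left", "right"],
    "scanner_field": ["1.5T", "3T"],
}


@dataclass
class SimulationConfig:
    """Cohort-scale genotype/phenotype simulation settings.

    ``effect_map`` plants additive per-allele effects: each entry is
    ``(snp_index, roi, trait, beta)`` in trait units per minor allele.
    ``covariate_effects`` maps covariate name to a slope (continuous) or a
    per-level-index step (categorical).
    """

    n_subjects: int = 100
    n_snps: int = 10
    maf_range: tuple[float, float] = (0.15, 0.5)
    ld_block_sizes: list[int] = field(default_factory=list)
    within_block_r: float = 0.0
    effect_map: list[tuple[int, str, str, float]] = field(default_factory=list)
    covariate_effects: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.ld_block_sizes:
            self.ld_block_sizes = [1] * self.n_snps
        if self.n_subjects < 10:
            raise ValueError(f"n_subjects must be >= 10, got {self.n_subjects}")
        if sum(self.ld_block_sizes) != self.n_snps:
            raise ValueError(
                f"ld_block_sizes sum to {sum(self.ld_block_sizes)}, expected n_snps={self.n_snps}"
            )
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if not (0 <= self.within_block_r <= 1):
            raise ValueError(f"within_block_r must be in [0, 1], got {self.within_block_r}")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")
        if not (0 <= self.missing_rate < 1):
            raise ValueError(f"missing_rate must be in [0, 1), got {self.missing_rate}")


@dataclass
class ExpressionSimConfig:
    """Multi-region expression simulation with a planted eQTL and TF driver."""

    n_individuals: int = 134
    regions_per_individual: int = 10
    eqtl_beta: float = 0.0
    tf_target_r: float = 0.0
    noise_sd: float = 1.0
    region_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 10:
            raise ValueError(f"n_individuals must be >= 10, got {self.n_individuals}")
        if self.regions_per_individual < 1:
            raise ValueError(
                f"regions_per_individual must be >= 1, got {self.regions_per_individual}"
            )
        if abs(self.tf_target_r) > 1:
            raise ValueError(f"|tf_target_r| must be <= 1, got {self.tf_target_r}")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw LD-blocked diploid genotypes in Hardy-Weinberg proportions.

    2 * n_subjects haplotypes are generated independently and paired at
    random order, so HWE holds by construction; blocks are independent.
    """
    rng = np.random.default_rng(config.seed)
    n_hap = 2 * config.n_subjects
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=config.n_snps)
    haps = np.empty((n_hap, config.n_snps), dtype=np.int8)
    start = 0
    r = config.within_block_r
    for size in config.ld_block_sizes:
        cols = slice(start, start + size)
        # exchangeable latent correlation r via a shared factor
        shared = rng.standard_normal((n_hap, 1))
        own = rng.standard_normal((n_hap, size))
        z = np.sqrt(r) * shared + np.sqrt(1.0 - r) * own
        thresh = stats.norm.ppf(mafs[cols])
        haps[:, cols] = (z < thresh).astype(np.int8)
        start += size
    dosages = (haps[::2] + haps[1::2]).astype(float)
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = np.nan
    bases = np.array(list("ACGT"))
    labels = [tuple(rng.choice(bases, size=2, replace=False)) for _ in range(config.n_snps)]
    return GenotypeMatrix(
        subject_ids=[f"S{i:05d}" for i in range(config.n_subjects)],
        snp_ids=[f"rs{i + 1:04d}" for i in range(config.n_snps)],
        dosages=dosages,
        allele_labels=labels,
    )


def simulate_covariates(n_subjects: int, rng: np.random.Generator) -> pd.DataFrame:
    age = rng.uniform(18, 65, size=n_subjects).round(1)
    cols: dict[str, np.ndarray] = {"age": age}
    for name, levels in COVARIATE_LEVELS.items():
        cols[name] = rng.choice(levels, size=n_subjects)
    return pd.DataFrame(cols, index=[f"S{i:05d}" for i in range(n_subjects)])


def simulate_roi_phenotypes(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ROI phenotype and covariate tables with planted additive SNP effects.

    Each trait:ROI column is intercept + sum of planted beta x dosage +
    covariate contributions + N(0, noise_sd); a trait-matched global column
    (``<trait>:global``) is generated per trait. Missing dosages contribute 0
    to the planted effect (the phenotype stays defined for every subject).
    Returns ``(phenotypes, covariates)`` indexed by subject ID.
    """
    if genotypes.n_subjects != config.n_subjects:
        raise ValueError(
            f"genotypes have {genotypes.n_subjects} subjects, config says {config.n_subjects}"
        )
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_subjects
    covariates = simulate_covariates(n, rng)
    covariates.index = pd.Index(genotypes.subject_ids, name="subject_id")

    cov_contrib = np.zeros(n)
    for name, slope in config.covariate_effects.items():
        if name == "age":
            cov_contrib = cov_contrib + slope * covariates["age"].to_numpy(float)
        elif name in COVARIATE_LEVELS:
            codes = pd.Categorical(
                covariates[name], categories=COVARIATE_LEVELS[name]
            ).codes.astype(float)
            cov_contrib = cov_contrib + slope * codes
        else:
            raise ValueError(f"covariate_effects references unknown covariate {name!r}")

    effects: dict[tuple[str, str], np.ndarray] = {}
    for snp_index, roi, trait, beta in config.effect_map:
        if not (0 <= snp_index < genotypes.n_snps):
            raise ValueError(f"effect_map references unknown SNP index {snp_index}")
        if trait not in TRAITS:
            raise ValueError(f"effect_map references unknown trait {trait!r}")
        rois = VOLUME_ROIS if trait == "volume" else CORTICAL_ROIS
        if roi not in rois:
            raise ValueError(f"effect_map references unknown ROI {roi!r} for trait {trait!r}")
        g = np.nan_to_num(genotypes.dosages[:, snp_index])
        key = (trait, roi)
        effects[key] = effects.get(key, np.zeros(n)) + beta * g

    pheno: dict[str, np.ndarray] = {}
    for trait in TRAITS:
        rois = VOLUME_ROIS if trait == "volume" else CORTICAL_ROIS
        global_col = 100.0 + 10.0 * rng.standard_normal(n)
        pheno[f"{trait}:global"] = global_col
        for roi in rois:
            y = (
                50.0
                + effects.get((trait, roi), 0.0)
                + cov_contrib
                + 0.2 * (global_col - 100.0)
                + config.noise_sd * rng.standard_normal(n)
            )
            pheno[f"{trait}:{roi}"] = y
    phenotypes = pd.DataFrame(pheno, index=covariates.index)
    return phenotypes, covariates


@dataclass
class ExpressionBundle:
    """Sample x probe expression with sample->individual/region maps."""

    values: pd.DataFrame  # samples x probes
    sample_map: pd.DataFrame  # sample_id, individual_id, region
    individual_ids: list[str]


def simulate_expression(
    genotypes: GenotypeMatrix, config: ExpressionSimConfig, snp: str | None = None
) -> ExpressionBundle:
    """Per-individual expression with a planted linear eQTL and TF driver.

    The target probe's individual-level value is
    ``5 + eqtl_beta * dosage + lam * TF + N(0, noise_sd)`` where TF expression
    is standard normal and ``lam`` is chosen so the population target-TF
    Pearson correlation equals ``tf_target_r``. Region-level samples add
    N(0, region_noise_sd) around the individual value.
    """
    if genotypes.n_subjects != config.n_individuals:
        raise ValueError(
            f"genotypes have {genotypes.n_subjects} subjects, config says {config.n_individuals}"
        )
    rng = np.random.default_rng(config.seed + 2)
    snp = snp or genotypes.snp_ids[0]
    g = np.nan_to_num(genotypes.dosage(snp))
    n = config.n_individuals

    tf = rng.standard_normal(n)
    rho = config.tf_target_r
    var_rest = config.eqtl_beta**2 * g.var() + config.noise_sd**2
    if abs(rho) >= 1.0:
        lam = 1.0 if rho > 0 else -1.0
        noise = np.zeros(n)
        target = 5.0 + lam * tf
    else:
        # corr(target, tf) = lam / sqrt(lam^2 + var_rest)  =>  solve for lam
        lam = 0.0 if rho == 0 else np.sign(rho) * np.sqrt(rho**2 * var_rest / (1 - rho**2))
        noise = config.noise_sd * rng.standard_normal(n)
        target = 5.0 + config.eqtl_beta * g + lam * tf + noise
    tf_expr = 5.0 + tf

    individual_ids = [f"I{i:04d}" for i in range(n)]
    regions = [f"region{j:02d}" for j in range(config.regions_per_individual)]
    rows, sample_ids, map_rows = [], [], []
    for i, ind in enumerate(individual_ids):
        for region in regions:
            eps_t = (
                0.0
                if config.regions_per_individual == 1
                else config.region_noise_sd * rng.standard_normal()
            )
            eps_f = (
                0.0
                if config.regions_per_individual == 1
                else config.region_noise_sd * rng.standard_normal()
            )
            sid = f"{ind}_{region}"
            sample_ids.append(sid)
            map_rows.append({"sample_id": sid, "individual_id": ind, "region": region})
            rows.append({"target_probe": target[i] + eps_t, "tf_probe": tf_expr[i] + eps_f})
    values = pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample_id"))
    return ExpressionBundle(values, pd.DataFrame(map_rows), individual_ids)


def _two_base_column(target_ic: float) -> np.ndarray:
    """Column (p, q, q, q)/permutations with IC = 2 + sum p log2 p = target_ic."""
    if not (0.0 <= target_ic <= 2.0):
        raise ValueError(f"target_ic must be in [0, 2] bits, got {target_ic}")
    if target_ic == 2.0:
        return np.array([1.0, 0.0, 0.0, 0.0])

    def ic(p: float) -> float:
        q = (1.0 - p) / 3.0
        h = -p * np.log2(p) - (3 * q * np.log2(q) if q > 0 else 0.0)
        return 2.0 - h

    p = optimize.brentq(lambda p: ic(p) - target_ic, 0.25, 1.0 - 1e-12, xtol=1e-12)
    q = (1.0 - p) / 3.0
    return np.array([p, q, q, q])


@dataclass
class VariantContext:
    variant_id: str
    alleles: tuple[str, str]
    flank_5p: str
    flank_3p: str
    variable_offset: int = 50

    def __post_init__(self) -> None:
        if len(self.flank_5p) != 50 or len(self.flank_3p) != 50:
            raise ValueError("flanks must each be exactly 50 bases")
        if self.alleles[0] == self.alleles[1]:
            raise ValueError("alleles must differ")

    def sequence(self, allele: str) -> str:
        if allele not in self.alleles:
            raise ValueError(f"allele {allele!r} not in {self.alleles}")
        return self.flank_5p + allele + self.flank_3p


def simulate_pwm_and_flanks(length: int, target_ic: float, seed: int):
    """A PWM with a chosen-IC column plus a per-allele flank pair.

    The designated column is the central one; the returned variant's first
    allele is that column's consensus base (embedded in a 101-base context so
    that the motif's consensus appears exactly at the variant), the second is
    the column's least-preferred base. Returns ``(pwm, context, column)``.
    """
    from .motifs import PWM  # local import to avoid a cycle

    if length < 4:
        raise ValueError(f"length must be >= 4, got {length}")
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    col = length // 2
    probs = np.empty((4, length))
    for j in range(length):
        if j == col:
            p = _two_base_column(target_ic)
        else:
            # sharp random column so the consensus is unambiguous
            p = rng.dirichlet([0.3] * 4)
            p = p * 0.1
            p[rng.integers(4)] += 0.9
            p /= p.sum()
        probs[:, j] = p[rng.permutation(4)] if j == col else p
    # the JASPAR-style pseudocount keeps every log-odds finite when a column
    # has structural zeros (e.g. target_ic = 2)
    counts = probs * 1000.0
    pwm = PWM(name=f"SIM{seed}", counts=counts, pseudocount=0.8)

    consensus = "".join(bases[int(np.argmax(probs[:, j]))] for j in range(length))
    ref = consensus[col]
    alt = bases[int(np.argmin(probs[:, col]))]
    if alt == ref:  # degenerate (uniform column): pick any other base
        alt = next(b for b in bases if b != ref)
    flank_5p = "".join(rng.choice(list(bases), size=50))
    flank_3p = "".join(rng.choice(list(bases), size=50))
    # embed the consensus so that its designated column sits on the variant
    flank_5p = flank_5p[: 50 - col] + consensus[:col]
    flank_3p = consensus[col + 1 :] + flank_3p[length - col - 1 :]
    context = VariantContext(
        variant_id=f"var{seed}", alleles=(ref, alt), flank_5p=flank_5p, flank_3p=flank_3p
    )
    return pwm, context, col
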