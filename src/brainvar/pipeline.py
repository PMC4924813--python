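"""End-to-end orchestration: simulate -> QC/tag -> association -> eQTL ->
TF screen -> motif scan -> prioritization.

Each stage reads only prior-stage outputs (plain TSV/VCF/FASTA/PFM text with
documented schemas) and the whole run is reproducible from the config plus
seed; a manifest records the config echo, package version, per-stage output
digests and seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io as bio
from .association import (
    AssocModelSpec, DISCOVERY_COVARIATES, VALIDATION_COVARIATES,
    pairwise_scan, permutation_test,
)
from .eqtl import average_by_individual, fit_eqtl, tf_correlation_screen
from .genotypes import GenotypeMatrix, greedy_tag_selection, qc_report, r2_matrix
from .motifs import differential_binding, fold_affinity, prioritize_tf
from .simulate import (
    ExpressionSimConfig, SimulationConfig,
    simulate_expression, simulate_genotypes, simulate_pwm_and_flanks,
    simulate_roi_phenotypes,
)

log = logging.getLogger("brainvar")

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "validate_inputs"]

STAGES = ("simulate", "qc", "tag", "assoc", "eqtl", "tfscreen", "tfscan", "prioritize")
_STAGE_DEPS = {
    "qc": ("simulate",),
    "tag": ("qc",),
    "assoc": ("simulate",),
    "eqtl": ("simulate",),
    "tfscreen": ("simulate",),
    "tfscan": ("simulate",),
    "prioritize": ("eqtl", "tfscreen", "tfscan"),
}


@dataclass
class PipelineConfig:
    """Run configuration; thresholds default to the study's printed values."""

    stages: list[str] = field(default_factory=lambda: list(STAGES))
    seed: int = 0
    out_dir: str = "brainvar_out"
    # synthetic-data settings
    n_subjects: int = 100
    n_snps: int = 10
    n_individuals: int = 134
    regions_per_individual: int = 10
    planted_snp_index: int = 0
    planted_roi: str = "lh.SMG"
    planted_trait: str = "surface_area"
    planted_beta: float = 0.0
    eqtl_beta: float = 0.0
    tf_target_r: float = 0.0
    # analysis settings
    trait: str = "surface_area"
    n_perm: int = 1000
    correction_mode: str = "per_snp"
    maf_min: float = 0.15
    hwe_alpha: float = 0.001
    r2_tag: float = 0.8
    match_threshold: float = 0.8
    ic_min: float = 1.0
    alpha: float = 0.05
    n_tests: int = 127
    motif_length: int = 8
    motif_ic: float = 1.5
    validation_model: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        for name, val, lo, hi in (
            ("maf_min", self.maf_min, 0, 0.5), ("r2_tag", self.r2_tag, 0, 1),
            ("match_threshold", self.match_threshold, 0, 1),
            ("ic_min", self.ic_min, 0, 2), ("alpha", self.alpha, 0, 1),
        ):
            if not (lo <= val <= hi):
                raise ValueError(f"{name}={val} outside [{lo}, {hi}]")
        enabled = set(self.stages)
        for stage in sorted(enabled):
            missing = [d for d in _STAGE_DEPS.get(stage, ()) if d not in enabled]
            if missing:
                raise ValueError(
                    f"stage {stage!r} requires {missing}, not enabled"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    stage_outputs: dict[str, dict[str, str]]  # stage -> {filename: sha256}

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the enabled stages in order under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digests: dict[str, dict[str, str]] = {}

    def record(stage: str, *paths: Path) -> None:
        digests[stage] = {p.name: _sha256(p) for p in paths}
        log.info("stage %s: wrote %s", stage, ", ".join(p.name for p in paths))

    enabled = set(config.stages)
    genotypes = phenotypes = covariates = expr = None
    pwm = context = var_col = None

    if "simulate" in enabled:
        sim = SimulationConfig(
            n_subjects=config.n_subjects, n_snps=config.n_snps,
            effect_map=(
                [(config.planted_snp_index, config.planted_roi,
                  config.planted_trait, config.planted_beta)]
                if config.planted_beta else []
            ),
            seed=config.seed,
        )
        genotypes = simulate_genotypes(sim)
        phenotypes, covariates = simulate_roi_phenotypes(genotypes, sim)
        expr_geno = simulate_genotypes(
            SimulationConfig(n_subjects=config.n_individuals, n_snps=1,
                             seed=config.seed + 10)
        )
        expr = simulate_expression(
            expr_geno,
            ExpressionSimConfig(
                n_individuals=config.n_individuals,
                regions_per_individual=config.regions_per_individual,
                eqtl_beta=config.eqtl_beta, tf_target_r=config.tf_target_r,
                seed=config.seed + 20,
            ),
        )
        pwm, context, var_col = simulate_pwm_and_flanks(
            config.motif_length, config.motif_ic, seed=config.seed + 30
        )
        paths = {
            "genotypes.vcf": lambda p: bio.write_vcf(genotypes, p),
            "genotypes.tsv": lambda p: bio.write_dosage_tsv(genotypes, p),
            "phenotypes.tsv": lambda p: bio.write_table(phenotypes, p),
            "covariates.tsv": lambda p: bio.write_table(covariates, p),
            "motif.pfm": lambda p: bio.write_pfm_file([pwm], p),
            "flanks.fasta": lambda p: bio.write_flanks_fasta([context], p),
        }
        for name, writer in paths.items():
            writer(out / name)
        bio.write_expression(expr, out / "expression.tsv", out / "expression_map.tsv")
        # expression-cohort genotypes (for the eQTL stage)
        bio.write_dosage_tsv(expr_geno, out / "expr_genotypes.tsv")
        record("simulate", *(out / n for n in list(paths) +
                             ["expression.tsv", "expression_map.tsv", "expr_genotypes.tsv"]))
    else:
        raise ValueError(
            "file-input runs go through the stage CLIs; run_pipeline currently "
            "requires the simulate stage"
        )

    if "qc" in enabled:
        report = qc_report(genotypes, maf_min=config.maf_min, hwe_alpha=config.hwe_alpha)
        report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        record("qc", out / "qc_report.tsv")
        keep = [s for s, ok in zip(genotypes.snp_ids, report["pass"]) if ok]
        if not keep:
            raise RuntimeError("qc: no SNPs pass; relax maf_min/hwe_alpha")
        idx = [genotypes.snp_index(s) for s in keep]
        genotypes = GenotypeMatrix(
            genotypes.subject_ids, keep, genotypes.dosages[:, idx],
            [genotypes.allele_labels[i] for i in idx],
        )

    if "tag" in enabled:
        r2 = r2_matrix(genotypes)
        tags, assignment = greedy_tag_selection(r2, threshold=config.r2_tag)
        tag_df = pd.DataFrame(
            [{"snp": snp, "tag": tag, "r2_to_tag": r2.loc[snp, tag]}
             for snp, tag in assignment.items()]
        )
        tag_df.to_csv(out / "tags.tsv", sep="\t", index=False)
        record("tag", out / "tags.tsv")

    if "assoc" in enabled:
        covs = VALIDATION_COVARIATES if config.validation_model else DISCOVERY_COVARIATES
        spec = AssocModelSpec(trait=config.trait, covariates=list(covs))
        pairs = pairwise_scan(phenotypes, genotypes, covariates, spec)
        pairs.to_csv(out / "assoc_pairwise.tsv", sep="\t", index=False)
        agg = permutation_test(
            phenotypes, genotypes, covariates, spec,
            n_perm=config.n_perm, seed=config.seed + 40,
            correction_mode=config.correction_mode,
        )
        agg_df = pd.DataFrame(
            [{"snp": r.snp, "trait": config.trait, "x2_obs": r.x2_obs,
              "n_perm": r.n_perm, "seed": r.seed,
              "correction_mode": r.correction_mode, "p_perm": r.p_perm}
             for r in agg]
        )
        agg_df.to_csv(out / "assoc_aggregate.tsv", sep="\t", index=False)
        record("assoc", out / "assoc_pairwise.tsv", out / "assoc_aggregate.tsv")

    eqtl_res = None
    if "eqtl" in enabled:
        expr_geno = bio.read_dosage_tsv(out / "expr_genotypes.tsv")
        snp = expr_geno.snp_ids[0]
        target = average_by_individual(expr, "target_probe")
        eqtl_res = fit_eqtl(
            target, expr_geno.dosage(snp), snp=snp, probe="target_probe",
            alleles=expr_geno.allele_labels[0],
        )
        pd.DataFrame([asdict(eqtl_res)]).to_csv(out / "eqtl.tsv", sep="\t", index=False)
        record("eqtl", out / "eqtl.tsv")

    screen = None
    if "tfscreen" in enabled:
        screen = tf_correlation_screen(
            expr, ["tf_probe"], "target_probe", n_tests=config.n_tests
        )
        pd.DataFrame([asdict(c) for c in screen]).to_csv(
            out / "tfscreen.tsv", sep="\t", index=False
        )
        record("tfscreen", out / "tfscreen.tsv")

    scan = None
    if "tfscan" in enabled:
        call_a, call_b, diff = differential_binding(
            pwm, context, threshold=config.match_threshold, ic_min=config.ic_min
        )
        rows = []
        for call in (call_a, call_b):
            rows.append(
                {"variant": context.variant_id, "motif": call.motif,
                 "allele": call.allele,
                 "best_relative_score": call.best_relative_score,
                 "best_offset": call.best_offset, "strand": call.strand,
                 "is_match": call.is_match, "aligned_column": call.aligned_column,
                 "column_ic": call.column_ic, "differential": diff}
            )
        scan = (call_a, call_b, diff)
        pd.DataFrame(rows).to_csv(out / "tfscan.tsv", sep="\t", index=False)
        record("tfscan", out / "tfscan.tsv")

    if "prioritize" in enabled:
        call_a, call_b, diff = scan
        sign = "+" if screen[0].r >= 0 else "-"
        # the allele associated with increased target expression, from the
        # planted eQTL direction; allele labels live in the scan context
        inc_allele = context.alleles[0] if eqtl_res.slope >= 0 else context.alleles[1]
        best = max((call_a, call_b), key=lambda c: c.best_relative_score)
        fold = None
        if best.aligned_column is not None and all(len(a) == 1 for a in context.alleles):
            fold, _ = fold_affinity(pwm, best.aligned_column, *context.alleles)
        cand = prioritize_tf("tf_probe", sign, inc_allele, call_a, call_b, diff, fold)
        pd.DataFrame([asdict(cand)]).to_csv(out / "prioritized.tsv", sep="\t", index=False)
        record("prioritize", out / "prioritized.tsv")

    manifest = RunManifest(
        config=asdict(config), version=__version__, seed=config.seed,
        stage_outputs=digests,
    )
    manifest.write(out / "manifest.json")
    return manifest


def validate_inputs(
    genotype_path: str | Path | None = None,
    covariate_path: str | Path | None = None,
    phenotype_path: str | Path | None = None,
) -> pd.DataFrame:
    """Schema/consistency report for a genotype/covariate/phenotype bundle.

    Never raises: each check is one report row with status pass/warn/fail.
    """
    rows = []

    def add(file: str, check: str, status: str, detail: str = "") -> None:
        rows.append({"file": file, "check": check, "status": status, "detail": detail})

    geno = cov = pheno = None
    if genotype_path:
        try:
            geno = bio.read_genotypes(genotype_path)
            add(str(genotype_path), "parse", "pass",
                f"{geno.n_subjects} subjects x {geno.n_snps} SNPs")
        except Exception as exc:
            add(str(genotype_path), "parse", "fail", str(exc))
    for path, label in ((covariate_path, "covariates"), (phenotype_path, "phenotypes")):
        if not path:
            continue
        try:
            df = bio.read_table(path)
            add(str(path), "parse", "pass", f"{df.shape[0]} rows x {df.shape[1]} cols")
            if label == "covariates":
                cov = df
            else:
                pheno = df
        except Exception as exc:
            add(str(path), "parse", "fail", str(exc))
    if geno is not None:
        gset = set(geno.subject_ids)
        for df, path in ((cov, covariate_path), (pheno, phenotype_path)):
            if df is None:
                continue
            missing = sorted(gset - set(map(str, df.index)))
            if missing:
                add(str(path), "subject_overlap", "warn",
                    f"{len(missing)} genotyped subjects absent: {', '.join(missing[:10])}")
            else:
                add(str(path), "subject_overlap", "pass")
    return pd.DataFrame(rows)
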