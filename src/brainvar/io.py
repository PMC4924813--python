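"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as minimal VCF (GT only) or a TSV dosage matrix; phenotype,
covariate and expression tables as TSV with the subject/sample ID in column
1; PWMs as JASPAR PFM text; variant flanks as FASTA with record IDs
``<variant>_<allele>``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genotypes import GenotypeMatrix
from .motifs import PWM, parse_jaspar_pfm, write_jaspar_pfm
from .simulate import ExpressionBundle, VariantContext

__all__ = [
    "read_genotypes",
    "read_vcf",
    "read_dosage_tsv",
    "write_vcf",
    "write_dosage_tsv",
    "read_table",
    "write_table",
    "read_expression",
    "write_expression",
    "read_pfm_file",
    "write_pfm_file",
    "read_flanks_fasta",
    "write_flanks_fasta",
]

_GT_TO_DOSE = {
    (0, 0): 0.0, (0, 1): 1.0, (1, 0): 1.0, (1, 1): 2.0,
}


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Minimal VCF 4.2 with one GT sample column per subject.

    REF is the major allele, ALT the minor, so the written genotype carries
    minor-allele dosage directly.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=chr15>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.subject_ids)
            + "\n"
        )
        for j, snp in enumerate(genotypes.snp_ids):
            major, minor = genotypes.allele_labels[j]
            calls = []
            for d in genotypes.dosages[:, j]:
                if np.isnan(d):
                    calls.append("./.")
                else:
                    calls.append({0: "0/0", 1: "0/1", 2: "1/1"}[int(d)])
            fh.write(
                f"chr15\t{22783636 + j * 100}\t{snp}\t{major}\t{minor}\t.\tPASS\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read GT fields from a VCF into minor-allele dosages (ALT counted)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    snp_ids, rows, labels = [], [], []
    for var in vcf:
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        labels.append((var.REF, var.ALT[0] if var.ALT else "."))
        dos = []
        for gt in var.genotypes:  # [allele1, allele2, phased]
            a, b = gt[0], gt[1]
            dos.append(np.nan if a < 0 or b < 0 else float(a + b))
        rows.append(dos)
    return GenotypeMatrix(subjects, snp_ids, np.array(rows).T, labels)


def write_dosage_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    df = genotypes.to_frame()
    df.index.name = "subject_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return GenotypeMatrix(
        [str(s) for s in df.index], [str(c) for c in df.columns], df.to_numpy(dtype=float)
    )


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Dispatch on extension: .vcf[.gz] or dosage TSV."""
    name = str(path)
    if name.endswith((".vcf", ".vcf.gz")):
        return read_vcf(path)
    return read_dosage_tsv(path)


def write_table(df: pd.DataFrame, path: str | Path, index_label: str = "subject_id") -> None:
    df.to_csv(path, sep="\t", na_rep="NA", index_label=index_label)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])


def write_expression(expr: ExpressionBundle, values_path: str | Path, map_path: str | Path) -> None:
    expr.values.to_csv(values_path, sep="\t", na_rep="NA", index_label="sample_id")
    expr.sample_map.to_csv(map_path, sep="\t", index=False)


def read_expression(values_path: str | Path, map_path: str | Path) -> ExpressionBundle:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    sample_map = pd.read_csv(map_path, sep="\t", dtype=str)
    need = {"sample_id", "individual_id", "region"}
    if not need.issubset(sample_map.columns):
        raise ValueError(f"sample map must have columns {sorted(need)}")
    individuals = list(dict.fromkeys(sample_map["individual_id"]))
    return ExpressionBundle(values, sample_map, individuals)


def read_pfm_file(path: str | Path) -> list[PWM]:
    """All JASPAR PFM records in a file."""
    text = Path(path).read_text()
    records, current = [], []
    for line in text.splitlines():
        if line.startswith(">") and current:
            records.append("\n".join(current))
            current = []
        if line.strip():
            current.append(line)
    if current:
        records.append("\n".join(current))
    return [parse_jaspar_pfm(rec) for rec in records]


def write_pfm_file(pwms: list[PWM], path: str | Path) -> None:
    Path(path).write_text("".join(write_jaspar_pfm(p) for p in pwms))


def write_flanks_fasta(contexts: list[VariantContext], path: str | Path) -> None:
    records = []
    for ctx in contexts:
        for allele in ctx.alleles:
            records.append(
                SeqRecord(Seq(ctx.sequence(allele)), id=f"{ctx.variant_id}_{allele}",
                          description="")
            )
    SeqIO.write(records, str(path), "fasta")


def read_flanks_fasta(path: str | Path) -> list[VariantContext]:
    """Rebuild variant contexts from ``<variant>_<allele>`` FASTA pairs."""
    by_variant: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        variant, _, allele = rec.id.rpartition("_")
        if not variant:
            raise ValueError(f"record ID {rec.id!r} is not <variant>_<allele>")
        by_variant.setdefault(variant, {})[allele] = str(rec.seq).upper()
    contexts = []
    for variant, seqs in by_variant.items():
        if len(seqs) != 2:
            raise ValueError(f"variant {variant!r} needs exactly 2 allele records")
        (al_a, seq_a), (al_b, seq_b) = sorted(seqs.items())
        if seq_a[:50] != seq_b[:50] or seq_a[-50:] != seq_b[-50:]:
            raise ValueError(f"variant {variant!r}: allele records disagree on flanks")
        contexts.append(
            VariantContext(variant_id=variant, alleles=(al_a, al_b),
                           flank_5p=seq_a[:50], flank_3p=seq_a[-50:])
        )
    return contexts
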