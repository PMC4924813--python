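import numpy as np
import pytest

from brainvar import GenotypeMatrix, SimulationConfig, simulate_genotypes, simulate_roi_phenotypes


def make_genotypes(dosages, snp_ids=None, allele_labels=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    return GenotypeMatrix(
        subject_ids=[f"S{i}" for i in range(n)],
        snp_ids=snp_ids or [f"snp{j}" for j in range(m)],
        dosages=dosages,
        allele_labels=allele_labels or [("A", "G")] * m,
    )


def genotypes_from_counts(n0, n1, n2, snp_id="snp0"):
    """One-SNP matrix with the given dosage-class counts."""
    g = np.concatenate([np.zeros(n0), np.ones(n1), np.full(n2, 2.0)])
    return make_genotypes(g[:, None], snp_ids=[snp_id])


@pytest.fixture
def small_cohort():
    """100-subject cohort with no planted effect, plus its model tables."""
    cfg = SimulationConfig(n_subjects=100, n_snps=3, seed=42)
    geno = simulate_genotypes(cfg)
    pheno, covar = simulate_roi_phenotypes(geno, cfg)
    return geno, pheno, covar, cfg
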