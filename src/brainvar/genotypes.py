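"""Genotype QC and linkage-disequilibrium machinery.

Holds the subject x SNP minor-allele dosage container plus the standard
single-locus and two-locus statistics a targeted association study needs:
minor allele frequency with allele folding, the exact Hardy-Weinberg test,
pairwise r^2 (EM over the two-locus haplotype ambiguity, or dosage
correlation), and greedy pairwise tag-SNP selection at an r^2 threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "LdResult",
    "MonomorphicSnpWarning",
    "minor_allele_frequency",
    "hwe_exact_test",
    "pairwise_r2",
    "greedy_tag_selection",
    "qc_report",
]


class MonomorphicSnpWarning(UserWarning):
    pass


@dataclass
class GenotypeMatrix:
    """Subject x SNP minor-allele dosages with missingness.

    Dosages are stored as a float array with values in {0, 1, 2} and NaN for
    missing calls. ``allele_labels[j]`` is the (major, minor) base pair for
    SNP ``j``; the dosage counts copies of the minor allele.
    """

    subject_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray
    allele_labels: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if len(self.subject_ids) != n:
            raise ValueError(
                f"dosage rows ({n}) != number of subject_ids ({len(self.subject_ids)})"
            )
        if len(self.snp_ids) != m:
            raise ValueError(
                f"dosage columns ({m}) != number of snp_ids ({len(self.snp_ids)})"
            )
        if len(set(self.subject_ids)) != n:
            raise ValueError("duplicate subject IDs")
        if len(set(self.snp_ids)) != m:
            raise ValueError("duplicate SNP IDs")
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise ValueError(
                f"dosage for subject {self.subject_ids[bad[0]]}, SNP "
                f"{self.snp_ids[bad[1]]} is {self.dosages[tuple(bad)]!r}; "
                "must be 0, 1, 2 or missing"
            )
        if not self.allele_labels:
            self.allele_labels = [("A", "B")] * m

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def snp_index(self, snp: str) -> int:
        try:
            return self.snp_ids.index(snp)
        except ValueError:
            raise KeyError(f"unknown SNP {snp!r}") from None

    def dosage(self, snp: str) -> np.ndarray:
        return self.dosages[:, self.snp_index(snp)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.subject_ids, columns=self.snp_ids)

    def subset_subjects(self, subject_ids: list[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.subject_ids)}
        idx = [pos[s] for s in subject_ids]
        return GenotypeMatrix(
            list(subject_ids), list(self.snp_ids), self.dosages[idx], list(self.allele_labels)
        )


@dataclass
class LdResult:
    snp_a: str
    snp_b: str
    r2: float
    n_used: int
    method: str


def _genotype_counts(g: np.ndarray) -> tuple[int, int, int]:
    g = g[~np.isnan(g)]
    return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())


def minor_allele_frequency(genotypes: GenotypeMatrix, snp: str) -> tuple[float, bool]:
    """Minor allele frequency of ``snp``, folded to <= 0.5.

    Returns ``(maf, flipped)`` where ``flipped`` is True when the allele
    labelled minor is actually the major one in this sample (frequency of the
    coded allele > 0.5), so the dosage direction can be reconstructed.
    """
    g = genotypes.dosage(snp)
    g = g[~np.isnan(g)]
    if g.size == 0:
        raise ValueError(f"SNP {snp!r} has no non-missing calls")
    freq = float(g.sum()) / (2.0 * g.size)
    if freq > 0.5:
        return 1.0 - freq, True
    return freq, False


def hwe_exact_test(genotypes: GenotypeMatrix, snp: str, mid_p: bool = False) -> float:
    """Exact Hardy-Weinberg test p-value for one SNP.

    Conditional on the observed allele counts, the number of heterozygotes
    under HWE follows the distribution of Wigginton, Cutler & Abecasis (2005);
    the p-value sums probabilities of all heterozygote counts no more likely
    than the observed one. ``mid_p`` halves the observed configuration's
    contribution. Monomorphic SNPs return p = 1 with a warning.
    """
    g = genotypes.dosage(snp)
    n_aa, n_ab, n_bb = _genotype_counts(g)
    n = n_aa + n_ab + n_bb
    if n < 3:
        raise ValueError(f"SNP {snp!r}: need >=3 non-missing calls, have {n}")
    return hwe_exact_from_counts(n_aa, n_ab, n_bb, mid_p=mid_p, snp=snp)


def hwe_exact_from_counts(
    n_hom_major: int, n_het: int, n_hom_minor: int, mid_p: bool = False, snp: str = "?"
) -> float:
    n = n_hom_major + n_het + n_hom_minor
    n_minor = 2 * n_hom_minor + n_het
    n_major = 2 * n_hom_major + n_het
    if min(n_minor, n_major) == 0:
        warnings.warn(f"SNP {snp!r} is monomorphic; HWE p set to 1", MonomorphicSnpWarning)
        return 1.0
    rare = min(n_minor, n_major)
    obs_het = n_het
    # recurrence over heterozygote counts with the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    logp = np.zeros(hets.size)
    for i in range(1, hets.size):
        h = hets[i]
        hom_r = (rare - h) / 2  # rare homozygotes at het count h
        hom_c = n - h - hom_r
        # P(h) / P(h-2) = 4 * hom_r(h-2) * hom_c(h-2) / (h * (h-1)), rearranged:
        logp[i] = logp[i - 1] + np.log(4.0 * (hom_r + 1) * (hom_c + 1)) - np.log(h * (h - 1.0))
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hets == obs_het][0]
    tail = probs[probs <= p_obs * (1.0 + 1e-9)].sum()
    if mid_p:
        tail -= 0.5 * p_obs
    return float(min(1.0, tail))


def _em_haplotype_freqs(
    ga: np.ndarray, gb: np.ndarray, tol: float = 1e-8, max_iter: int = 100
) -> np.ndarray:
    """EM haplotype frequencies (AB, Ab, aB, ab) for two biallelic loci.

    'A'/'B' denote the minor (dosage-counted) alleles. Only the double
    heterozygote is phase-ambiguous; the EM starts at linkage equilibrium.
    """
    pa = ga.mean() / 2.0
    pb = gb.mean() / 2.0
    f = np.array([pa * pb, pa * (1 - pb), (1 - pa) * pb, (1 - pa) * (1 - pb)])
    f = np.clip(f, 1e-12, None)
    f /= f.sum()

    n = ga.size
    n_dh = int(((ga == 1) & (gb == 1)).sum())
    # unambiguous haplotype counts
    base = np.zeros(4)
    for da, db, add in (
        (2, 2, (2, 0, 0, 0)), (2, 1, (1, 1, 0, 0)), (2, 0, (0, 2, 0, 0)),
        (1, 2, (1, 0, 1, 0)), (1, 0, (0, 1, 0, 1)),
        (0, 2, (0, 0, 2, 0)), (0, 1, (0, 0, 1, 1)), (0, 0, (0, 0, 0, 2)),
    ):
        cnt = int(((ga == da) & (gb == db)).sum())
        base += cnt * np.asarray(add, dtype=float)

    for _ in range(max_iter):
        # E-step: split double heterozygotes between cis (AB/ab) and trans (Ab/aB)
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        w = cis / (cis + trans) if cis + trans > 0 else 0.5
        counts = base + n_dh * np.array([w, 1 - w, 1 - w, w])
        new = counts / (2.0 * n)
        if np.max(np.abs(new - f)) < tol:
            f = new
            break
        f = new
    return f


def pairwise_r2(
    genotypes: GenotypeMatrix, snp_a: str, snp_b: str, method: str = "em_haplotype"
) -> LdResult:
    """Pairwise LD r^2 between two SNPs on complete-case subjects.

    ``em_haplotype`` estimates two-locus haplotype frequencies by EM and
    returns r^2 = D^2 / (pA pa pB pb); ``dosage_correlation`` returns the
    squared Pearson correlation of dosages.
    """
    if method not in ("em_haplotype", "dosage_correlation"):
        raise ValueError(f"unknown method {method!r}")
    ga = genotypes.dosage(snp_a)
    gb = genotypes.dosage(snp_b)
    keep = ~np.isnan(ga) & ~np.isnan(gb)
    ga, gb = ga[keep], gb[keep]
    n_used = int(keep.sum())
    if n_used < 5:
        raise ValueError(f"({snp_a}, {snp_b}): need >=5 complete-case subjects, have {n_used}")
    for snp, g in ((snp_a, ga), (snp_b, gb)):
        if np.all(g == g[0]):
            raise ValueError(f"SNP {snp!r} is monomorphic in the complete cases; r2 undefined")
    if snp_a == snp_b:
        return LdResult(snp_a, snp_b, 1.0, n_used, method)
    if method == "dosage_correlation":
        r = np.corrcoef(ga, gb)[0, 1]
        return LdResult(snp_a, snp_b, float(np.clip(r * r, 0.0, 1.0)), n_used, method)
    f = _em_haplotype_freqs(ga, gb)
    p_a = f[0] + f[1]
    p_b = f[0] + f[2]
    d = f[0] - p_a * p_b
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    r2 = float(np.clip(d * d / denom, 0.0, 1.0)) if denom > 0 else 0.0
    return LdResult(snp_a, snp_b, r2, n_used, method)


def r2_matrix(genotypes: GenotypeMatrix, method: str = "em_haplotype") -> pd.DataFrame:
    """Full symmetric pairwise r^2 matrix over all SNPs."""
    m = genotypes.n_snps
    out = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            out[i, j] = out[j, i] = pairwise_r2(
                genotypes, genotypes.snp_ids[i], genotypes.snp_ids[j], method=method
            ).r2
    return pd.DataFrame(out, index=genotypes.snp_ids, columns=genotypes.snp_ids)


def greedy_tag_selection(
    r2: pd.DataFrame | np.ndarray, threshold: float = 0.8
) -> tuple[list[str], dict[str, str]]:
    """Greedy pairwise tag-SNP selection at an r^2 threshold.

    Repeatedly picks the SNP covering the most uncovered SNPs at
    ``r2 >= threshold`` (a SNP always covers itself), breaking ties by lower
    index, until every SNP is covered. Returns the ordered tag list and a map
    from each SNP to its covering tag.
    """
    if isinstance(r2, pd.DataFrame):
        names = [str(c) for c in r2.columns]
        mat = r2.to_numpy(dtype=float)
    else:
        mat = np.asarray(r2, dtype=float)
        names = [f"snp{i}" for i in range(mat.shape[0])]
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T, atol=1e-12):
        raise ValueError("r2 matrix must be square and symmetric")
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    m = mat.shape[0]
    covers = (mat >= threshold) | np.eye(m, dtype=bool)
    uncovered = np.ones(m, dtype=bool)
    tags: list[str] = []
    assignment: dict[str, str] = {}
    while uncovered.any():
        gain = (covers & uncovered).sum(axis=1)
        best = int(np.argmax(gain))  # argmax takes the first (lowest index) on ties
        tags.append(names[best])
        newly = covers[best] & uncovered
        for j in np.flatnonzero(newly):
            assignment[names[j]] = names[best]
        uncovered &= ~covers[best]
    return tags, assignment


def qc_report(
    genotypes: GenotypeMatrix, maf_min: float = 0.15, hwe_alpha: float = 0.001
) -> pd.DataFrame:
    """Per-SNP QC metrics (MAF, exact HWE p, call rate) with pass/fail flags."""
    rows = []
    for snp in genotypes.snp_ids:
        g = genotypes.dosage(snp)
        call_rate = float((~np.isnan(g)).mean())
        maf, flipped = minor_allele_frequency(genotypes, snp)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", MonomorphicSnpWarning)
            hwe_p = hwe_exact_test(genotypes, snp)
        rows.append(
            {
                "snp": snp,
                "maf": maf,
                "allele_flipped": flipped,
                "hwe_p": hwe_p,
                "call_rate": call_rate,
                "pass_maf": maf >= maf_min,
                "pass_hwe": hwe_p >= hwe_alpha,
                "pass": (maf >= maf_min) and (hwe_p >= hwe_alpha),
            }
        )
    return pd.DataFrame(rows)
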