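"""Covariate-adjusted SNP-ROI association and permutation inference.

The per-pair model is ordinary least squares,

    trait(ROI) = alpha + beta1 * dosage + covariates + beta_g * global + eps,

with the genotype entered as minor-allele dosage (0/1/2, additive coding) and
categorical covariates dummy-coded against the lexicographically first level.
Each pair contributes a 1-df Wald chi-square (the squared t of beta1); a
SNP's aggregate statistic over an ROI set is X2_0 = sum of those chi-squares,
and inference is by permutation of the genotype columns across subjects: one
shared subject shuffle per replicate keeps the phenotype-covariate pairing
and the inter-SNP LD intact, which is what makes the max-T family-wise modes
valid. Permutation p-values use the add-one rule and are never exactly zero.

The permutation loop runs on the Frisch-Waugh decomposition: phenotypes and
(permuted) genotype columns are residualized on the covariate design once per
replicate with a precomputed orthonormal basis, which yields the identical
beta/SE/t as a full refit at a fraction of the cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .genotypes import GenotypeMatrix

__all__ = [
    "AssocModelSpec",
    "RegressionResult",
    "AggregatePermResult",
    "PairPermResult",
    "fit_snp_roi",
    "aggregate_x2",
    "permutation_test",
    "pairwise_scan",
    "genotype_trend_summary",
    "bonferroni",
]

DEFAULT_ROI_SETS = {
    "volume": ["lh.insula", "rh.ACC", "CC", "lh.tempWM", "lh.SMG"],
    "surface_area": ["lh.insula", "rh.ACC", "lh.SMG"],
    "thickness": ["lh.insula", "rh.ACC", "lh.SMG"],
}

#: discovery-cohort covariate set; the validation cohort swaps handedness for
#: scanner field strength purely through this list
DISCOVERY_COVARIATES = [
    ("age", "continuous"),
    ("sex", "categorical"),
    ("ethnicity", "categorical"),
    ("handedness", "categorical"),
]
VALIDATION_COVARIATES = [
    ("age", "continuous"),
    ("sex", "categorical"),
    ("ethnicity", "categorical"),
    ("scanner_field", "categorical"),
]

_SUBCORTICAL = {"CC", "lh.tempWM"}


@dataclass
class AssocModelSpec:
    """Trait, ROI set and covariate design for the per-SNP-per-ROI model."""

    trait: str = "volume"
    roi_set: list[str] = field(default_factory=list)
    covariates: list[tuple[str, str]] = field(default_factory=lambda: list(DISCOVERY_COVARIATES))
    global_covariate: str | None = None
    additive: bool = True

    def __post_init__(self) -> None:
        if self.trait not in DEFAULT_ROI_SETS:
            raise ValueError(f"unknown trait {self.trait!r}")
        if not self.roi_set:
            self.roi_set = list(DEFAULT_ROI_SETS[self.trait])
        if self.trait != "volume":
            bad = _SUBCORTICAL.intersection(self.roi_set)
            if bad:
                raise ValueError(
                    f"ROIs {sorted(bad)} have no {self.trait}; they are volume-only"
                )
        if self.global_covariate is None:
            self.global_covariate = f"{self.trait}:global"
        for name, kind in self.covariates:
            if kind not in ("continuous", "categorical"):
                raise ValueError(f"covariate {name!r} has unknown kind {kind!r}")

    def column(self, roi: str) -> str:
        return f"{self.trait}:{roi}"


@dataclass
class RegressionResult:
    snp: str
    roi: str
    beta: float
    se: float
    t_stat: float
    df_resid: int
    chi2: float
    p_nominal: float
    n_used: int


@dataclass
class AggregatePermResult:
    snp: str
    x2_obs: float
    p_perm: float
    n_perm: int
    seed: int
    correction_mode: str
    perm_stats: np.ndarray | None = None


@dataclass
class PairPermResult:
    snp: str
    roi: str
    chi2_obs: float
    p_perm: float
    n_perm: int
    seed: int
    correction_mode: str = "max_t_snp_roi"


def bonferroni(p: float, n_tests: int) -> float:
    """Bonferroni-adjusted p: ``min(1, p * n_tests)``."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return min(1.0, p * n_tests)


def build_design(
    covariates: pd.DataFrame,
    spec: AssocModelSpec,
    phenotypes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Covariate design matrix (with intercept and global measure, no genotype).

    Categorical covariates are dummy-coded with the lexicographically first
    observed level as reference.
    """
    cols: dict[str, np.ndarray] = {}
    cols["const"] = np.ones(len(covariates))
    for name, kind in spec.covariates:
        if name not in covariates.columns:
            raise KeyError(f"covariate {name!r} missing from covariate table")
        if kind == "continuous":
            cols[name] = covariates[name].to_numpy(dtype=float)
        else:
            levels = sorted(pd.unique(covariates[name].astype(str)))
            for level in levels[1:]:
                cols[f"{name}[{level}]"] = (
                    covariates[name].astype(str) == level
                ).to_numpy(dtype=float)
    if spec.global_covariate:
        source = None
        if phenotypes is not None and spec.global_covariate in phenotypes.columns:
            source = phenotypes[spec.global_covariate]
        elif spec.global_covariate in covariates.columns:
            source = covariates[spec.global_covariate]
        else:
            raise KeyError(f"global covariate {spec.global_covariate!r} not found")
        cols[spec.global_covariate] = source.to_numpy(dtype=float)
    design = pd.DataFrame(cols, index=covariates.index)
    return design


def fit_snp_roi(
    phenotypes: pd.DataFrame,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame,
    spec: AssocModelSpec,
    snp: str,
    roi: str,
) -> RegressionResult:
    """OLS fit of one SNP-ROI pair on complete cases.

    Returns the genotype coefficient's estimate, SE, Wald t, its square as the
    pair's 1-df chi-square, and the two-sided p from the t distribution with
    the residual degrees of freedom.
    """
    col = spec.column(roi)
    if col not in phenotypes.columns:
        raise KeyError(f"phenotype column {col!r} not found")
    subjects = list(phenotypes.index)
    g = pd.Series(genotypes.dosage(snp), index=genotypes.subject_ids).reindex(subjects)
    design = build_design(covariates.loc[subjects], spec, phenotypes)
    y = phenotypes[col]

    frame = design.copy()
    frame.insert(1, "genotype", g)
    frame["__y__"] = y
    frame = frame.dropna()
    n_used = len(frame)
    k = frame.shape[1] - 1
    if n_used < k + 2:
        raise ValueError(
            f"({snp}, {roi}): {n_used} complete cases for {k} design columns; need >= {k + 2}"
        )
    X = frame.iloc[:, :-1]
    yv = frame["__y__"]
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"({snp}, {roi}): rank-deficient design; columns {list(X.columns)}"
        )
    fit = sm.OLS(yv, X).fit()
    beta = float(fit.params["genotype"])
    se = float(fit.bse["genotype"])
    scale = max(float(np.abs(yv).max()), 1.0)
    if se <= 1e-12 * scale or not np.isfinite(se):
        # numerically perfect fit: a constant phenotype carries no signal,
        # a genuinely non-zero coefficient is off-scale significant
        t = 0.0 if abs(beta) <= 1e-9 * scale else np.sign(beta) * np.inf
        beta = 0.0 if t == 0.0 else beta
    else:
        t = beta / se
    df = int(fit.df_resid)
    p = float(2.0 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    if t == 0.0:
        p = 1.0
    return RegressionResult(
        snp=snp, roi=roi, beta=beta, se=se, t_stat=float(t), df_resid=df,
        chi2=float(t * t), p_nominal=p, n_used=n_used,
    )


def aggregate_x2(results: list[RegressionResult], roi_set: list[str]) -> float:
    """Aggregate statistic X2_0 = sum of per-ROI chi-squares for one SNP."""
    snps = {r.snp for r in results}
    if len(snps) != 1:
        raise ValueError(f"results mix SNPs: {sorted(snps)}")
    have = {r.roi: r for r in results}
    missing = [roi for roi in roi_set if roi not in have]
    if missing:
        raise ValueError(f"missing ROI results for {missing}")
    return float(sum(have[roi].chi2 for roi in roi_set))


def _aligned_arrays(
    phenotypes: pd.DataFrame,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame,
    spec: AssocModelSpec,
    snps: list[str],
):
    """Complete-case (over phenotypes/covariates) aligned numeric arrays."""
    subjects = list(phenotypes.index)
    design = build_design(covariates.loc[subjects], spec, phenotypes)
    ycols = [spec.column(roi) for roi in spec.roi_set]
    for c in ycols:
        if c not in phenotypes.columns:
            raise KeyError(f"phenotype column {c!r} not found")
    Y = phenotypes[ycols]
    keep = design.notna().all(axis=1) & Y.notna().all(axis=1)
    subjects = [s for s, k in zip(subjects, keep) if k]
    X = design.loc[subjects].to_numpy(dtype=float)
    Y = Y.loc[subjects].to_numpy(dtype=float)
    gsub = genotypes.subset_subjects(subjects)
    G = np.column_stack([gsub.dosage(s) for s in snps])
    return X, Y, G, subjects


def _perm_chi2(
    X: np.ndarray, Y: np.ndarray, G: np.ndarray
) -> np.ndarray:
    """Wald chi-squares (t^2) for every genotype column x phenotype column.

    ``G`` may contain many columns (e.g. all permutations of one SNP); each is
    residualized on ``X`` and regressed against each residualized phenotype.
    Equivalent to a full OLS refit per column by Frisch-Waugh-Lovell.
    Columns with NaN are handled by the caller; this path requires complete G.
    """
    n, p = X.shape
    Q, _ = np.linalg.qr(X)
    RY = Y - Q @ (Q.T @ Y)  # n x n_roi
    RG = G - Q @ (Q.T @ G)  # n x n_g
    gg = np.einsum("ij,ij->j", RG, RG)  # squared norms per genotype column
    gg_safe = np.where(gg > 1e-12, gg, np.inf)
    # slopes: (n_g x n_roi)
    num = RG.T @ RY
    b = num / gg_safe[:, None]
    yy = np.einsum("ij,ij->j", RY, RY)  # per-ROI squared norms
    rss = yy[None, :] - b * num
    df = n - p - 1
    sigma2 = np.maximum(rss, 0.0) / df
    denom = np.where(sigma2 > 1e-300, sigma2, np.inf)
    chi2 = b * num / denom  # b^2 * gg / sigma2
    return chi2


def permutation_test(
    phenotypes: pd.DataFrame,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame,
    spec: AssocModelSpec,
    snps: list[str] | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    correction_mode: str = "per_snp",
    scheme: str = "genotype",
    exhaustive: bool = False,
):
    """Permutation inference for the aggregate statistic.

    Modes: ``per_snp`` compares each SNP's X2_0 to its own permutation
    distribution; ``max_t_snps`` to the per-replicate max over SNPs (FWER over
    SNPs); ``max_t_snp_roi`` compares each pair's chi-square to the max over
    all SNP x ROI chi-squares (FWER over pairs) and returns PairPermResults.
    ``scheme='freedman_lane'`` permutes covariate-adjusted phenotype residuals
    instead of genotype rows. ``exhaustive=True`` enumerates all n! subject
    permutations (tiny n only) instead of Monte-Carlo sampling.
    """
    if correction_mode not in ("per_snp", "max_t_snps", "max_t_snp_roi"):
        raise ValueError(f"unknown correction_mode {correction_mode!r}")
    if scheme not in ("genotype", "freedman_lane"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if not exhaustive and n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    snps = list(snps) if snps is not None else list(genotypes.snp_ids)

    X, Y, G, subjects = _aligned_arrays(phenotypes, genotypes, covariates, spec, snps)
    n = X.shape[0]
    has_missing_g = np.isnan(G).any()

    def chi2_all(Gmat: np.ndarray, Ymat: np.ndarray) -> np.ndarray:
        """SNP x ROI chi-square table, complete-case per SNP when needed."""
        if not np.isnan(Gmat).any():
            return _perm_chi2(X, Ymat, Gmat)
        out = np.empty((Gmat.shape[1], Ymat.shape[1]))
        for j in range(Gmat.shape[1]):
            ok = ~np.isnan(Gmat[:, j])
            out[j] = _perm_chi2(X[ok], Ymat[ok], Gmat[ok, j : j + 1])[0]
        return out

    obs = chi2_all(G, Y)  # n_snp x n_roi
    x2_obs = obs.sum(axis=1)

    rng = np.random.default_rng(seed)
    if exhaustive:
        from itertools import permutations as _perms

        perm_rows = np.array(list(_perms(range(n))), dtype=int)
    else:
        perm_rows = np.array([rng.permutation(n) for _ in range(n_perm)])
    n_rep = perm_rows.shape[0]

    if scheme == "freedman_lane":
        Q, _ = np.linalg.qr(X)
        fitted = Q @ (Q.T @ Y)
        resid = Y - fitted

    # per-replicate statistics
    x2_perm = np.empty((n_rep, len(snps)))
    if correction_mode == "max_t_snp_roi":
        max_pair = np.empty(n_rep)
    if has_missing_g or scheme == "freedman_lane":
        for r in range(n_rep):
            if scheme == "freedman_lane":
                chi = chi2_all(G, fitted + resid[perm_rows[r]])
            else:
                chi = chi2_all(G[perm_rows[r]], Y)
            x2_perm[r] = chi.sum(axis=1)
            if correction_mode == "max_t_snp_roi":
                max_pair[r] = chi.max()
    else:
        # vectorized: for each SNP, all permuted columns at once
        chunks = []
        for j in range(len(snps)):
            Gp = G[perm_rows.T, j]  # n x n_rep
            chi = _perm_chi2(X, Y, Gp)  # n_rep x n_roi
            chunks.append(chi)
        stacked = np.stack(chunks, axis=0)  # n_snp x n_rep x n_roi
        x2_perm = stacked.sum(axis=2).T
        if correction_mode == "max_t_snp_roi":
            max_pair = stacked.max(axis=(0, 2))

    if correction_mode == "max_t_snp_roi":
        results = []
        for i, snp in enumerate(snps):
            for j, roi in enumerate(spec.roi_set):
                p = (1.0 + np.sum(max_pair >= obs[i, j])) / (1.0 + n_rep)
                results.append(
                    PairPermResult(snp=snp, roi=roi, chi2_obs=float(obs[i, j]),
                                   p_perm=float(p), n_perm=n_rep, seed=seed)
                )
        return results

    if correction_mode == "max_t_snps":
        ref = x2_perm.max(axis=1)[:, None]  # replicate-wise max across SNPs
    else:
        ref = x2_perm
    results = []
    for i, snp in enumerate(snps):
        col = ref[:, 0] if correction_mode == "max_t_snps" else ref[:, i]
        p = (1.0 + np.sum(col >= x2_obs[i])) / (1.0 + n_rep)
        results.append(
            AggregatePermResult(
                snp=snp, x2_obs=float(x2_obs[i]), p_perm=float(p), n_perm=n_rep,
                seed=seed, correction_mode=correction_mode, perm_stats=col,
            )
        )
    return results


def pairwise_scan(
    phenotypes: pd.DataFrame,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame,
    spec: AssocModelSpec,
    snps: list[str] | None = None,
) -> pd.DataFrame:
    """Nominal per-pair results for every SNP x ROI in scope (no correction).

    Pairs whose fit fails (degenerate phenotype, too few subjects, collinear
    design) are reported as NA with the reason recorded.
    """
    snps = list(snps) if snps is not None else list(genotypes.snp_ids)
    rows = []
    for snp in snps:
        for roi in spec.roi_set:
            try:
                col = spec.column(roi)
                if col in phenotypes.columns and phenotypes[col].nunique(dropna=True) <= 1:
                    raise ValueError("zero-variance phenotype column")
                r = fit_snp_roi(phenotypes, genotypes, covariates, spec, snp, roi)
                rows.append(
                    {"snp": snp, "roi": roi, "trait": spec.trait, "n": r.n_used,
                     "beta": r.beta, "se": r.se, "t": r.t_stat, "chi2": r.chi2,
                     "p_nominal": r.p_nominal, "reason": ""}
                )
            except (ValueError, KeyError, np.linalg.LinAlgError) as exc:
                rows.append(
                    {"snp": snp, "roi": roi, "trait": spec.trait, "n": np.nan,
                     "beta": np.nan, "se": np.nan, "t": np.nan, "chi2": np.nan,
                     "p_nominal": np.nan, "reason": str(exc)}
                )
    return pd.DataFrame(rows)


def genotype_trend_summary(
    phenotypes: pd.DataFrame,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame,
    spec: AssocModelSpec,
    snp: str,
    roi: str,
) -> pd.DataFrame:
    """Covariate-adjusted mean phenotype per dosage class (0/1/2) with SEs.

    Fits phenotype ~ C(dosage) + covariates and evaluates the fit at the
    complete-case covariate means, so class differences reflect genotype after
    adjustment. Empty classes are reported with NA.
    """
    col = spec.column(roi)
    subjects = list(phenotypes.index)
    g = pd.Series(genotypes.dosage(snp), index=genotypes.subject_ids).reindex(subjects)
    design = build_design(covariates.loc[subjects], spec, phenotypes)
    frame = design.copy()
    frame["__g__"] = g
    frame["__y__"] = phenotypes[col]
    frame = frame.dropna()

    present = sorted(int(v) for v in frame["__g__"].unique())
    Xcov = frame[design.columns]
    dummies = pd.DataFrame(
        {f"g{c}": (frame["__g__"] == c).astype(float) for c in present}, index=frame.index
    )
    X = pd.concat([dummies, Xcov.drop(columns="const")], axis=1)
    fit = sm.OLS(frame["__y__"], X).fit()

    covmeans = Xcov.drop(columns="const").mean()
    rows = []
    for c in (0, 1, 2):
        if c not in present:
            rows.append({"dosage": c, "adjusted_mean": np.nan, "se": np.nan, "n": 0})
            continue
        vec = pd.Series(0.0, index=X.columns)
        vec[f"g{c}"] = 1.0
        vec[covmeans.index] = covmeans
        est = float(vec @ fit.params)
        se = float(np.sqrt(vec @ fit.cov_params() @ vec))
        rows.append(
            {"dosage": c, "adjusted_mean": est, "se": se, "n": int((frame["__g__"] == c).sum())}
        )
    return pd.DataFrame(rows)
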