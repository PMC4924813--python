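"""eQTL regression and TF-target correlation screening on brain expression.

Expression arrives as a sample x probe matrix with each sample mapped to one
individual and one brain region; per-probe values are first averaged within
individual across regions (unweighted), then regressed on genotype dosage
(simple linear regression, no covariates) or correlated with a candidate
transcription factor's expression. The TF screen applies a Bonferroni
multiplier over the number of TFs considered; significance of a correlation
can also be assessed by a lack-of-fit F-test that partitions the residual sum
of squares around the linear fit into lack-of-fit and pure-error components
when the predictor has replicated levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix
from .simulate import ExpressionBundle

__all__ = [
    "EqtlResult",
    "TfCorrelation",
    "average_by_individual",
    "fit_eqtl",
    "tf_correlation_screen",
    "lack_of_fit_f_test",
]


@dataclass
class EqtlResult:
    probe: str
    snp: str
    slope: float
    se: float
    t: float
    p: float
    n_individuals: int
    direction: str  # allele label associated with increased expression


@dataclass
class TfCorrelation:
    tf_name: str
    probe: str
    r: float
    r2: float
    p_raw: float
    p_bonferroni: float
    n_tests: int
    flag: str = ""


def average_by_individual(expr: ExpressionBundle, probe: str) -> pd.Series:
    """Unweighted mean expression of ``probe`` per individual across regions."""
    if probe not in expr.values.columns:
        raise KeyError(f"probe {probe!r} not in expression matrix")
    ind = expr.sample_map.set_index("sample_id")["individual_id"]
    vals = expr.values[probe]
    means = vals.groupby(ind.reindex(vals.index)).mean()
    return means.reindex(expr.individual_ids)


def fit_eqtl(
    expr_by_individual: pd.Series | np.ndarray,
    dosages: pd.Series | np.ndarray,
    snp: str = "?",
    probe: str = "?",
    alleles: tuple[str, str] | None = None,
) -> EqtlResult:
    """Simple linear regression of averaged expression on minor-allele dosage.

    ``alleles`` is the SNP's (major, minor) pair; ``direction`` reports the
    allele whose count increases fitted expression.
    """
    y = np.asarray(expr_by_individual, dtype=float)
    x = np.asarray(dosages, dtype=float)
    keep = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 5:
        raise ValueError(f"({probe}, {snp}): need >=5 complete cases, have {n}")
    if np.var(x) == 0:
        raise ValueError(f"SNP {snp!r} has zero dosage variance")
    res = stats.linregress(x, y)
    t = res.slope / res.stderr if res.stderr > 0 else 0.0
    major, minor = alleles if alleles else ("major", "minor")
    direction = minor if res.slope >= 0 else major
    return EqtlResult(
        probe=probe, snp=snp, slope=float(res.slope), se=float(res.stderr),
        t=float(t), p=float(res.pvalue), n_individuals=n, direction=direction,
    )


def tf_correlation_screen(
    expr: ExpressionBundle,
    tf_probes: list[str],
    target_probe: str,
    n_tests: int | None = None,
) -> list[TfCorrelation]:
    """Pearson correlation of each TF with the target, Bonferroni-corrected.

    p_raw is the F-test p of the regression of the target on the TF (equal to
    the two-sided t-test of the correlation); results are sorted by p_raw
    with NA entries (zero-variance TF) last.
    """
    n_tests = n_tests if n_tests is not None else len(tf_probes)
    if n_tests < len(tf_probes):
        raise ValueError(f"n_tests ({n_tests}) < number of TF probes ({len(tf_probes)})")
    target = average_by_individual(expr, target_probe).to_numpy(dtype=float)
    out = []
    for tf in tf_probes:
        x = average_by_individual(expr, tf).to_numpy(dtype=float)
        keep = ~np.isnan(x) & ~np.isnan(target)
        xv, yv = x[keep], target[keep]
        if xv.size < 3 or np.var(xv) == 0 or np.var(yv) == 0:
            out.append(
                TfCorrelation(tf, target_probe, np.nan, np.nan, np.nan, np.nan,
                              n_tests, flag="zero-variance or too few values")
            )
            continue
        r, p = stats.pearsonr(xv, yv)
        out.append(
            TfCorrelation(tf_name=tf, probe=target_probe, r=float(r), r2=float(r * r),
                          p_raw=float(p), p_bonferroni=min(1.0, float(p) * n_tests),
                          n_tests=n_tests)
        )
    return sorted(out, key=lambda c: (np.isnan(c.p_raw), c.p_raw))


def lack_of_fit_f_test(x, y) -> tuple[float, float, str]:
    """Lack-of-fit F-test of a simple linear regression.

    With replicated x levels, partitions the residual SS around the linear fit
    into pure error (within-level) and lack of fit:
    F = (SS_lof / df_lof) / (SS_pe / df_pe), df_lof = levels - 2,
    df_pe = n - levels. Without any replication the overall regression F-test
    is returned with flag ``"no_replication"``. Returns ``(F, p, flag)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError(f"need >=3 observations, have {n}")
    levels, inverse, counts = np.unique(x, return_inverse=True, return_counts=True)
    if levels.size < 2:
        raise ValueError("x must have >=2 distinct levels")

    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    ss_resid = float(resid @ resid)

    if np.all(counts == 1) or levels.size <= 2:
        # two levels saturate the line (df_lof = 0); either way fall back to
        # the overall regression F
        flag = "no_replication" if np.all(counts == 1) else "saturated_linear"
        ss_tot = float(((y - y.mean()) ** 2).sum())
        ss_reg = ss_tot - ss_resid
        df1, df2 = 1, n - 2
        if ss_resid <= 0:
            return np.inf, 0.0, flag
        f = (ss_reg / df1) / (ss_resid / df2)
        return float(f), float(stats.f.sf(f, df1, df2)), flag

    level_means = np.bincount(inverse, weights=y) / counts
    ss_pe = float(((y - level_means[inverse]) ** 2).sum())
    ss_lof = max(ss_resid - ss_pe, 0.0)
    df_lof = levels.size - 2
    df_pe = n - levels.size
    if df_pe <= 0 or ss_pe <= 0:
        return (0.0, 1.0, "degenerate_pure_error") if ss_lof <= 1e-12 else (
            np.inf, 0.0, "degenerate_pure_error"
        )
    f = (ss_lof / df_lof) / (ss_pe / df_pe)
    return float(f), float(stats.f.sf(f, df_lof, df_pe)), ""
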