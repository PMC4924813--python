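"""SNP-ROI regression and permutation inference against explicit oracles."""

import numpy as np
import pandas as pd
import pytest

from brainvar import (
    AssocModelSpec, SimulationConfig, aggregate_x2, bonferroni, fit_snp_roi,
    genotype_trend_summary, pairwise_scan, permutation_test,
    simulate_genotypes, simulate_roi_phenotypes,
)
from brainvar.association import build_design, RegressionResult

from conftest import make_genotypes


def normal_equations_oracle(X, y):
    """(beta, se, t) for every coefficient by an explicit matrix solve."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = X.shape[0] - X.shape[1]
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    return beta, se, beta / se, df


def _random_tables(rng, n=30):
    g = rng.integers(0, 3, size=n).astype(float)
    covar = pd.DataFrame(
        {
            "age": rng.uniform(20, 60, n).round(1),
            "sex": rng.choice(["female", "male"], n),
            "ethnicity": rng.choice(["african", "asian", "european"], n),
            "handedness": rng.choice(["left", "right"], n),
            "scanner_field": rng.choice(["1.5T", "3T"], n),
        },
        index=[f"S{i}" for i in range(n)],
    )
    pheno = pd.DataFrame(
        {
            "volume:lh.SMG": rng.normal(50, 5, n),
            "volume:global": rng.normal(100, 10, n),
        },
        index=covar.index,
    )
    geno = make_genotypes(g[:, None], snp_ids=["rs1"])
    return pheno, geno, covar


def test_fit_matches_normal_equations_on_random_designs():
    rng = np.random.default_rng(0)
    spec = AssocModelSpec(trait="volume", roi_set=["lh.SMG"])
    for _ in range(25):
        pheno, geno, covar = _random_tables(rng)
        res = fit_snp_roi(pheno, geno, covar, spec, "rs1", "lh.SMG")
        design = build_design(covar, spec, pheno)
        X = design.copy()
        X.insert(1, "genotype", geno.dosages[:, 0])
        beta, se, t, df = normal_equations_oracle(
            X.to_numpy(float), pheno["volume:lh.SMG"].to_numpy(float)
        )
        j = list(X.columns).index("genotype")
        assert res.beta == pytest.approx(beta[j], rel=1e-8)
        assert res.se == pytest.approx(se[j], rel=1e-8)
        assert res.t_stat == pytest.approx(t[j], rel=1e-8)
        assert res.df_resid == df
        assert res.chi2 == pytest.approx(res.t_stat**2, rel=1e-10)


def test_planted_beta_recovered_noise_free():
    cfg = SimulationConfig(
        n_subjects=200, n_snps=1, noise_sd=1e-8, seed=3,
        effect_map=[(0, "lh.SMG", "volume", 5.0)],
    )
    geno = simulate_genotypes(cfg)
    pheno, covar = simulate_roi_phenotypes(geno, cfg)
    spec = AssocModelSpec(trait="volume", roi_set=["lh.SMG"])
    res = fit_snp_roi(pheno, geno, covar, spec, "rs0001", "lh.SMG")
    assert res.beta == pytest.approx(5.0, rel=0.01)
    assert res.p_nominal < 1e-10


def test_constant_phenotype_gives_zero_statistics():
    rng = np.random.default_rng(1)
    pheno, geno, covar = _random_tables(rng)
    pheno["volume:lh.SMG"] = 42.0
    spec = AssocModelSpec(trait="volume", roi_set=["lh.SMG"])
    res = fit_snp_roi(pheno, geno, covar, spec, "rs1", "lh.SMG")
    assert res.beta == pytest.approx(0.0, abs=1e-10)
    assert res.t_stat == 0.0 and res.chi2 == 0.0


def test_collinear_design_raises():
    rng = np.random.default_rng(2)
    pheno, geno, covar = _random_tables(rng)
    covar["age"] = 30.0  # constant -> collinear with intercept
    spec = AssocModelSpec(trait="volume", roi_set=["lh.SMG"])
    with pytest.raises(np.linalg.LinAlgError, match="rank"):
        fit_snp_roi(pheno, geno, covar, spec, "rs1", "lh.SMG")


def test_too_few_subjects_raises():
    rng = np.random.default_rng(3)
    pheno, geno, covar = _random_tables(rng, n=30)
    spec = AssocModelSpec(trait="volume", roi_set=["lh.SMG"])
    with pytest.raises(ValueError, match="complete cases"):
        fit_snp_roi(pheno.iloc[:6], geno, covar, spec, "rs1", "lh.SMG")


def test_validation_model_expressible_via_covariates():
    # swapping handedness for scanner field strength is purely a covariate-list change
    from brainvar.association import VALIDATION_COVARIATES

    rng = np.random.default_rng(4)
    pheno, geno, covar = _random_tables(rng, n=60)
    spec = AssocModelSpec(trait="volume", roi_set=["lh.SMG"],
                          covariates=list(VALIDATION_COVARIATES))
    res = fit_snp_roi(pheno, geno, covar, spec, "rs1", "lh.SMG")
    design = build_design(covar, spec, pheno)
    assert any(c.startswith("scanner_field") for c in design.columns)
    assert not any(c.startswith("handedness") for c in design.columns)
    assert np.isfinite(res.p_nominal)


def test_surface_area_excludes_subcortical_rois():
    with pytest.raises(ValueError, match="volume-only"):
        AssocModelSpec(trait="surface_area", roi_set=["lh.SMG", "CC"])


# ---------------------------------------------------------------- aggregate

def test_aggregate_x2_arithmetic():
    rs = [
        RegressionResult("s", roi, 0, 1, 0, 10, chi2, 1, 30)
        for roi, chi2 in [("a", 1.0), ("b", 2.5), ("c", 0.5)]
    ]
    assert aggregate_x2(rs, ["a", "b", "c"]) == pytest.approx(4.0)
    assert aggregate_x2(rs[:1], ["a"]) == pytest.approx(1.0)
    with pytest.raises(ValueError, match="missing ROI"):
        aggregate_x2(rs, ["a", "b", "c", "d"])


def test_aggregate_null_mean_is_number_of_rois():
    # sum of five 1-df chi-squares has mean 5
    vals = []
    spec = AssocModelSpec(trait="volume")
    for i in range(300):
        cfg = SimulationConfig(n_subjects=100, n_snps=1, seed=40_000 + i)
        geno = simulate_genotypes(cfg)
        pheno, covar = simulate_roi_phenotypes(geno, cfg)
        rs = [fit_snp_roi(pheno, geno, covar, spec, "rs0001", roi)
              for roi in spec.roi_set]
        vals.append(aggregate_x2(rs, spec.roi_set))
    se = np.sqrt(10.0 / len(vals))  # var of 5-df chi-square is 10
    assert abs(np.mean(vals) - 5.0) < 3 * se


# ---------------------------------------------------------------- permutation

def test_addone_rule_lower_bound(small_cohort):
    geno, pheno, covar, _ = small_cohort
    spec = AssocModelSpec(trait="volume")
    # plant an overwhelming effect so the observed statistic beats every perm
    pheno = pheno.copy()
    pheno["volume:lh.SMG"] += 50 * geno.dosages[:, 0]
    res = permutation_test(pheno, geno, covar, spec, snps=["rs0001"],
                           n_perm=200, seed=1)
    assert res[0].p_perm == pytest.approx(1.0 / 201.0)


def test_permutation_matches_exhaustive_enumeration():
    # n=6 subjects: all 720 subject permutations vs Monte-Carlo
    rng = np.random.default_rng(5)
    spec = AssocModelSpec(trait="volume", roi_set=["lh.SMG"], covariates=[],
                          global_covariate=None)
    spec.global_covariate = None
    for trial in range(5):
        g = rng.integers(0, 3, size=6).astype(float)
        while len(set(g)) < 2:
            g = rng.integers(0, 3, size=6).astype(float)
        geno = make_genotypes(g[:, None], snp_ids=["rs1"])
        pheno = pd.DataFrame({"volume:lh.SMG": rng.normal(size=6)},
                             index=geno.subject_ids)
        covar = pd.DataFrame(index=geno.subject_ids)
        exact = permutation_test(pheno, geno, covar, spec, exhaustive=True,
                                 seed=0)[0]
        mc = permutation_test(pheno, geno, covar, spec, n_perm=4000,
                              seed=100 + trial)[0]
        se = np.sqrt(exact.p_perm * (1 - exact.p_perm) / 4000)
        assert abs(mc.p_perm - exact.p_perm) <= 2 * se + 2.0 / 4000


def test_permutation_p_invariant_to_subject_order(small_cohort):
    geno, pheno, covar, _ = small_cohort
    spec = AssocModelSpec(trait="volume")
    res1 = permutation_test(pheno, geno, covar, spec, snps=["rs0001"],
                            n_perm=300, seed=9)
    order = list(pheno.index)[::-1]
    res2 = permutation_test(pheno.loc[order], geno, covar.loc[order], spec,
                            snps=["rs0001"], n_perm=300, seed=9)
    assert res1[0].x2_obs == pytest.approx(res2[0].x2_obs, rel=1e-9)
    # same observed statistic; p differs only by Monte-Carlo noise
    assert abs(res1[0].p_perm - res2[0].p_perm) < 0.1


def test_max_t_not_anticonservative(small_cohort):
    geno, pheno, covar, _ = small_cohort
    spec = AssocModelSpec(trait="volume")
    pairs = pairwise_scan(pheno, geno, covar, spec)
    corrected = permutation_test(pheno, geno, covar, spec, n_perm=500, seed=2,
                                 correction_mode="max_t_snp_roi")
    for res in corrected:
        nominal = pairs.query("snp == @res.snp and roi == @res.roi")[
            "p_nominal"
        ].iloc[0]
        assert res.p_perm >= nominal - 1e-9


def test_max_t_snps_mode_more_conservative(small_cohort):
    geno, pheno, covar, _ = small_cohort
    spec = AssocModelSpec(trait="volume")
    per = permutation_test(pheno, geno, covar, spec, n_perm=400, seed=3,
                           correction_mode="per_snp")
    fam = permutation_test(pheno, geno, covar, spec, n_perm=400, seed=3,
                           correction_mode="max_t_snps")
    for a, b in zip(per, fam):
        assert b.p_perm >= a.p_perm - 1e-12


def test_same_seed_identical_p(small_cohort):
    geno, pheno, covar, _ = small_cohort
    spec = AssocModelSpec(trait="volume")
    r1 = permutation_test(pheno, geno, covar, spec, n_perm=200, seed=7)
    r2 = permutation_test(pheno, geno, covar, spec, n_perm=200, seed=7)
    assert [x.p_perm for x in r1] == [x.p_perm for x in r2]


def test_permutation_argument_validation(small_cohort):
    geno, pheno, covar, _ = small_cohort
    spec = AssocModelSpec(trait="volume")
    with pytest.raises(ValueError, match="n_perm"):
        permutation_test(pheno, geno, covar, spec, n_perm=50, seed=1)
    with pytest.raises(ValueError, match="correction_mode"):
        permutation_test(pheno, geno, covar, spec, n_perm=200, seed=1,
                         correction_mode="nope")


def test_freedman_lane_scheme_agrees_with_genotype_scheme(small_cohort):
    geno, pheno, covar, _ = small_cohort
    spec = AssocModelSpec(trait="volume")
    a = permutation_test(pheno, geno, covar, spec, snps=["rs0001"],
                         n_perm=500, seed=4, scheme="genotype")[0]
    b = permutation_test(pheno, geno, covar, spec, snps=["rs0001"],
                         n_perm=500, seed=4, scheme="freedman_lane")[0]
    assert abs(a.p_perm - b.p_perm) < 0.12  # both valid null schemes


def test_missing_genotypes_travel_with_shuffle():
    cfg = SimulationConfig(n_subjects=80, n_snps=2, missing_rate=0.1, seed=6)
    geno = simulate_genotypes(cfg)
    pheno, covar = simulate_roi_phenotypes(geno, cfg)
    spec = AssocModelSpec(trait="volume")
    res = permutation_test(pheno, geno, covar, spec, n_perm=150, seed=5)
    for r in res:
        assert 0 < r.p_perm <= 1


# ---------------------------------------------------------------- scans

def test_pairwise_scan_shape_and_degenerate_column(small_cohort):
    geno, pheno, covar, _ = small_cohort
    spec = AssocModelSpec(trait="volume")
    pheno = pheno.copy()
    pheno["volume:CC"] = 7.0  # zero variance
    table = pairwise_scan(pheno, geno, covar, spec)
    assert len(table) == geno.n_snps * len(spec.roi_set)
    cc = table[table.roi == "CC"]
    assert cc["p_nominal"].isna().all()
    assert (cc["reason"] != "").all()
    others = table[table.roi != "CC"]
    assert others["p_nominal"].notna().all()


def test_pairwise_scan_planted_pair_is_top_hit():
    hits = 0
    for i in range(20):
        cfg = SimulationConfig(
            n_subjects=300, n_snps=3, seed=50_000 + i,
            effect_map=[(1, "lh.SMG", "volume", 0.8)],
        )
        geno = simulate_genotypes(cfg)
        pheno, covar = simulate_roi_phenotypes(geno, cfg)
        spec = AssocModelSpec(trait="volume")
        table = pairwise_scan(pheno, geno, covar, spec)
        best = table.loc[table["p_nominal"].idxmin()]
        hits += (best.snp == "rs0002") and (best.roi == "lh.SMG")
    assert hits >= 18


# ---------------------------------------------------------------- trend

def test_trend_adjacent_class_difference_noise_free():
    cfg = SimulationConfig(
        n_subjects=300, n_snps=1, noise_sd=1e-9, seed=12,
        effect_map=[(0, "lh.SMG", "volume", 3.0)],
    )
    geno = simulate_genotypes(cfg)
    pheno, covar = simulate_roi_phenotypes(geno, cfg)
    spec = AssocModelSpec(trait="volume")
    tab = genotype_trend_summary(pheno, geno, covar, spec, "rs0001", "lh.SMG")
    means = tab["adjusted_mean"].to_numpy()
    assert means[1] - means[0] == pytest.approx(3.0, abs=1e-5)
    assert means[2] - means[1] == pytest.approx(3.0, abs=1e-5)


def test_trend_missing_class_reported_na():
    rng = np.random.default_rng(13)
    g = rng.choice([0.0, 1.0], size=40)
    geno = make_genotypes(g[:, None], snp_ids=["rs1"])
    covar = pd.DataFrame(
        {"age": rng.uniform(20, 60, 40),
         "sex": rng.choice(["female", "male"], 40),
         "ethnicity": rng.choice(["a", "b"], 40),
         "handedness": rng.choice(["left", "right"], 40)},
        index=geno.subject_ids,
    )
    pheno = pd.DataFrame(
        {"volume:lh.SMG": rng.normal(50, 5, 40),
         "volume:global": rng.normal(100, 10, 40)},
        index=geno.subject_ids,
    )
    spec = AssocModelSpec(trait="volume")
    tab = genotype_trend_summary(pheno, geno, covar, spec, "rs1", "lh.SMG")
    assert np.isnan(tab.loc[tab.dosage == 2, "adjusted_mean"]).all()
    assert tab.loc[tab.dosage != 2, "adjusted_mean"].notna().all()


def test_bonferroni_caps_at_one():
    assert bonferroni(0.02, 3) == pytest.approx(0.06)
    assert bonferroni(0.5, 3) == 1.0
    assert bonferroni(0.1, 1) == pytest.approx(0.1)
    with pytest.raises(ValueError):
        bonferroni(0.1, 0)
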