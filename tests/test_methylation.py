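"""β/M conversion, BH-FDR oracle checks, EWAS models, annotation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from abomics._ols import RankDeficientError, ols_fit
from abomics.methylation import (
    annotate_promoter_region,
    beta_to_m,
    bh_fdr,
    build_design,
    compare_cell_proportions,
    m_to_beta,
    run_ewas,
    snp_conditioned_ewas,
)

# ---------------------------------------------------------------------------
# conversions


def test_m_to_beta_examples():
    assert m_to_beta(0.0) == pytest.approx(0.5)
    assert m_to_beta(1.0) == pytest.approx(2.0 / 3.0, abs=1e-12)
    grid = np.linspace(-20, 20, 101)
    beta = m_to_beta(grid)
    assert np.all(np.diff(beta) > 0)          # strictly increasing
    assert np.all((beta > 0) & (beta < 1))
    assert np.allclose(m_to_beta(-grid), 1 - beta, atol=1e-15)  # symmetry


def test_beta_to_m_examples():
    assert beta_to_m(0.5) == pytest.approx(0.0, abs=1e-15)
    assert beta_to_m(2.0 / 3.0) == pytest.approx(1.0, abs=1e-12)
    for bad in (0.0, 1.0, -0.1, 1.1, np.nan):
        with pytest.raises(ValueError):
            beta_to_m(bad)


def test_roundtrip_within_float64_bounds():
    """Round trip is exact to 1e-12 where float64 can represent it.

    Near |M| = 30 the β value sits within ~2^-30 of 1, so a half-ulp
    rounding of β maps back to an M error of order 2^|M|·2^-54/ln2; the
    1e-12 guarantee therefore holds for |M| ≲ 13 and the error grows
    geometrically beyond.
    """
    core = np.linspace(-13, 13, 521)
    assert np.abs(beta_to_m(m_to_beta(core)) - core).max() < 1e-12
    wide = np.linspace(-30, 30, 601)[1:-1]
    err = np.abs(beta_to_m(m_to_beta(wide)) - wide)
    bound = 2.0 ** np.abs(wide) * 2.0**-50
    assert np.all(err <= np.maximum(bound, 1e-12))


# ---------------------------------------------------------------------------
# Benjamini–Hochberg


def bh_oracle(p):
    """Brute-force step-up: q_(i) = min over j >= i of m p_(j) / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [
            m * p[order[j]] / (j + 1) for j in range(rank_pos, m)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


def test_bh_examples():
    assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    assert bh_fdr([0.2])[0] == pytest.approx(0.2)
    assert np.allclose(bh_fdr([0.4, 0.4, 0.4]), [0.4, 0.4, 0.4])


def test_bh_matches_oracle_on_permutations():
    rng = np.random.default_rng(0)
    base = rng.random(5)
    for perm in itertools.permutations(range(5)):
        p = base[list(perm)]
        assert np.allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)


def test_bh_nan_policy_and_errors():
    with pytest.warns(UserWarning):
        q = bh_fdr([0.01, np.nan, 0.04])
    assert np.isnan(q[1])
    assert np.allclose(q[[0, 2]], bh_oracle([0.01, 0.04]))
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])
    with pytest.raises(ValueError):
        bh_fdr([-0.1])


# ---------------------------------------------------------------------------
# EWAS


def test_injected_cpgs_rank_first(effect_cohort):
    res = run_ewas(
        effect_cohort.methylation, effect_cohort.covariates,
        effect_cohort.o_status,
    )
    promoters = set(effect_cohort.methylation.columns[:5])
    top = set(res.nsmallest(5, "q").index)
    assert top == promoters


def test_single_cpg_matches_statsmodels(effect_cohort):
    """Independent oracle: statsmodels OLS reproduces effect, SE and p."""
    import statsmodels.api as sm

    res = run_ewas(
        effect_cohort.methylation, effect_cohort.covariates,
        effect_cohort.o_status,
    )
    cpg = effect_cohort.methylation.columns[0]
    design = build_design(effect_cohort.covariates, effect_cohort.o_status)
    fit = sm.OLS(effect_cohort.methylation[cpg].to_numpy(),
                 design.to_numpy()).fit()
    j = list(design.columns).index("non_o")
    assert res.loc[cpg, "effect"] == pytest.approx(fit.params[j], abs=1e-10)
    assert res.loc[cpg, "se"] == pytest.approx(fit.bse[j], abs=1e-10)
    assert res.loc[cpg, "p"] == pytest.approx(fit.pvalues[j], abs=1e-10)


def test_effect_equals_adjusted_mean_difference():
    """With covariates orthogonal to X, the X coefficient is the group
    mean difference (OLS algebra)."""
    rng = np.random.default_rng(3)
    n = 200
    x = np.repeat([0.0, 1.0], n // 2)
    z = rng.normal(size=n)
    z[: n // 2] -= z[: n // 2].mean()   # centre within groups => z ⟂ {1, x}
    z[n // 2:] -= z[n // 2:].mean()
    y = 1.0 + 0.7 * x + 0.3 * z + rng.normal(0, 0.1, n)
    fit = ols_fit(np.column_stack([np.ones(n), x, z]), y)
    assert fit.coef[1] == pytest.approx(
        y[x == 1].mean() - y[x == 0].mean(), abs=1e-12
    )


def test_zero_variance_cpg_skipped(effect_cohort):
    meth = effect_cohort.methylation.copy()
    meth["cg_const"] = 0.5
    with pytest.warns(UserWarning, match="constant"):
        res = run_ewas(meth, effect_cohort.covariates, effect_cohort.o_status)
    assert np.isnan(res.loc["cg_const", "p"])
    assert res["p"].drop("cg_const").notna().all()


def test_rank_deficient_design_names_columns(effect_cohort):
    pheno = effect_cohort.covariates.copy()
    pheno["cell_17"] = pheno["cell_01"]   # exact duplicate
    with pytest.raises(RankDeficientError) as err:
        run_ewas(effect_cohort.methylation, pheno, effect_cohort.o_status)
    assert any(c.startswith("cell_") for c in err.value.columns)


def test_genome_wide_flag(effect_cohort):
    res = run_ewas(effect_cohort.methylation, effect_cohort.covariates,
                   effect_cohort.o_status)
    assert (res["genome_wide"] == (res["p"] < 5e-8)).all()


# ---------------------------------------------------------------------------
# SNP-conditioned sensitivity refits


def test_conditioning_on_independent_snp_leaves_effect(effect_cohort):
    rng = np.random.default_rng(11)
    snps = pd.DataFrame(
        {"rs_indep": rng.integers(0, 3, len(effect_cohort.covariates))},
        index=effect_cohort.covariates.index,
    )
    base = run_ewas(effect_cohort.methylation, effect_cohort.covariates,
                    effect_cohort.o_status)
    cond = snp_conditioned_ewas(
        effect_cohort.methylation, effect_cohort.covariates,
        effect_cohort.o_status, snps,
    ).set_index("cpg")
    cpg = effect_cohort.methylation.columns[0]
    # independent covariate barely moves the estimate
    assert cond.loc[cpg, "effect"] == pytest.approx(
        base.loc[cpg, "effect"], abs=3 * base.loc[cpg, "se"]
    )
    assert (cond["status"] == "estimated").all()


def test_conditioning_on_blood_group_dosage_absorbs(effect_cohort):
    x = (effect_cohort.o_status == "nonO").astype(float)
    snps = pd.DataFrame({"rs8176719_dosage": 2 * x})
    cond = snp_conditioned_ewas(
        effect_cohort.methylation, effect_cohort.covariates,
        effect_cohort.o_status, snps,
    )
    assert (cond["status"] == "absorbed").all()
    assert cond["effect"].isna().all()


def test_perfect_tag_snp_absorbed_noisy_tag_not(effect_cohort):
    from abomics.blood_groups import allele_dosage

    tag = allele_dosage(effect_cohort.genotypes["rs8176719"], "G")
    snps = pd.DataFrame(
        {"tag_r2_1": tag}, index=effect_cohort.genotypes.index
    )
    cond = snp_conditioned_ewas(
        effect_cohort.methylation, effect_cohort.covariates,
        effect_cohort.o_status, snps,
    )
    # rs8176719 G dosage determines O/non-O but is not collinear with the
    # 0/1 indicator (three levels), so the signal is partly absorbed yet
    # still estimable; a *binarised* tag (r2 = 1 with X) is fully absorbed.
    snps2 = pd.DataFrame({"carrier": (tag > 0).astype(float)},
                         index=effect_cohort.genotypes.index)
    cond2 = snp_conditioned_ewas(
        effect_cohort.methylation, effect_cohort.covariates,
        effect_cohort.o_status, snps2,
    )
    assert (cond2["status"] == "absorbed").all()
    assert (cond["status"] == "estimated").all()


# ---------------------------------------------------------------------------
# cell proportions & annotation


def test_cell_proportions_null(null_small):
    res = compare_cell_proportions(null_small.covariates, null_small.o_status)
    assert len(res) == 16
    assert (res["q"] > 0.05).all()


def test_cell_proportions_detect_injected_shift(null_small):
    pheno = null_small.covariates.copy()
    x = (null_small.o_status == "nonO").astype(float)
    pheno["cell_03"] = pheno["cell_03"] + 0.05 * x
    res = compare_cell_proportions(pheno, null_small.o_status)
    assert res["q"].idxmin() == "cell_03"
    assert res.loc["cell_03", "q"] < 0.05


def test_cell_proportions_constant_subset(null_small):
    pheno = null_small.covariates.copy()
    pheno["cell_05"] = 0.0625
    with pytest.warns(UserWarning):
        res = compare_cell_proportions(pheno, null_small.o_status)
    assert np.isnan(res.loc["cell_05", "p"])


@pytest.mark.parametrize(
    "chrom,pos,expected",
    [
        ("chr9", 133_273_000, True),
        ("chr9", 133_272_926, True),    # lower boundary
        ("chr9", 133_272_925, False),   # boundary - 1
        ("chr9", 133_276_404, True),    # upper boundary
        ("chr9", 133_276_405, False),
        ("chr8", 133_273_000, False),
        ("9", 133_273_000, True),       # chr prefix optional
    ],
)
def test_promoter_region_annotation(chrom, pos, expected):
    assert annotate_promoter_region(chrom, pos) is expected
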