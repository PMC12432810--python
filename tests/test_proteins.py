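"""Protein differential models, dosage ANOVA/Tukey, A1/A2 gradient."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from abomics.blood_groups import type_cohort
from abomics.proteins import (
    a2_gradient_summary,
    dosage_anova,
    dosage_groups,
    fit_protein_models,
    sex_stratified_models,
)
from abomics.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="module")
def o_higher_cohort():
    """Direct (−0.25) plus mediated (0.5·−0.5) non-O effects total −0.50,
    mirroring a protein that is higher in type O donors."""
    cfg = SimulationConfig(
        n_donors=400, n_cpgs=10, n_promoter_cpgs=2, n_proteins=30,
        effect_XM=0.5, effect_MY=-0.5, effect_XY_direct=-0.25,
        noise_sd_Y=0.5, seed=23,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="module")
def o_higher_calls(o_higher_cohort):
    return type_cohort(o_higher_cohort.genotypes)


def test_total_effect_recovered(o_higher_cohort, o_higher_calls):
    res = fit_protein_models(
        o_higher_cohort.proteins, o_higher_cohort.covariates, o_higher_calls
    )
    row = res.loc["sEselectin_like"]
    assert abs(row["effect"] - (-0.50)) < 3 * row["se"]
    assert row["effect"] < 0          # O donors higher => negative log2FC
    assert row["q"] < 0.05


def test_matches_statsmodels_oracle(o_higher_cohort, o_higher_calls):
    import statsmodels.api as sm

    from abomics.proteins import _protein_design

    res = fit_protein_models(
        o_higher_cohort.proteins, o_higher_cohort.covariates, o_higher_calls
    )
    design = _protein_design(o_higher_cohort.covariates, o_higher_calls)
    y = o_higher_cohort.proteins.loc[design.index, "vWF_like"]
    fit = sm.OLS(y.to_numpy(), design.to_numpy()).fit()
    j = list(design.columns).index("non_o")
    assert res.loc["vWF_like", "effect"] == pytest.approx(fit.params[j], abs=1e-10)
    assert res.loc["vWF_like", "p"] == pytest.approx(fit.pvalues[j], abs=1e-10)


def test_null_cohort_fdr_control(null_small):
    calls = type_cohort(null_small.genotypes)
    res = fit_protein_models(null_small.proteins, null_small.covariates, calls)
    assert (res["q"] < 0.05).sum() <= 2


def test_constant_protein_na(o_higher_cohort, o_higher_calls):
    prot = o_higher_cohort.proteins.copy()
    prot["flat"] = 3.0
    with pytest.warns(UserWarning):
        res = fit_protein_models(prot, o_higher_cohort.covariates, o_higher_calls)
    assert np.isnan(res.loc["flat", "effect"])


def test_permutation_destroys_association(o_higher_cohort, o_higher_calls):
    rng = np.random.default_rng(5)
    perm = o_higher_cohort.proteins.sample(frac=1.0, random_state=17)
    perm.index = o_higher_cohort.proteins.index
    res = fit_protein_models(perm, o_higher_cohort.covariates, o_higher_calls)
    base = fit_protein_models(
        o_higher_cohort.proteins, o_higher_cohort.covariates, o_higher_calls
    )
    assert abs(res.loc["sEselectin_like", "effect"]) < abs(
        base.loc["sEselectin_like", "effect"]
    )
    assert (res["q"] > 0.05).all()


def test_significant_set_invariant_to_column_order(o_higher_cohort, o_higher_calls):
    base = fit_protein_models(
        o_higher_cohort.proteins, o_higher_cohort.covariates, o_higher_calls
    )
    shuffled = o_higher_cohort.proteins.iloc[:, ::-1]
    alt = fit_protein_models(shuffled, o_higher_cohort.covariates, o_higher_calls)
    assert set(base.index[base["q"] < 0.05]) == set(alt.index[alt["q"] < 0.05])


# ---------------------------------------------------------------------------
# sex stratification


def test_pooled_effect_between_strata(o_higher_cohort, o_higher_calls):
    """Generating effects are sex-homogeneous, so the pooled estimate lies
    near both stratum estimates (between them up to sampling noise)."""
    pooled = fit_protein_models(
        o_higher_cohort.proteins, o_higher_cohort.covariates, o_higher_calls
    ).loc["sEselectin_like"]
    strata = sex_stratified_models(
        o_higher_cohort.proteins, o_higher_cohort.covariates, o_higher_calls
    ).set_index(["protein", "sex"])
    f = strata.loc[("sEselectin_like", "F")]
    m = strata.loc[("sEselectin_like", "M")]
    lo, hi = sorted([f["effect"], m["effect"]])
    slack = 1.0 * max(f["se"], m["se"])
    assert lo - slack <= pooled["effect"] <= hi + slack


def test_single_sex_input(o_higher_cohort, o_higher_calls):
    females = o_higher_cohort.covariates[o_higher_cohort.covariates["sex"] == "F"]
    res = sex_stratified_models(
        o_higher_cohort.proteins, females, o_higher_calls
    )
    assert set(res["sex"]) == {"F"}


def test_empty_stratum_errors(o_higher_cohort, o_higher_calls):
    females = o_higher_cohort.covariates[o_higher_cohort.covariates["sex"] == "F"]
    with pytest.raises(ValueError, match="empty stratum"):
        sex_stratified_models(
            o_higher_cohort.proteins, females, o_higher_calls, strata=["F", "M"]
        )


# ---------------------------------------------------------------------------
# dosage ANOVA / Tukey


def test_two_group_anova_equals_squared_t():
    rng = np.random.default_rng(9)
    y = pd.Series(rng.normal(size=60), name="p")
    g = pd.Series(["a"] * 30 + ["b"] * 30)
    res = dosage_anova(y, g)
    t, p = stats.ttest_ind(y[:30], y[30:], equal_var=True)
    assert res.f_statistic == pytest.approx(t**2, rel=1e-10)
    assert res.p == pytest.approx(p, rel=1e-10)


def test_recessive_pattern_tukey():
    """OO shifted, heterozygotes equal to non-O homozygotes: the two OO
    contrasts are significant, dosage1 vs dosage2 is not."""
    rng = np.random.default_rng(31)
    labels = np.array(["dosage0"] * 140 + ["dosage1"] * 160 + ["dosage2"] * 100)
    y = rng.normal(size=400) + np.where(labels == "dosage0", 1.0, 0.0)
    res = dosage_anova(pd.Series(y, name="p"), pd.Series(labels))
    pairs = res.pairwise.set_index(["group_a", "group_b"])["tukey_p"]
    assert pairs.loc[("dosage0", "dosage1")] < 0.05
    assert pairs.loc[("dosage0", "dosage2")] < 0.05
    assert pairs.loc[("dosage1", "dosage2")] > 0.05


def test_anova_p_uniform_under_null():
    rng = np.random.default_rng(77)
    ps = []
    for _ in range(200):
        groups = [rng.normal(size=30) for _ in range(3)]
        ps.append(stats.f_oneway(*groups)[1])
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_small_class_dropped_and_few_classes_error():
    y = pd.Series(np.r_[np.zeros(10), np.ones(10), [5.0]], name="p")
    g = pd.Series(["a"] * 10 + ["b"] * 10 + ["c"])
    with pytest.warns(UserWarning, match="dropped"):
        res = dosage_anova(y, g)
    assert res.dropped == ["c"]
    with pytest.raises(ValueError):
        dosage_anova(pd.Series([1.0, 2.0], name="p"), pd.Series(["a", "a"]))


def test_tukey_p_at_least_pairwise_t():
    rng = np.random.default_rng(13)
    y = pd.Series(rng.normal(size=90), name="p")
    g = pd.Series(np.repeat(["a", "b", "c"], 30))
    res = dosage_anova(y, g)
    for _, row in res.pairwise.iterrows():
        ya = y[g == row["group_a"]]
        yb = y[g == row["group_b"]]
        _, p_t = stats.ttest_ind(ya, yb, equal_var=True)
        assert row["tukey_p"] >= p_t - 1e-12


def test_dosage_groups_mapping(o_higher_calls):
    g3 = dosage_groups(o_higher_calls, "dosage3")
    assert set(g3.dropna()) <= {"dosage0", "dosage1", "dosage2"}
    g6 = dosage_groups(o_higher_calls, "genotype")
    assert set(g6.dropna()) <= {"OO", "AO", "AA", "BO", "BB", "AB"}
    with pytest.raises(ValueError):
        dosage_groups(o_higher_calls, "bogus")


# ---------------------------------------------------------------------------
# A1/A2 gradient


def test_a2_gradient_monotone(o_higher_calls):
    """Means set monotone in H-antigen dose (O > A2 > A1) flag as monotone."""
    rng = np.random.default_rng(3)
    h_dose = o_higher_calls.apply(
        lambda r: 2.0 if r["diplotype"] == "OO"
        else (1.0 if r["a_subtype"] == "A2-carrier"
              else (0.0 if r["a_subtype"] == "A1-carrier" else np.nan)),
        axis=1,
    )
    y = pd.Series(
        h_dose + rng.normal(0, 0.05, len(h_dose)), index=o_higher_calls.index,
        name="p",
    )
    out = a2_gradient_summary(y, o_higher_calls)
    assert out["monotone"].iloc[0] == "monotone"
    means = out["mean"]
    assert means["O"] > means["A2"] > means["A1"]


def test_a2_gradient_ties_and_partial(o_higher_calls):
    y = pd.Series(1.0, index=o_higher_calls.index, name="p")
    out = a2_gradient_summary(y, o_higher_calls)
    assert out["monotone"].iloc[0] == "ties"
    no_a2 = o_higher_calls[o_higher_calls["a_subtype"] != "A2-carrier"]
    out2 = a2_gradient_summary(y.loc[no_a2.index], no_a2)
    assert out2["monotone"].iloc[0] == "partial"
    assert out2.loc["A2", "n"] == 0
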