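"""Plasma-protein association with ABO blood group.

Per-protein linear models of log2 concentration on the non-O indicator with
sex, age, CMV serostatus and FUT2 secretor status as covariates; sex-stratified
refits; one-way ANOVA with Tukey HSD across the six ABO genotype classes (or
the three-level non-O allele dosage grouping); and an A1/A2/O gradient summary
for the H-antigen dose ordering.

Coding convention: non-O = 1, O = 0, so a protein that is higher in type O
donors (e.g. soluble E-selectin) gets a negative log2 fold change, and one
higher in non-O donors (e.g. vWF) a positive one.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .methylation import _mass_univariate, bh_fdr, build_design

__all__ = [
    "fit_protein_models",
    "sex_stratified_models",
    "dosage_anova",
    "dosage_groups",
    "a2_gradient_summary",
    "DosageResult",
]


def _protein_design(pheno, calls, sex=True):
    secr = calls["secretor"].map({"secretor": 1.0, "non-secretor": 0.0})
    design = build_design(
        pheno, calls["o_status"], extra={"secretor": secr}, cells=False, sex=sex
    )
    return design.dropna()


def fit_protein_models(
    proteins: pd.DataFrame, pheno: pd.DataFrame, calls: pd.DataFrame
) -> pd.DataFrame:
    """Differential plasma-protein levels between O and non-O donors.

    Fits ``log2(level) ~ non_o + sex + age + CMV + secretor`` per protein and
    reports the non-O coefficient (log2 fold change non-O vs O), its standard
    error, two-sided p, BH q across all proteins tested, and the
    complete-case n.  Constant proteins yield NA with a warning.
    """
    design = _protein_design(pheno, calls)
    return _mass_univariate(design, proteins, "non_o")


def sex_stratified_models(
    proteins: pd.DataFrame,
    pheno: pd.DataFrame,
    calls: pd.DataFrame,
    strata: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-sex refits (without the sex covariate), BH within each stratum.

    ``strata`` defaults to the sexes observed in the phenotype table; naming
    a stratum with no donors is an error.
    """
    out = []
    if strata is None:
        strata = sorted(pheno["sex"].dropna().unique())
    for sx in strata:
        sub = pheno.index[pheno["sex"] == sx]
        if len(sub) == 0:
            raise ValueError(f"empty stratum: sex={sx}")
        design = _protein_design(pheno.loc[sub], calls.loc[calls.index.intersection(sub)], sex=False)
        res = _mass_univariate(design, proteins, "non_o")
        res["sex"] = sx
        out.append(res)
    if not out:
        raise ValueError("no sex strata present")
    table = pd.concat(out)
    table.index.name = "protein"
    return table.reset_index()


@dataclass
class DosageResult:
    """One-way ANOVA across genotype classes with Tukey HSD pair tests."""

    protein: str
    f_statistic: float
    p: float
    groups: pd.DataFrame    # per class: n, mean, ci_lo, ci_hi
    pairwise: pd.DataFrame  # per pair: diff, tukey_p
    dropped: list


def dosage_groups(calls: pd.DataFrame, model: str = "genotype") -> pd.Series:
    """Group labels for the dosage analysis.

    ``"genotype"`` keeps the six diplotype classes; ``"dosage3"`` collapses to
    the non-O allele dosage grouping OO vs {AO, BO} vs {AA, AB, BB}.
    """
    if model == "genotype":
        g = calls["diplotype"].where(calls["diplotype"] != "unclassified")
        return g
    if model == "dosage3":
        return calls["non_o_dosage"].map({0.0: "dosage0", 1.0: "dosage1", 2.0: "dosage2"})
    raise ValueError("model must be 'genotype' or 'dosage3'")


def dosage_anova(
    protein_vector: pd.Series, groups: pd.Series, ci_level: float = 0.95
) -> DosageResult:
    """One-way ANOVA plus Tukey HSD of a protein across genotype classes.

    Classes with fewer than 2 donors are dropped with a warning; fewer than
    two surviving classes is an error.  Tukey HSD uses the studentized range
    distribution on all surviving pairs.
    """
    df = pd.DataFrame({"y": protein_vector, "g": groups}).dropna()
    sizes = df.groupby("g", observed=True)["y"].size()
    dropped = list(sizes.index[sizes < 2])
    if dropped:
        warnings.warn(f"classes dropped with n<2: {dropped}")
        df = df[~df["g"].isin(dropped)]
    labels = sorted(df["g"].unique())
    if len(labels) < 2:
        raise ValueError("need at least 2 genotype classes with n >= 2")
    samples = [df.loc[df["g"] == lab, "y"].to_numpy() for lab in labels]
    f, p = stats.f_oneway(*samples)
    tuk = stats.tukey_hsd(*samples)
    alpha = 1 - ci_level
    grows = []
    for lab, y in zip(labels, samples):
        m, s, n = y.mean(), y.std(ddof=1), len(y)
        h = stats.t.ppf(1 - alpha / 2, n - 1) * s / np.sqrt(n) if n > 1 else np.nan
        grows.append({"group": lab, "n": n, "mean": m, "ci_lo": m - h, "ci_hi": m + h})
    prows = []
    for i, j in itertools.combinations(range(len(labels)), 2):
        prows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "diff": samples[i].mean() - samples[j].mean(),
                "tukey_p": float(tuk.pvalue[i, j]),
            }
        )
    return DosageResult(
        protein=str(protein_vector.name),
        f_statistic=float(f),
        p=float(p),
        groups=pd.DataFrame(grows).set_index("group"),
        pairwise=pd.DataFrame(prows),
        dropped=dropped,
    )


def dosage_anova_screen(
    proteins: pd.DataFrame,
    calls: pd.DataFrame,
    model: str = "genotype",
) -> pd.DataFrame:
    """ANOVA per protein across genotype classes, BH-corrected across proteins."""
    groups = dosage_groups(calls, model)
    rows = []
    for prot in proteins.columns:
        try:
            res = dosage_anova(proteins[prot], groups)
        except ValueError:
            rows.append({"protein": prot, "f_statistic": np.nan, "p": np.nan})
            continue
        rows.append({"protein": prot, "f_statistic": res.f_statistic, "p": res.p})
    out = pd.DataFrame(rows).set_index("protein")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def a2_gradient_summary(
    protein_vector: pd.Series, calls: pd.Series | pd.DataFrame, ci_level: float = 0.95
) -> pd.DataFrame:
    """Ordered group means for O, A2-carrier and A1-only donors.

    The relative H-antigen dose runs O > A2 > A1, so a protein driven by H
    antigen should show monotone means across the three groups.  Returns one
    row per group present (n, mean, CI) with a ``monotone`` flag: True when
    the three means are strictly monotone, False otherwise, and "ties" when
    adjacent means are equal; NaN rows mark absent groups.
    """
    lab = pd.Series(index=calls.index, dtype=object)
    lab[calls["diplotype"] == "OO"] = "O"
    lab[calls["a_subtype"] == "A2-carrier"] = "A2"
    lab[calls["a_subtype"] == "A1-carrier"] = "A1"
    df = pd.DataFrame({"y": protein_vector, "g": lab}).dropna()
    alpha = 1 - ci_level
    rows = []
    for g in ("O", "A2", "A1"):
        y = df.loc[df["g"] == g, "y"].to_numpy()
        if len(y) == 0:
            rows.append({"group": g, "n": 0, "mean": np.nan,
                         "ci_lo": np.nan, "ci_hi": np.nan})
            continue
        m = y.mean()
        if len(y) > 1:
            h = stats.t.ppf(1 - alpha / 2, len(y) - 1) * y.std(ddof=1) / np.sqrt(len(y))
        else:
            h = np.nan
        rows.append({"group": g, "n": len(y), "mean": m,
                     "ci_lo": m - h, "ci_hi": m + h})
    out = pd.DataFrame(rows).set_index("group")
    means = out["mean"].to_numpy()
    if np.isnan(means).any():
        flag = "partial"
    elif np.any(np.diff(means) == 0):
        flag = "ties"
    elif np.all(np.diff(means) > 0) or np.all(np.diff(means) < 0):
        flag = "monotone"
    else:
        flag = "non-monotone"
    out.attrs["monotone"] = flag
    out["monotone"] = flag
    return out
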