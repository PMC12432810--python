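"""β/M conversion, BH-FDR, and the blood-group EWAS with covariate models.

Methylation at a CpG is expressed either as a β value (fraction methylated,
in (0, 1)) or an M value (logit2 of β): β = 2^M / (2^M + 1), M = log2(β/(1−β)).
The EWAS regresses each CpG on the non-O indicator with sex, age, CMV
serostatus and 16 immune-cell proportions as covariates, and corrects the
per-CpG p values across the run with Benjamini–Hochberg.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import special
from statsmodels.stats.multitest import multipletests

from ._ols import RankDeficientError, check_full_rank, in_span, ols_fit

__all__ = [
    "m_to_beta",
    "beta_to_m",
    "bh_fdr",
    "ABO_PROMOTER_REGION",
    "annotate_promoter_region",
    "run_ewas",
    "snp_conditioned_ewas",
    "compare_cell_proportions",
    "build_design",
]

_LN2 = np.log(2.0)

#: GeneHancer promoter/enhancer region of ABO (GRCh38, 1-based inclusive).
ABO_PROMOTER_REGION = ("chr9", 133_272_926, 133_276_404)

#: Genome-wide significance line conventionally drawn on Manhattan plots.
GENOME_WIDE_P = 5e-8


def m_to_beta(m):
    """β = 2^M / (2^M + 1), the logistic transform of an M value.

    Strictly increasing with β(−M) = 1 − β(M); computed via ``expit`` for
    numerical stability at large |M|.
    """
    return special.expit(_LN2 * np.asarray(m, dtype=float))


def beta_to_m(beta):
    """M = log2(β / (1 − β)); inverse of :func:`m_to_beta`.

    Raises for β outside the open interval (0, 1) — 0 and 1 have no finite
    M value.
    """
    b = np.asarray(beta, dtype=float)
    if np.any(~np.isfinite(b)) or np.any(b <= 0.0) or np.any(b >= 1.0):
        raise ValueError("beta values must lie strictly in (0, 1)")
    return special.logit(b) / _LN2


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up q values, returned in input order.

    q_(i) = min_{j>=i} ( m * p_(j) / j ), capped at 1, where m counts the
    tested (non-NaN) hypotheses.  NaNs propagate with m reduced and a
    warning; p outside [0, 1] is an error.
    """
    p = np.asarray(p, dtype=float)
    flat = p.ravel()
    nan = np.isnan(flat)
    valid = flat[~nan]
    if np.any((valid < 0) | (valid > 1)):
        raise ValueError("p values must lie in [0, 1]")
    q = np.full(flat.shape, np.nan)
    if nan.any():
        warnings.warn(f"bh_fdr: {int(nan.sum())} NaN p values excluded from m")
    if valid.size:
        q[~nan] = multipletests(valid, method="fdr_bh")[1]
    return q.reshape(p.shape)


def annotate_promoter_region(chrom, pos, region=ABO_PROMOTER_REGION) -> bool:
    """True when a 1-based position falls inside the ABO promoter/enhancer
    region GH09J133272 (chr9:133,272,926–133,276,404, inclusive ends)."""
    c = str(chrom)
    if not c.startswith("chr"):
        c = "chr" + c
    return bool(c == region[0] and region[1] <= int(pos) <= region[2])


# ---------------------------------------------------------------------------
# Design-matrix assembly shared by the association modules


def build_design(
    pheno: pd.DataFrame,
    o_status: pd.Series,
    extra: Mapping[str, pd.Series] | None = None,
    cells: bool = True,
    sex: bool = True,
    cmv: bool = True,
) -> pd.DataFrame:
    """Assemble the covariate design shared by the association models.

    Columns: intercept, non_o (non-O=1, O=0), optionally sex_M, age, CMV,
    the 16 cell-proportion columns, plus any ``extra`` named regressors.
    Donors with an unknown blood-group call are dropped.
    """
    keep = o_status.isin(["O", "nonO"])
    idx = pheno.index.intersection(o_status.index[keep])
    d = pd.DataFrame(index=idx)
    d["intercept"] = 1.0
    d["non_o"] = (o_status.loc[idx] == "nonO").astype(float)
    if sex:
        d["sex_M"] = (pheno.loc[idx, "sex"] == "M").astype(float)
    d["age"] = pheno.loc[idx, "age"].astype(float)
    if cmv:
        d["cmv"] = pheno.loc[idx, "cmv"].astype(float)
    if cells:
        cell_cols = [c for c in pheno.columns if c.startswith("cell_")]
        for c in cell_cols:
            d[c] = pheno.loc[idx, c].astype(float)
    for name, series in (extra or {}).items():
        d[name] = pd.Series(series).reindex(idx).astype(float)
    return d


def _mass_univariate(design: pd.DataFrame, Y: pd.DataFrame, coef: str) -> pd.DataFrame:
    """Per-feature OLS of each column of ``Y`` on a shared design.

    Complete-case per feature; zero-variance features are skipped with NA and
    a warning.  Returns effect/se/p/q/n_complete indexed by feature.
    """
    idx = design.index.intersection(Y.index)
    X = design.loc[idx]
    Y = Y.loc[idx]
    check_full_rank(X.to_numpy(), list(X.columns))
    j = list(X.columns).index(coef)
    Xm = X.to_numpy()
    row_ok = ~np.isnan(Xm).any(axis=1)
    Xm = Xm[row_ok]
    Ym = Y.to_numpy(dtype=float)[row_ok]

    n_feat = Ym.shape[1]
    eff = np.full(n_feat, np.nan)
    se = np.full(n_feat, np.nan)
    pv = np.full(n_feat, np.nan)
    nc = np.zeros(n_feat, dtype=int)

    has_nan = np.isnan(Ym).any(axis=0)
    clean = np.where(~has_nan)[0]
    if clean.size:
        Yc = Ym[:, clean]
        var = Yc.var(axis=0)
        const = var == 0
        if const.any():
            warnings.warn(
                f"{int(const.sum())} constant feature(s) skipped (zero variance)"
            )
        ok = clean[~const]
        if ok.size:
            fit = ols_fit(Xm, Ym[:, ok])
            eff[ok], se[ok], pv[ok] = fit.coef[j], fit.se[j], fit.p[j]
        nc[clean] = Xm.shape[0]
    for k in np.where(has_nan)[0]:
        y = Ym[:, k]
        m = ~np.isnan(y)
        nc[k] = int(m.sum())
        if nc[k] <= Xm.shape[1] or y[m].var() == 0:
            warnings.warn(f"feature {Y.columns[k]!r} skipped (constant or too few)")
            continue
        fit = ols_fit(Xm[m], y[m])
        eff[k], se[k], pv[k] = fit.coef[j], fit.se[j], fit.p[j]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        q = bh_fdr(pv)
    return pd.DataFrame(
        {"effect": eff, "se": se, "p": pv, "q": q, "n_complete": nc},
        index=Y.columns,
    )


def run_ewas(
    meth: pd.DataFrame,
    pheno: pd.DataFrame,
    o_status: pd.Series,
    scale: str = "beta",
    gw_threshold: float = GENOME_WIDE_P,
) -> pd.DataFrame:
    """Epigenome-wide association of methylation with O/non-O status.

    Fits, per CpG, ``value ~ non_o + sex + age + CMV + 16 cell proportions``
    by OLS and reports the non-O coefficient with a two-sided t test, BH q
    values across all CpGs tested in the run, and a ``genome_wide`` flag for
    p below ``gw_threshold``.

    Parameters
    ----------
    meth : donors × CpGs matrix of β values.
    scale : "beta" (default, matching the source convention of regressing β)
        or "M" to analyse logit2-transformed values.
    """
    if scale not in ("beta", "M"):
        raise ValueError("scale must be 'beta' or 'M'")
    Y = meth if scale == "beta" else pd.DataFrame(
        beta_to_m(meth.to_numpy()), index=meth.index, columns=meth.columns
    )
    design = build_design(pheno, o_status)
    res = _mass_univariate(design, Y, "non_o")
    res["genome_wide"] = res["p"] < gw_threshold
    return res


def snp_conditioned_ewas(
    meth: pd.DataFrame,
    pheno: pd.DataFrame,
    o_status: pd.Series,
    snp_dosages: pd.DataFrame,
    scale: str = "beta",
) -> pd.DataFrame:
    """Sensitivity refits adding one SNP dosage covariate at a time.

    For each SNP column, the EWAS design gains that SNP's allele dosage and
    every CpG is refit.  A SNP collinear with the non-O indicator (e.g.
    rs8176719 itself, or a tag SNP in perfect LD) makes the blood-group
    coefficient inestimable; such refits are reported with status
    ``"absorbed"`` rather than failing.
    """
    Y = meth if scale == "beta" else pd.DataFrame(
        beta_to_m(meth.to_numpy()), index=meth.index, columns=meth.columns
    )
    base = build_design(pheno, o_status)
    out = []
    for snp in snp_dosages.columns:
        design = base.copy()
        design[snp] = pd.Series(snp_dosages[snp]).reindex(design.index).astype(float)
        design = design.dropna()
        X = design.to_numpy()
        names = list(design.columns)
        try:
            check_full_rank(X, names)
        except RankDeficientError:
            others = design.drop(columns=["non_o"]).to_numpy()
            if in_span(others, design["non_o"].to_numpy()):
                res = pd.DataFrame(
                    {
                        "effect": np.nan,
                        "se": np.nan,
                        "p": np.nan,
                        "q": np.nan,
                        "n_complete": len(design),
                        "snp": snp,
                        "status": "absorbed",
                    },
                    index=Y.columns,
                )
                out.append(res)
                continue
            raise
        res = _mass_univariate(design, Y, "non_o")
        res["snp"] = snp
        res["status"] = "estimated"
        out.append(res)
    table = pd.concat(out)
    table.index.name = "cpg"
    return table.reset_index()


def compare_cell_proportions(
    pheno: pd.DataFrame, o_status: pd.Series
) -> pd.DataFrame:
    """Pre-check that immune-cell proportions do not differ by blood group.

    One linear model per cell subset, ``proportion ~ non_o + sex + age +
    CMV``, BH-corrected across the 16 subsets.  Constant subsets are skipped
    with NA.
    """
    design = build_design(pheno, o_status, cells=False)
    cell_cols = [c for c in pheno.columns if c.startswith("cell_")]
    if not cell_cols:
        raise ValueError("phenotype table has no cell_* proportion columns")
    return _mass_univariate(design, pheno[cell_cols], "non_o")
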