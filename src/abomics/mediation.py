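"""Linear causal mediation with nonparametric bootstrap inference.

The decomposition follows the standard three-regression scheme for a binary
treatment X (non-O status), a continuous mediator M (methylation at one CpG)
and an outcome Y (one plasma protein):

    model XM :  M ~ X + covariates_XM            -> path a
    model XMY:  Y ~ X + M + covariates_XMY       -> paths b and c' (ADE)
    model XY :  Y ~ X + covariates_XMY           -> path c (total effect)

ACME (the indirect effect transmitted through M) is reported by the
difference method, c − c', with the product a·b alongside; the two coincide
exactly when the covariate sets of the two models match, and differ when
they do not (the default mediation model adjusts for cell proportions only
in model XM).  Confidence intervals and p values come from a nonparametric
bootstrap that resamples donors with replacement and refits all three
models per resample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._ols import boot_ols_coef, ols_fit

__all__ = ["MediationResult", "fit_mediation", "proportion_mediated",
           "mediation_screen"]


def proportion_mediated(acme: float, ade: float) -> float:
    """ACME / (ACME + ADE), the share of the total effect that is indirect.

    Undefined (raises) when the total effect ACME + ADE is zero.
    """
    total = acme + ade
    if total == 0:
        raise ZeroDivisionError("total effect is zero; proportion undefined")
    return acme / total


@dataclass
class MediationResult:
    """Point estimates, bootstrap CIs and p values for one (CpG, protein) pair."""

    a: float          # X -> M
    b: float          # M -> Y given X
    c: float          # X -> Y (total)
    c_prime: float    # X -> Y given M (ADE)
    acme: float       # c - c' (difference method)
    acme_product: float  # a * b (product method)
    ade: float
    total: float
    prop_mediated: float
    ci: Mapping[str, tuple] = field(default_factory=dict)
    p: Mapping[str, float] = field(default_factory=dict)
    n: int = 0
    n_boot_effective: int = 0
    n_redrawn: int = 0
    seed: int | None = None
    ci_level: float = 0.95
    scale: str = "unspecified"

    def to_series(self) -> pd.Series:
        d = {k: getattr(self, k) for k in
             ("a", "b", "c", "c_prime", "acme", "acme_product", "ade", "total",
              "prop_mediated", "n", "n_boot_effective", "n_redrawn", "ci_level")}
        for key, (lo, hi) in self.ci.items():
            d[f"{key}_ci_lo"], d[f"{key}_ci_hi"] = lo, hi
        for key, val in self.p.items():
            d[f"{key}_p"] = val
        return pd.Series(d)


def _three_models(X_xm, m, X_xmy_full, X_xy, y, jx_xm, jx_xmy, jm_xmy, jx_xy):
    a = ols_fit(X_xm, m).coef[jx_xm]
    fit = ols_fit(X_xmy_full, y).coef
    c_prime, b = fit[jx_xmy], fit[jm_xmy]
    c = ols_fit(X_xy, y).coef[jx_xy]
    return a, b, c, c_prime


def _boot_p(draws: np.ndarray, n_boot: int) -> float:
    """Two-sided bootstrap p with a +1/(B+1) continuity floor."""
    lo = (np.sum(draws <= 0) + 1) / (n_boot + 1)
    hi = (np.sum(draws >= 0) + 1) / (n_boot + 1)
    return float(min(1.0, 2.0 * min(lo, hi)))


def fit_mediation(
    x: pd.Series,
    m: pd.Series,
    y: pd.Series,
    covariates_xm: pd.DataFrame | None = None,
    covariates_xmy: pd.DataFrame | None = None,
    n_boot: int = 500,
    seed: int | None = None,
    ci_level: float = 0.95,
    scale: str = "unspecified",
    _indices: np.ndarray | None = None,
) -> MediationResult:
    """Point estimates and bootstrap inference for one mediation triple.

    Parameters
    ----------
    x : binary treatment (0/1), both levels required.
    m, y : mediator and outcome, aligned with ``x`` on a shared index.
    covariates_xm, covariates_xmy : covariate frames for the mediator and
        outcome models (they may differ, and do in the default model where
        cell proportions enter only the mediator model).
    n_boot : bootstrap resamples (donors drawn with replacement; resamples
        with a single treatment level are redrawn, capped at 10×n_boot
        attempts).
    scale : free-text tag recording the outcome/mediator scale; carried into
        the result, not interpreted.
    _indices : advanced — explicit (B, n) resample indices, bypassing the RNG
        (used to verify that an identity resample reproduces the point
        estimates).

    Complete cases on the union of all variables are used.
    """
    if not 1 <= n_boot:
        raise ValueError("n_boot must be >= 1")
    if not 0.0 < ci_level < 1.0:
        raise ValueError("ci_level must be in (0, 1)")
    parts = {"x": x, "m": m, "y": y}
    frame = pd.DataFrame(parts)
    for tag, cov in (("xm", covariates_xm), ("xmy", covariates_xmy)):
        if cov is not None:
            for c in cov.columns:
                frame[f"{tag}:{c}"] = cov[c]
    frame = frame.dropna()
    n = len(frame)
    xv = frame["x"].to_numpy(dtype=float)
    levels = np.unique(xv)
    if len(levels) != 2:
        raise ValueError(f"treatment must be binary with both levels present, got {levels}")
    mv = frame["m"].to_numpy(dtype=float)
    yv = frame["y"].to_numpy(dtype=float)
    cov_xm = frame[[c for c in frame.columns if c.startswith("xm:")]].to_numpy(dtype=float)
    cov_xmy = frame[[c for c in frame.columns if c.startswith("xmy:")]].to_numpy(dtype=float)

    ones = np.ones((n, 1))
    X_xm = np.hstack([ones, xv[:, None], cov_xm])
    X_xmy = np.hstack([ones, xv[:, None], mv[:, None], cov_xmy])
    X_xy = np.hstack([ones, xv[:, None], cov_xmy])
    jx, jm = 1, 2

    a, b, c, c_prime = _three_models(X_xm, mv, X_xmy, X_xy, yv, jx, jx, jm, jx)
    acme = c - c_prime
    total = c
    prop = acme / (acme + c_prime) if (acme + c_prime) != 0 else np.nan

    # --- nonparametric bootstrap over donors ---
    rng = np.random.default_rng(seed)
    n_redrawn = 0
    if _indices is not None:
        idx = np.asarray(_indices)
        n_boot_eff = idx.shape[0]
    else:
        idx = rng.integers(0, n, size=(n_boot, n))
        attempts = 0
        while True:
            bad = np.where([(xv[row].min() == xv[row].max()) for row in idx])[0]
            if bad.size == 0:
                break
            attempts += bad.size
            n_redrawn += bad.size
            if attempts > 10 * n_boot:
                raise RuntimeError("too many degenerate bootstrap resamples")
            idx[bad] = rng.integers(0, n, size=(bad.size, n))
        n_boot_eff = n_boot

    a_b = boot_ols_coef(X_xm, mv, idx)[:, jx]
    coef_xmy = boot_ols_coef(X_xmy, yv, idx)
    cprime_b, b_b = coef_xmy[:, jx], coef_xmy[:, jm]
    c_b = boot_ols_coef(X_xy, yv, idx)[:, jx]
    acme_b = c_b - cprime_b
    total_b = c_b
    with np.errstate(divide="ignore", invalid="ignore"):
        prop_b = np.where(c_b != 0, acme_b / c_b, np.nan)

    alpha = 1 - ci_level
    qs = (100 * alpha / 2, 100 * (1 - alpha / 2))
    ci = {}
    pvals = {}
    for name, draws in (
        ("acme", acme_b), ("ade", cprime_b), ("total", total_b),
        ("prop_mediated", prop_b), ("acme_product", a_b * b_b),
    ):
        finite = draws[np.isfinite(draws)]
        if finite.size:
            lo, hi = np.percentile(finite, qs)
        else:
            lo = hi = np.nan
        ci[name] = (float(lo), float(hi))
        pvals[name] = _boot_p(finite, n_boot_eff)

    return MediationResult(
        a=float(a), b=float(b), c=float(c), c_prime=float(c_prime),
        acme=float(acme), acme_product=float(a * b), ade=float(c_prime),
        total=float(total), prop_mediated=float(prop),
        ci=ci, p=pvals, n=n, n_boot_effective=n_boot_eff,
        n_redrawn=n_redrawn, seed=seed, ci_level=ci_level, scale=scale,
    )


def mediation_screen(
    meth: pd.DataFrame,
    proteins: pd.DataFrame,
    x: pd.Series,
    covariates_xm: pd.DataFrame | None = None,
    covariates_xmy: pd.DataFrame | None = None,
    pairs: Sequence[tuple] | None = None,
    n_boot: int = 500,
    seed: int | None = None,
    ci_level: float = 0.95,
    scale: str = "unspecified",
) -> pd.DataFrame:
    """Run :func:`fit_mediation` over candidate (CpG, protein) pairs.

    ``pairs`` defaults to the full cross product of mediator and outcome
    columns.  Each pair gets its own seeded RNG stream.  The ``significant``
    flag marks ACME confidence intervals that exclude zero, and
    ``shared_mediator`` counts, per CpG, how many proteins it significantly
    mediates.  An empty candidate set yields an empty table.
    """
    if pairs is None:
        pairs = [(c, p) for c in meth.columns for p in proteins.columns]
    cols = ["cpg", "protein", "a", "b", "c", "c_prime", "acme", "acme_product",
            "ade", "total", "prop_mediated", "acme_ci_lo", "acme_ci_hi",
            "acme_p", "significant", "n", "n_boot_effective"]
    if len(pairs) == 0:
        return pd.DataFrame(columns=cols)
    streams = np.random.SeedSequence(seed).spawn(len(pairs))
    rows = []
    for (cpg, prot), ss in zip(pairs, streams):
        res = fit_mediation(
            x, meth[cpg], proteins[prot], covariates_xm, covariates_xmy,
            n_boot=n_boot, seed=ss, ci_level=ci_level, scale=scale,
        )
        lo, hi = res.ci["acme"]
        rows.append(
            {
                "cpg": cpg, "protein": prot, "a": res.a, "b": res.b,
                "c": res.c, "c_prime": res.c_prime, "acme": res.acme,
                "acme_product": res.acme_product, "ade": res.ade,
                "total": res.total, "prop_mediated": res.prop_mediated,
                "acme_ci_lo": lo, "acme_ci_hi": hi,
                "acme_p": res.p["acme"],
                "significant": bool(lo > 0 or hi < 0),
                "n": res.n, "n_boot_effective": res.n_boot_effective,
            }
        )
    table = pd.DataFrame(rows, columns=cols)
    shared = table.groupby("cpg")["significant"].sum()
    table["shared_mediator"] = table["cpg"].map(shared)
    return table
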