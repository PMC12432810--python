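"""Vectorised ordinary-least-squares helpers shared by the association modules.

All mass-univariate fits in this package (per-CpG EWAS, per-protein models,
attenuation refits, mediation bootstrap) share one design matrix and differ only
in the response, so coefficients for thousands of responses come from a single
QR factorisation.  Bootstrap resamples, which each have a different design, use
batched normal equations instead.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
from scipy import linalg, stats


class RankDeficientError(np.linalg.LinAlgError):
    """Design matrix is rank deficient; ``columns`` names the collinear ones."""

    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(self.columns)
        )


class OLSFit(NamedTuple):
    coef: np.ndarray  # (p,) or (p, k)
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df_resid: int


def check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    """Raise :class:`RankDeficientError` naming the offending columns.

    Uses column-pivoted QR: the pivots beyond the numerical rank are the
    columns that lie (numerically) in the span of the preceding ones.
    """
    X = np.asarray(X, dtype=float)
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = np.finfo(float).eps * max(X.shape) * (diag.max() if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    if rank < X.shape[1]:
        raise RankDeficientError([names[j] for j in piv[rank:]])


def ols_fit(X: np.ndarray, Y: np.ndarray) -> OLSFit:
    """Fit ``Y ~ X`` by least squares for one or many response columns.

    Parameters
    ----------
    X : (n, p) design matrix, full column rank required.
    Y : (n,) or (n, k) responses sharing the design.

    Returns coefficients, standard errors, t statistics and two-sided p
    values (t distribution on ``n - p`` degrees of freedom), shaped ``(p,)``
    for a single response and ``(p, k)`` otherwise.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    single = Y.ndim == 1
    if single:
        Y = Y[:, None]
    n, p = X.shape
    df = n - p
    if df <= 0:
        raise ValueError(f"need more observations ({n}) than parameters ({p})")
    Q, R = np.linalg.qr(X)
    rdiag = np.abs(np.diag(R))
    if rdiag.min() <= np.finfo(float).eps * max(n, p) * rdiag.max():
        raise RankDeficientError([f"x{j}" for j in range(p)])
    coef = linalg.solve_triangular(R, Q.T @ Y)
    resid = Y - X @ coef
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    Rinv = linalg.solve_triangular(R, np.eye(p))
    unscaled = np.einsum("ij,ij->i", Rinv, Rinv)  # diag of (X'X)^-1
    se = np.sqrt(unscaled[:, None] * sigma2[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / se
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    if single:
        return OLSFit(coef[:, 0], se[:, 0], t[:, 0], pvals[:, 0], df)
    return OLSFit(coef, se, t, pvals, df)


def in_span(X: np.ndarray, v: np.ndarray, rtol: float = 1e-8) -> bool:
    """True when vector ``v`` lies numerically in the column span of ``X``."""
    X = np.asarray(X, dtype=float)
    v = np.asarray(v, dtype=float)
    coef, *_ = np.linalg.lstsq(X, v, rcond=None)
    resid = v - X @ coef
    scale = np.linalg.norm(v) or 1.0
    return bool(np.linalg.norm(resid) <= rtol * scale)


def boot_ols_coef(X: np.ndarray, y: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Coefficients for a batch of bootstrap resamples.

    ``idx`` is a (B, n) integer array of donor indices; returns (B, p)
    coefficient vectors via batched normal equations (the designs are small
    and well conditioned, so Gram solves are adequate and fast).
    """
    Xb = X[idx]                     # (B, n, p)
    yb = y[idx]                     # (B, n)
    G = np.einsum("bni,bnj->bij", Xb, Xb)
    h = np.einsum("bni,bn->bi", Xb, yb)
    return np.linalg.solve(G, h[..., None])[..., 0]
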