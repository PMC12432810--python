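"""Covariate-adjustment screen: does a CpG absorb the blood-group effect?

For every (protein, CpG) pair the protein model is refit with the CpG's
methylation added as a covariate:

    log2(level) ~ non_o + sex + age + CMV + secretor + CpG

If the CpG mediates the blood-group→protein path, the non-O coefficient
shrinks toward zero (the adjusted coefficient is the direct effect), and
loses significance.  The result is an attenuation matrix whose first row is
the unadjusted baseline (identical to the plain protein models) and whose
remaining rows are the CpG-adjusted refits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .methylation import _mass_univariate, bh_fdr
from .proteins import _protein_design

__all__ = ["AttenuationMatrix", "adjusted_effect_matrix"]

BASELINE = "baseline"


@dataclass
class AttenuationMatrix:
    """Long-format screen results plus (cpgs+1) × proteins pivots."""

    long: pd.DataFrame  # columns: cpg, protein, effect, se, p, q, significant

    @property
    def effects(self) -> pd.DataFrame:
        return self.long.pivot(index="cpg", columns="protein", values="effect").reindex(
            self._row_order()
        )

    @property
    def q_values(self) -> pd.DataFrame:
        return self.long.pivot(index="cpg", columns="protein", values="q").reindex(
            self._row_order()
        )

    @property
    def significant(self) -> pd.DataFrame:
        return self.long.pivot(
            index="cpg", columns="protein", values="significant"
        ).reindex(self._row_order())

    def _row_order(self):
        rows = list(dict.fromkeys(self.long["cpg"]))
        rows.remove(BASELINE)
        return [BASELINE] + rows

    @property
    def shape(self):
        return self.effects.shape


def adjusted_effect_matrix(
    proteins: pd.DataFrame,
    meth: pd.DataFrame,
    pheno: pd.DataFrame,
    calls: pd.DataFrame,
    cpg_set: Sequence[str],
    protein_set: Sequence[str] | None = None,
    q_threshold: float = 0.05,
    fdr_scope: str = "row",
) -> AttenuationMatrix:
    """Re-estimate the non-O protein effect with each CpG as a covariate.

    Donors are intersected across the genotype calls, methylation and protein
    tables.  The baseline row refits the unadjusted protein model on that
    intersection (and therefore matches :func:`~abomics.proteins.
    fit_protein_models` run on the same donors exactly).  FDR is applied per
    covariate row across proteins by default (``fdr_scope="row"``), or over
    the whole matrix with ``"global"``.  A CpG constant on the intersected
    donors yields a row of NAs with a warning.
    """
    if fdr_scope not in ("row", "global"):
        raise ValueError("fdr_scope must be 'row' or 'global'")
    prot_cols = list(protein_set) if protein_set is not None else list(proteins.columns)
    donors = (
        proteins.index.intersection(meth.index)
        .intersection(pheno.index)
        .intersection(calls.index)
    )
    if len(donors) == 0:
        raise ValueError("no donors shared across proteins, methylation and calls")
    prot = proteins.loc[donors, prot_cols]
    base_design = _protein_design(pheno.loc[donors], calls.loc[donors])

    blocks = []
    base = _mass_univariate(base_design, prot, "non_o")
    base["cpg"] = BASELINE
    blocks.append(base)
    for cpg in cpg_set:
        mvals = meth.loc[donors, cpg].astype(float)
        if mvals.var() == 0 or mvals.isna().all():
            warnings.warn(f"CpG {cpg} constant on intersected donors; row is NA")
            na = pd.DataFrame(
                {"effect": np.nan, "se": np.nan, "p": np.nan, "q": np.nan,
                 "n_complete": 0, "cpg": cpg},
                index=prot.columns,
            )
            blocks.append(na)
            continue
        design = base_design.copy()
        design[cpg] = mvals.reindex(base_design.index)
        design = design.dropna()
        res = _mass_univariate(design, prot, "non_o")
        res["cpg"] = cpg
        blocks.append(res)

    long = pd.concat(blocks)
    long.index.name = "protein"
    long = long.reset_index()
    if fdr_scope == "global":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            long["q"] = bh_fdr(long["p"].to_numpy())
    long["significant"] = long["q"] < q_threshold
    long = long[["cpg", "protein", "effect", "se", "p", "q", "significant",
                 "n_complete"]]
    return AttenuationMatrix(long=long)
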