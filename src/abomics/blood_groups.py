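"""Genotype-based ABO and FUT2 secretor typing, plus two-locus LD statistics.

O/non-O status is read off rs8176719 (c.261delG): the single-base deletion
truncates the ABO glycosyltransferase, so deletion homozygotes (``-/-``) are
type O while G carriers are non-O.  The six-class diplotype (OO, AO, AA, BO,
BB, AB) additionally uses the two coding SNPs that distinguish the A and B
transferases, rs8176746 (Leu266Met, B carries T) and rs8176747 (Gly268Ala, B
carries G).  rs1053878 separates A1 from A2 haplotypes, and FUT2 secretor
status is read off rs601338 (A/A homozygotes are non-secretors).

Rule table (diplotype imputation):

    rs8176719  rs8176746  rs8176747   diplotype
    -/-        any        any         OO
    -/G        G/G        C/C         AO
    G/G        G/G        C/C         AA
    -/G        G/T        (C/G)       BO
    G/G        T/T        (G/G)       BB
    G/G        G/T        C/G         AB

rs8176747 in parentheses is optional for the B rows (the two-locus text rule
suffices) but, when present, must match; any other combination is
``unclassified``.  Classification deliberately ignores rare non-deletion O
alleles (c.802G>A, ~2% of O alleles), which tag-SNP panels cannot see.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MalformedGenotypeError",
    "UndefinedLDError",
    "TAG_LOCI",
    "ALL_LOCI",
    "call_o_status",
    "call_abo_diplotype",
    "call_secretor",
    "call_a_subtype",
    "non_o_dosage",
    "phenotype_of",
    "type_cohort",
    "cohort_frequencies",
    "allele_dosage",
    "ld_stats",
]

TAG_LOCI = ("rs8176719", "rs8176746", "rs8176747", "rs1053878")
ALL_LOCI = TAG_LOCI + ("rs601338",)

#: Valid alleles per locus; "-" is the rs8176719 single-base deletion.
LOCUS_ALLELES: Mapping[str, frozenset] = {
    "rs8176719": frozenset({"G", "-"}),
    "rs8176746": frozenset({"G", "T"}),
    "rs8176747": frozenset({"C", "G"}),
    "rs1053878": frozenset({"G", "A"}),
    "rs601338": frozenset({"G", "A"}),
}

DIPLOTYPES = ("OO", "AO", "AA", "BO", "BB", "AB")
_PHENOTYPE = {"OO": "O", "AO": "A", "AA": "A", "BO": "B", "BB": "B", "AB": "AB"}
_DOSAGE = {"OO": 0, "AO": 1, "BO": 1, "AA": 2, "AB": 2, "BB": 2}


class MalformedGenotypeError(ValueError):
    """A genotype call contains alleles impossible at its locus."""


class UndefinedLDError(ValueError):
    """LD statistics are undefined (monomorphic or non-biallelic locus)."""


def _parse_call(call, locus: str | None = None):
    """Normalise a diploid call to a sorted allele tuple, or None if missing.

    Accepts "X/Y" strings, 2-tuples/lists, None and NaN.  Alleles are
    validated against the locus when one is named.
    """
    if call is None:
        return None
    if isinstance(call, float) and math.isnan(call):
        return None
    if isinstance(call, str):
        if call in ("", ".", "./.", "NA", "nan"):
            return None
        alleles = call.split("/")
    else:
        alleles = list(call)
    if len(alleles) != 2:
        raise MalformedGenotypeError(f"expected 2 alleles, got {call!r}")
    alleles = tuple(sorted(str(a).strip() for a in alleles))
    if locus is not None:
        valid = LOCUS_ALLELES.get(locus)
        if valid is not None and not set(alleles) <= valid:
            raise MalformedGenotypeError(
                f"{locus}: alleles {alleles} outside {sorted(valid)}"
            )
    return alleles


def call_o_status(rs8176719_call) -> str:
    """O / non-O status from rs8176719: -/- is O; G/- and G/G are non-O."""
    g = _parse_call(rs8176719_call, "rs8176719")
    if g is None:
        return "unknown"
    return "O" if g == ("-", "-") else "nonO"


def call_abo_diplotype(rs8176719_call, rs8176746_call, rs8176747_call=None) -> str:
    """Six-class ABO diplotype by exact lookup against the rule table.

    Combinations absent from the table (and calls with a missing locus that
    the matching row requires) return ``"unclassified"``.
    """
    g719 = _parse_call(rs8176719_call, "rs8176719")
    if g719 is None:
        return "unclassified"
    if g719 == ("-", "-"):
        return "OO"
    g746 = _parse_call(rs8176746_call, "rs8176746")
    g747 = _parse_call(rs8176747_call, "rs8176747")
    if g719 == ("-", "G"):
        if g746 == ("G", "G"):
            return "AO" if g747 == ("C", "C") else "unclassified"
        if g746 == ("G", "T"):
            return "BO" if g747 in (None, ("C", "G")) else "unclassified"
    elif g719 == ("G", "G"):
        if g746 == ("G", "G"):
            return "AA" if g747 == ("C", "C") else "unclassified"
        if g746 == ("T", "T"):
            return "BB" if g747 in (None, ("G", "G")) else "unclassified"
        if g746 == ("G", "T"):
            return "AB" if g747 == ("C", "G") else "unclassified"
    return "unclassified"


def call_secretor(rs601338_call) -> str:
    """FUT2 secretor status: G/G and G/A secrete; A/A does not."""
    g = _parse_call(rs601338_call, "rs601338")
    if g is None:
        return "unknown"
    return "non-secretor" if g == ("A", "A") else "secretor"


def call_a_subtype(diplotype: str, rs1053878_call, a2_allele: str = "A") -> str:
    """A1/A2 subtype for A-bearing diplotypes.

    ``a2_allele`` selects which rs1053878 allele tags A2 haplotypes (the
    rule table does not pin down the direction; the alternate allele
    ``"A"`` is the default).
    """
    if a2_allele not in ("A", "G"):
        raise ValueError("a2_allele must be 'A' (alt) or 'G' (ref)")
    if diplotype in ("OO", "BO", "BB"):
        return "not-A"
    if diplotype not in ("AO", "AA", "AB"):
        return "unknown"
    g = _parse_call(rs1053878_call, "rs1053878")
    if g is None:
        return "unknown"
    return "A2-carrier" if a2_allele in g else "A1-carrier"


def phenotype_of(diplotype: str) -> str:
    """Project a diplotype onto the four serological phenotypes."""
    return _PHENOTYPE.get(diplotype, "unknown")


def non_o_dosage(diplotype: str) -> float:
    """Count of non-O alleles: OO=0; AO,BO=1; AA,AB,BB=2; else NaN."""
    return float(_DOSAGE.get(diplotype, np.nan))


def type_cohort(genotypes: pd.DataFrame, a2_allele: str = "A") -> pd.DataFrame:
    """Impute blood-group calls for every donor of a genotype table.

    Parameters
    ----------
    genotypes : DataFrame indexed by donor with one column per locus
        (``rs8176719`` ... ``rs601338``), values "X/Y" strings or missing.
    a2_allele : which rs1053878 allele tags A2 (see :func:`call_a_subtype`).

    Returns a DataFrame with columns ``o_status``, ``diplotype``,
    ``phenotype``, ``a_subtype``, ``non_o_dosage``, ``secretor``.
    """
    def col(locus):
        if locus in genotypes.columns:
            return genotypes[locus]
        return pd.Series([None] * len(genotypes), index=genotypes.index)

    g719, g746, g747 = col("rs8176719"), col("rs8176746"), col("rs8176747")
    g1053, g601 = col("rs1053878"), col("rs601338")

    rows = []
    for i in range(len(genotypes)):
        diplo = call_abo_diplotype(g719.iloc[i], g746.iloc[i], g747.iloc[i])
        rows.append(
            {
                "o_status": call_o_status(g719.iloc[i]),
                "diplotype": diplo,
                "phenotype": phenotype_of(diplo),
                "a_subtype": call_a_subtype(diplo, g1053.iloc[i], a2_allele),
                "non_o_dosage": non_o_dosage(diplo),
                "secretor": call_secretor(g601.iloc[i]),
            }
        )
    return pd.DataFrame(rows, index=genotypes.index)


def cohort_frequencies(calls: pd.DataFrame) -> pd.DataFrame:
    """Counts and proportions per o_status / diplotype / phenotype category.

    Proportions are taken over determinate calls ("unknown" and missing are
    excluded from the denominator; "unclassified" diplotypes are kept as a
    determinate level).  An empty input yields an empty table.
    """
    out = []
    for category in ("o_status", "diplotype", "phenotype"):
        if category not in calls.columns or len(calls) == 0:
            continue
        counts = calls[category].value_counts(dropna=True)
        determinate = counts.drop(index=["unknown"], errors="ignore")
        denom = int(determinate.sum())
        for level, count in counts.items():
            prop = count / denom if denom and level != "unknown" else np.nan
            out.append(
                {
                    "category": category,
                    "level": level,
                    "count": int(count),
                    "proportion": prop,
                }
            )
    return pd.DataFrame(out, columns=["category", "level", "count", "proportion"])


def allele_dosage(calls: Iterable, allele: str, locus: str | None = None) -> np.ndarray:
    """Per-donor count (0/1/2, NaN when missing) of ``allele`` in each call."""
    out = []
    for c in calls:
        g = _parse_call(c, locus)
        out.append(np.nan if g is None else float(sum(a == allele for a in g)))
    return np.asarray(out)


# ---------------------------------------------------------------------------
# Two-locus linkage disequilibrium from unphased genotypes


def _biallelic_dosages(calls, label):
    pairs = [_parse_call(c) for c in calls]
    alleles = sorted({a for g in pairs if g is not None for a in g})
    if len(alleles) < 2:
        raise UndefinedLDError(f"locus {label} is monomorphic")
    if len(alleles) > 2:
        raise UndefinedLDError(f"locus {label} is not biallelic: {alleles}")
    ref = alleles[0]
    dos = np.array(
        [np.nan if g is None else float(sum(a != ref for a in g)) for g in pairs]
    )
    return dos


def ld_stats(
    locus_a_calls: Sequence,
    locus_b_calls: Sequence,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> dict:
    """D, D' and r² between two biallelic loci, phased by two-locus EM.

    Haplotype frequencies are estimated by expectation-maximisation from
    unphased diploid genotypes (only double heterozygotes are phase
    ambiguous), initialised at linkage equilibrium and iterated to ``tol`` or
    ``max_iter``.  D' uses |D| / D_max; r² = D² / (pA·pa·pB·pb).
    """
    da = _biallelic_dosages(locus_a_calls, "A")
    db = _biallelic_dosages(locus_b_calls, "B")
    keep = ~(np.isnan(da) | np.isnan(db))
    da, db = da[keep].astype(int), db[keep].astype(int)
    n = len(da)
    if n < 2:
        raise UndefinedLDError("need at least 2 donors with complete calls")
    if da.min() == da.max():
        raise UndefinedLDError("locus A is monomorphic on complete cases")
    if db.min() == db.max():
        raise UndefinedLDError("locus B is monomorphic on complete cases")

    # 3x3 genotype table; haplotypes indexed (i, j) = (allele at A, allele at B)
    counts = np.zeros((3, 3))
    np.add.at(counts, (da, db), 1.0)
    pA = da.mean() / 2.0  # freq of alt allele at A
    pB = db.mean() / 2.0
    h = np.array(
        [
            [(1 - pA) * (1 - pB), (1 - pA) * pB],
            [pA * (1 - pB), pA * pB],
        ]
    )
    # Unambiguous haplotype counts from the eight determinate genotype classes.
    base = np.zeros((2, 2))
    for i in range(3):
        for j in range(3):
            c = counts[i, j]
            if c == 0 or (i == 1 and j == 1):
                continue
            # genotype (i, j) contributes known haplotypes
            a_alleles = [0] * (2 - i) + [1] * i
            b_alleles = [0] * (2 - j) + [1] * j
            if i in (0, 2):
                for bj in b_alleles:
                    base[a_alleles[0], bj] += c
            else:  # j in (0, 2), i == 1
                for ai in a_alleles:
                    base[ai, b_alleles[0]] += c
    ndh = counts[1, 1]
    for _ in range(max_iter):
        new = base.copy()
        if ndh:
            cis = h[0, 0] * h[1, 1]
            trans = h[0, 1] * h[1, 0]
            w = 0.5 if cis + trans == 0 else cis / (cis + trans)
            new[0, 0] += ndh * w
            new[1, 1] += ndh * w
            new[0, 1] += ndh * (1 - w)
            new[1, 0] += ndh * (1 - w)
        new /= new.sum()
        if np.abs(new - h).max() < tol:
            h = new
            break
        h = new

    pA, pB = h[1].sum(), h[:, 1].sum()
    D = h[1, 1] - pA * pB
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    dprime = abs(D) / dmax if dmax > 0 else np.nan
    denom = pA * (1 - pA) * pB * (1 - pB)
    r2 = D * D / denom if denom > 0 else np.nan
    return {"D": D, "D_prime": dprime, "r2": r2, "n": n}
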