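"""Synthetic cohort generator with the statistical structure the analyses assume.

The generator emulates a healthy-donor multi-omics cohort: ABO haplotypes
{O, A1, A2, B} drawn i.i.d. from configured frequencies and paired at random
(Hardy–Weinberg equilibrium), tag-SNP genotypes derived deterministically from
the haplotypes (so tag SNPs are in perfect LD with the blood-group alleles),
sex-balanced covariates with ages stratified across decades, methylation with
a non-O effect injected at promoter CpGs on the M scale, and plasma proteins
carrying both a direct non-O effect and a methylation-mediated one:

    M_cpg = baseline + a·X + ε,          ε ~ N(0, noise_sd_M)     (promoter CpGs)
    Y_prot = baseline + b·M + c'·X + η,  η ~ N(0, noise_sd_Y)     (focal proteins)

with X the non-O indicator.  The generating coefficients are recorded in a
truth table, so the true mediated effect (ACME) of every focal (CpG, protein)
pair is a·b by construction.  Default allele frequencies derive from European
reference genotype counts (O 1255/1996, A 590/1996, B 151/1996).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .methylation import ABO_PROMOTER_REGION, m_to_beta

__all__ = ["SimulationConfig", "SyntheticCohort", "generate_cohort", "null_cohort"]


class InvalidConfigError(ValueError):
    """Simulation configuration violates an invariant."""


#: Tag alleles carried by each ABO haplotype at
#: (rs8176719, rs8176746, rs8176747, rs1053878).  O haplotypes carry the
#: c.261delG deletion ("-"); B carries T/G at the two transferase SNPs; A2 is
#: tagged by the rs1053878 alternate allele.
HAPLOTYPE_TAGS: Mapping[str, tuple] = {
    "O": ("-", "G", "C", "G"),
    "A1": ("G", "G", "C", "G"),
    "A2": ("G", "G", "C", "A"),
    "B": ("G", "T", "G", "G"),
}
TAG_LOCI = ("rs8176719", "rs8176746", "rs8176747", "rs1053878")

N_CELL_SUBSETS = 16
#: Symmetric Dirichlet concentration for the 16 cell-subset proportions.
CELL_DIRICHLET_ALPHA = 5.0

FOCAL_PROTEIN_NAMES = ("sEselectin_like", "vWF_like")


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters for one synthetic cohort.

    Defaults encode the emulated study conditions: ~1000 donors balanced by
    sex and stratified over five age decades, European ABO allele
    frequencies, 2,000 CpGs of which 10 sit in the ABO promoter region and
    carry the blood-group methylation effect, and 229 plasma proteins of
    which two (E-selectin-like, vWF-like) carry a partially mediated non-O
    effect.
    """

    n_donors: int = 1000
    allele_freqs: Mapping[str, float] = field(
        default_factory=lambda: {"O": 1255 / 1996, "A": 590 / 1996, "B": 151 / 1996}
    )
    a2_fraction_of_A: float = 0.072 / 0.295  # A1 22.3% vs A2 7.2% allele freq
    secretor_allele_freq: float = 0.52       # rs601338 G; ~23% non-secretors
    n_cpgs: int = 2000
    n_promoter_cpgs: int = 10
    n_proteins: int = 229
    effect_XM: float = 0.5    # non-O effect on promoter-CpG M values (M units)
    effect_MY: float = 2.0    # mediator (M value) effect on focal proteins
    effect_XY_direct: float = 1.0  # direct non-O effect on focal proteins
    noise_sd_M: float = 0.5
    noise_sd_Y: float = 1.0
    age_decades: Sequence[tuple] = (
        (20, 29), (30, 39), (40, 49), (50, 59), (60, 69)
    )
    cmv_prevalence: float = 0.35
    seed: int = 0

    def validate(self) -> None:
        freqs = dict(self.allele_freqs)
        if set(freqs) != {"O", "A", "B"}:
            raise InvalidConfigError("allele_freqs must have keys O, A, B")
        for k, v in freqs.items():
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"allele frequency {k}={v} outside [0,1]")
        if abs(sum(freqs.values()) - 1.0) > 1e-12:
            raise InvalidConfigError("allele frequencies must sum to 1")
        for name in ("a2_fraction_of_A", "secretor_allele_freq", "cmv_prevalence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name}={v} outside [0,1]")
        for name in ("n_donors", "n_cpgs", "n_promoter_cpgs", "n_proteins"):
            if getattr(self, name) < 1:
                raise InvalidConfigError(f"{name} must be >= 1")
        if self.n_promoter_cpgs > self.n_cpgs:
            raise InvalidConfigError("n_promoter_cpgs cannot exceed n_cpgs")
        if self.noise_sd_M <= 0 or self.noise_sd_Y <= 0:
            raise InvalidConfigError("noise standard deviations must be > 0")
        if not self.age_decades:
            raise InvalidConfigError("age_decades must be non-empty")


@dataclass
class SyntheticCohort:
    """One generated cohort; all tables share a single donor index order."""

    config: SimulationConfig
    genotypes: pd.DataFrame       # donors × loci, "X/Y" call strings
    covariates: pd.DataFrame      # sex, age, cmv, secretor, cell_01..cell_16
    methylation: pd.DataFrame     # donors × CpGs, β values in (0, 1)
    cpg_annotation: pd.DataFrame  # cpg_id, chrom, pos (1-based)
    proteins: pd.DataFrame        # donors × proteins, log2 concentrations
    truth: pd.DataFrame           # per focal pair: a, b, c_prime, acme, total
    diplotypes: pd.Series         # generated six-class ABO diplotype

    @property
    def o_status(self) -> pd.Series:
        return pd.Series(
            np.where(self.diplotypes == "OO", "O", "nonO"),
            index=self.diplotypes.index,
            name="o_status",
        )


def _diplotype_label(g1: str, g2: str) -> str:
    return "".join(sorted((g1, g2)))


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw one cohort from the generative model described in the module docs.

    Identical configs (including seed) produce bit-identical cohorts; the
    per-component RNG streams are spawned from one seed sequence, so e.g.
    enlarging the protein panel does not perturb the genotypes.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    r_hap, r_cov, r_meth, r_prot, r_fut2 = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    n = config.n_donors
    donors = pd.Index([f"donor_{i:05d}" for i in range(n)], name="donor_id")

    # --- haplotypes and tag-SNP genotypes (HWE by i.i.d. pairing) ---
    freqs = dict(config.allele_freqs)
    a2 = config.a2_fraction_of_A
    probs = [freqs["O"], freqs["A"] * (1 - a2), freqs["A"] * a2, freqs["B"]]
    hap_names = np.array(["O", "A1", "A2", "B"])
    haps = hap_names[r_hap.choice(4, size=(n, 2), p=probs)]
    group = np.char.replace(np.char.replace(haps, "A1", "A"), "A2", "A")
    diplo = pd.Series(
        [_diplotype_label(a, b) for a, b in group], index=donors, name="diplotype"
    )

    geno = {}
    for j, locus in enumerate(TAG_LOCI):
        a1 = np.array([HAPLOTYPE_TAGS[h][j] for h in haps[:, 0]])
        a2_ = np.array([HAPLOTYPE_TAGS[h][j] for h in haps[:, 1]])
        geno[locus] = ["/".join(sorted((x, y))) for x, y in zip(a1, a2_)]
    sec = r_fut2.choice(
        ["G", "A"],
        size=(n, 2),
        p=[config.secretor_allele_freq, 1 - config.secretor_allele_freq],
    )
    geno["rs601338"] = ["/".join(sorted(p)) for p in sec]
    genotypes = pd.DataFrame(geno, index=donors)

    # --- covariates: balanced sex, decade-stratified ages, CMV, cells ---
    sex = np.array(["M"] * (n // 2) + ["F"] * (n - n // 2))
    r_cov.shuffle(sex)
    decades = list(config.age_decades)
    decade_idx = np.arange(n) % len(decades)
    r_cov.shuffle(decade_idx)
    lows = np.array([decades[i][0] for i in decade_idx])
    highs = np.array([decades[i][1] for i in decade_idx])
    age = r_cov.integers(lows, highs + 1)
    cmv = (r_cov.random(n) < config.cmv_prevalence).astype(int)
    # Proportions sum to slightly less than 1 (unassigned minor populations
    # vary by donor), which keeps the 16-column EWAS design full rank.
    cells = r_cov.dirichlet(np.full(N_CELL_SUBSETS, CELL_DIRICHLET_ALPHA), size=n)
    cells *= r_cov.uniform(0.85, 0.95, size=n)[:, None]
    covariates = pd.DataFrame(
        {"sex": sex, "age": age, "cmv": cmv,
         "secretor": [0 if g == "A/A" else 1 for g in geno["rs601338"]]},
        index=donors,
    )
    for k in range(N_CELL_SUBSETS):
        covariates[f"cell_{k + 1:02d}"] = cells[:, k]

    # --- methylation (effects injected on the M scale, emitted as β) ---
    x = (diplo != "OO").to_numpy(dtype=float)
    n_cpg, n_prom = config.n_cpgs, config.n_promoter_cpgs
    bimodal = np.where(
        r_meth.random(n_cpg) < 0.5,
        r_meth.normal(-3.0, 1.0, n_cpg),
        r_meth.normal(3.0, 1.0, n_cpg),
    )
    base_m = bimodal
    base_m[:n_prom] = r_meth.normal(0.0, 0.5, n_prom)  # mid-range promoter CpGs
    M = base_m[None, :] + r_meth.normal(0.0, config.noise_sd_M, (n, n_cpg))
    M[:, :n_prom] += config.effect_XM * x[:, None]
    cpg_ids = [f"cg{i + 1:06d}" for i in range(n_cpg)]
    methylation = pd.DataFrame(m_to_beta(M), index=donors, columns=cpg_ids)

    chrom_bg = r_meth.integers(1, 23, size=n_cpg)
    pos_bg = r_meth.integers(1_000_000, 200_000_000, size=n_cpg)
    _, lo, hi = ABO_PROMOTER_REGION
    clash = (chrom_bg == 9) & (pos_bg >= lo - 1000) & (pos_bg <= hi + 1000)
    pos_bg[clash] += 5_000_000
    prom_pos = np.linspace(lo, hi, n_prom).astype(int)
    chrom = np.array([f"chr{c}" for c in chrom_bg], dtype=object)
    pos = pos_bg.copy()
    chrom[:n_prom] = ABO_PROMOTER_REGION[0]
    pos[:n_prom] = prom_pos
    cpg_annotation = pd.DataFrame(
        {"cpg_id": cpg_ids, "chrom": chrom, "pos": pos}
    ).set_index("cpg_id")

    # --- proteins: two focal ones carry direct + mediated non-O effects ---
    n_prot = config.n_proteins
    n_focal = min(len(FOCAL_PROTEIN_NAMES), n_prot, n_prom)
    prot_ids = list(FOCAL_PROTEIN_NAMES[:n_focal]) + [
        f"protein_{i + 1:03d}" for i in range(n_prot - n_focal)
    ]
    base_p = r_prot.normal(10.0, 2.0, n_prot)
    Y = base_p[None, :] + r_prot.normal(0.0, config.noise_sd_Y, (n, n_prot))
    truth_rows = []
    for j in range(n_focal):
        Y[:, j] += config.effect_MY * M[:, j] + config.effect_XY_direct * x
        truth_rows.append(
            {
                "protein": prot_ids[j],
                "cpg": cpg_ids[j],
                "a": config.effect_XM,
                "b": config.effect_MY,
                "c_prime": config.effect_XY_direct,
                "acme": config.effect_XM * config.effect_MY,
                "total": config.effect_XM * config.effect_MY
                + config.effect_XY_direct,
            }
        )
    proteins = pd.DataFrame(Y, index=donors, columns=prot_ids)
    truth = pd.DataFrame(
        truth_rows, columns=["protein", "cpg", "a", "b", "c_prime", "acme", "total"]
    )

    return SyntheticCohort(
        config=config,
        genotypes=genotypes,
        covariates=covariates,
        methylation=methylation,
        cpg_annotation=cpg_annotation,
        proteins=proteins,
        truth=truth,
        diplotypes=diplo,
    )


def null_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Cohort with all blood-group effects forced to zero (a = b = c' = 0)."""
    return generate_cohort(
        replace(config, effect_XM=0.0, effect_MY=0.0, effect_XY_direct=0.0)
    )
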