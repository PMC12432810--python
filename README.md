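# abomics

ABO blood group is one of the strongest *trans*-pQTLs in the human genome:
type O donors carry higher plasma levels of soluble E-selectin and lower
levels of von Willebrand Factor (vWF) than non-O donors, differences that are
thought to contribute to the lower thrombotic risk of type O individuals.
`abomics` is a toolkit for asking *how much of that blood-group effect runs
through DNA methylation at the ABO locus*. It is aimed at analysts working
with cohort-style multi-omics tables: tag-SNP genotypes, an EPIC-style
donors × CpG methylation matrix, a donors × protein log2 concentration
matrix, and a covariate table (sex, age, CMV serostatus, immune-cell
proportions).

The package provides:

- **Genotype-based typing** — O/non-O status from the rs8176719 c.261delG
  indel; the six-class ABO diplotype (OO, AO, AA, BO, BB, AB) from
  rs8176719 + rs8176746 + rs8176747; A1/A2 subtyping from rs1053878; FUT2
  secretor status from rs601338; and two-locus LD statistics (D, D′, r²) via
  an EM haplotype-frequency estimator for unphased genotypes.
- **EWAS** — per-CpG OLS of methylation (β values, with `β = 2^M/(2^M+1)`)
  on the non-O indicator adjusted for sex, age, CMV and 16 immune-cell
  proportions, Benjamini–Hochberg q values, a genome-wide `p < 5×10⁻⁸` flag,
  SNP-conditioned sensitivity refits, and a pre-check that cell proportions
  do not differ by blood group.
- **Protein association** — per-protein models
  `log2(level) ~ nonO + sex + age + CMV + secretor`, sex-stratified refits,
  and recessive/dosage analyses (one-way ANOVA + Tukey HSD across genotype
  classes, A1/A2/O gradient summaries).
- **Attenuation screen** — the blood-group protein effect re-estimated with
  each candidate CpG as a covariate, as an effect-size matrix with post-FDR
  significance flags.
- **Causal mediation** — the linear three-model decomposition
  (X → M, X + M → Y, X → Y) with ACME = c − c′ (a·b reported alongside),
  ADE = c′, proportion mediated = ACME/(ACME + ADE), and percentile
  confidence intervals and p values from a nonparametric bootstrap that
  resamples donors and refits all three models per resample.
- **A synthetic cohort generator** that draws ABO haplotypes in
  Hardy–Weinberg equilibrium at European allele frequencies, derives the tag
  SNPs from them, and injects configurable blood-group effects on promoter
  CpGs and partially mediated effects on two focal proteins — so the entire
  pipeline is testable without access to individual-level cohort data.

## Worked example

```python
import pandas as pd
from abomics import (SimulationConfig, generate_cohort, type_cohort,
                     run_ewas, fit_protein_models, fit_mediation)
from abomics.methylation import beta_to_m

cfg = SimulationConfig(n_donors=400, n_cpgs=1000, n_promoter_cpgs=6,
                       n_proteins=50, seed=42)
cohort = generate_cohort(cfg)
calls = type_cohort(cohort.genotypes)

ewas = run_ewas(cohort.methylation, cohort.covariates, calls["o_status"])
prot = fit_protein_models(cohort.proteins, cohort.covariates, calls)

mvals = pd.DataFrame(beta_to_m(cohort.methylation.to_numpy()),
                     index=cohort.methylation.index,
                     columns=cohort.methylation.columns)
x = (calls["o_status"] == "nonO").astype(float)
cells = [c for c in cohort.covariates.columns if c.startswith("cell_")]
cov_xm = pd.get_dummies(cohort.covariates[["sex", "age"] + cells],
                        columns=["sex"], drop_first=True, dtype=float)
cov_xmy = pd.get_dummies(cohort.covariates[["sex", "age"]],
                         columns=["sex"], drop_first=True, dtype=float)
res = fit_mediation(x, mvals["cg000001"], cohort.proteins["sEselectin_like"],
                    cov_xm, cov_xmy, n_boot=500, seed=42, scale="M")
```

This run prints (exact numbers for seed 42):

```
EWAS: 6 of 1000 CpGs at q<0.05; 6 pass p<5e-8

Mediation cg000001 -> sEselectin_like (n=400, 500 bootstraps):
  ACME = 1.086 (95% CI 0.907 to 1.304, p = 0.004)
  ADE  = 1.040 (95% CI 0.822 to 1.266, p = 0.004)
  proportion mediated = 0.511
```

The six CpGs recovered at q < 0.05 are exactly the six promoter CpGs that
received the generating effect; the mediation decomposition recovers the
generating indirect effect a·b = 0.5 × 2.0 = 1.0 (ACME), the direct effect
c′ = 1.0 (ADE), and a mediated proportion of ~0.5, each inside its 95%
bootstrap interval.

## Command line

```bash
abomics simulate --out cohort/ --n-donors 400 --seed 1
abomics type-abo --vcf cohort/genotypes.vcf --out calls.tsv
abomics ewas --meth cohort/methylation.tsv --pheno cohort/covariates.tsv \
             --calls calls.tsv --out ewas.tsv
abomics run-all --config config.yaml     # the full sequence, seeded
```

All result tables are TSV with a `#`-comment provenance header (tool
version, seed, config hash); reruns with the same config are byte-identical.

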