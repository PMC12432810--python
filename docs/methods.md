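# Methods

## Blood-group imputation

O/non-O status is read off rs8176719 (c.261delG): `-/-` → O, `G/-` and
`G/G` → non-O. The six-class diplotype uses an exact rule-table lookup over
rs8176719, rs8176746 (Leu266Met) and rs8176747 (Gly268Ala):

| rs8176719 | rs8176746 | rs8176747 | diplotype |
|-----------|-----------|-----------|-----------|
| -/-       | any       | any       | OO        |
| -/G       | G/G       | C/C       | AO        |
| G/G       | G/G       | C/C       | AA        |
| -/G       | G/T       | (C/G)     | BO        |
| G/G       | T/T       | (G/G)     | BB        |
| G/G       | G/T       | C/G       | AB        |

For the two B rows, rs8176747 is optional (the two-locus rule suffices) but
is checked when present; a present-but-contradictory call, or any
combination absent from the table, is `unclassified`. The A and AB rows
require rs8176747. Rare non-deletion O alleles (c.802G>A, ~2% of O alleles)
are invisible to a tag-SNP panel and are deliberately not modelled, so a
small fraction of true O donors will be typed non-O on real data.

A1/A2 subtyping uses rs1053878. Which allele tags A2 is not fixed by the
rule table; the package defaults to the alternate allele (A) and exposes the
direction as a switch (`--a2-allele`). FUT2 secretor status: rs601338 A/A →
non-secretor, G carriers → secretor.

LD between two biallelic loci is estimated from unphased genotypes by
two-locus EM (only double heterozygotes are phase-ambiguous), initialised at
linkage equilibrium and iterated to a 1e-10 change tolerance or 1,000
iterations. D′ = |D|/D_max and r² = D²/(p_A p_a p_B p_b). Monomorphic or
multi-allelic input is an error rather than a silent NaN.

## β/M conversion

β = 2^M/(2^M+1) (computed as a logistic for stability) and
M = log2(β/(1−β)), with β ∈ {0, 1} rejected. The pair is strictly inverse
up to float64 resolution: because β(1−β) ≈ 2^−|M| at large |M|, a half-ulp
rounding of the stored β maps back to an M error of order
2^|M|·2^−54/ln 2. The round trip is therefore exact to 1e-12 only for
|M| ≲ 13, and the error grows geometrically to ~1e-7 near |M| = 30. This is
a representation limit of double precision (there are only ~2^23 distinct
doubles in the β range corresponding to one unit of M at M ≈ 30), not an
implementation choice; no downstream analysis operates at M values beyond
~±10, where the conversion is exact to 1e-12.

## Association models

All mass-univariate fits are ordinary least squares sharing one design
matrix per run (one QR factorisation serves every response column), with
two-sided t tests for the non-O coefficient and Benjamini–Hochberg step-up
q values across the features tested in that run:

- EWAS: `CpG ~ nonO + sex + age + CMV + 16 cell proportions`, on β values
  by default (an M-scale option exists). CpGs with p < 5×10⁻⁸ are flagged
  as genome-wide significant.
- Cell-proportion pre-check: each of the 16 subsets regressed on the same
  covariates minus the cells themselves, BH over 16 tests.
- Proteins: `log2(level) ~ nonO + sex + age + CMV + secretor`. Non-O is
  coded 1 and O 0, so a protein higher in O donors gets a negative log2
  fold change. Sex-stratified refits drop the sex term and apply BH within
  each stratum.
- SNP-conditioned refits add one SNP dosage at a time. A SNP whose dosage
  is numerically in the span of the other regressors including the non-O
  indicator (e.g. a perfect tag of blood group) makes the coefficient
  inestimable; those runs are reported with status `absorbed` rather than
  failing, mirroring what happens when conditioning on the causal variant
  itself.

Missingness is handled complete-case per model, with `n_complete` reported.
Zero-variance features are skipped with NA and a warning; a rank-deficient
design raises an error naming the collinear columns (found by column-pivoted
QR). BH is computed by the standard step-up; NaN p values propagate with the
hypothesis count reduced.

The dosage analysis runs one-way ANOVA across the six diplotype classes (or
the three-level dosage grouping OO vs {AO, BO} vs {AA, AB, BB}) followed by
Tukey HSD on all surviving pairs (classes with n < 2 are dropped with a
warning). The screen-level FDR correction is applied across proteins to the
ANOVA p values — Tukey already adjusts within-protein pairs.

## Attenuation screen

For each (protein, CpG) pair the protein model is refit with the CpG added
as a covariate. The first matrix row is the unadjusted baseline, computed on
the same donor intersection (genotyped ∩ methylation ∩ proteins) and by the
same code path, so it matches the plain protein models bit-for-bit. FDR is
applied per covariate row across proteins by default — each row is one model
family — with a global option. With matched covariate sets the adjusted
non-O coefficient equals the mediation model's direct effect c′ exactly
(verified to 1e-10 in the tests).

## Mediation

Linear three-model decomposition for binary X, continuous M and Y:

- model XM: `M ~ X + covariates_XM` → a
- model XMY: `Y ~ X + M + covariates_XMY` → b, c′ (ADE)
- model XY: `Y ~ X + covariates_XMY` → c (total effect)

The headline ACME is the difference c − c′; the product a·b is reported
alongside. The two coincide exactly for nested OLS with identical covariate
sets and differ when the sets differ — the default model adjusts for cell
proportions only in model XM, so both are emitted. The proportion mediated
is computed from the point estimates, ACME/(ACME + c′).

Inference is a nonparametric bootstrap (default 500 resamples): donors are
resampled with replacement, all three models are refit per resample (batched
normal-equation solves), and percentile intervals at the requested level are
taken per quantity. Bootstrap p values are two-sided,
`2·min(#{≤0}+1, #{≥0}+1)/(B+1)` capped at 1. Resamples that lose one
treatment level are redrawn (counted, capped at 10·B attempts). A known
property worth stating: under a *complete* null (both a = 0 and b = 0) the
ACME draws behave like a product of two mean-zero estimates, so percentile
CIs exclude zero far less often than 5% — the test is valid but
conservative at that corner of the parameter space; CI coverage of a true
non-zero ACME is nominal (verified at 95%±4% over 200 simulated datasets).
The quasi-Bayesian approximation offered by some mediation software is not
implemented; only the bootstrap is.

## Synthetic cohort generator

The generator is first-class, tested code; its defaults encode the emulated
study conditions. Per cohort it draws:

- ABO haplotypes {O, A1, A2, B} i.i.d. at frequencies derived from
  European reference genotype counts (O 1255/1996 ≈ 0.6288, A 590/1996 ≈
  0.2956, B 151/1996 ≈ 0.0757; A2 fraction of A from allele frequencies
  22.3% A1 / 7.2% A2), paired at random — Hardy–Weinberg by construction.
  Tag-SNP genotypes are derived deterministically from the haplotypes, so
  tag SNPs are in perfect LD with blood group and the SNP-conditioned EWAS
  "absorbed" behaviour is reproducible.
- Covariates: sex balanced, ages integer-uniform within five decades
  (20–69) assigned evenly; CMV seropositivity at 35%; FUT2 genotypes at a
  secretor (G) allele frequency of 0.52 (~23% non-secretors, typical of
  European cohorts). The 16 cell proportions come from a symmetric
  Dirichlet(5) scaled by a per-donor Uniform(0.85, 0.95) factor: real
  panels never sum exactly to 1 (unassigned minor populations vary by
  donor), and a constant sum would be exactly collinear with the intercept
  in the 16-covariate EWAS design.
- Methylation: per-CpG baselines from a bimodal M-value mixture (±3 ± 1),
  promoter CpGs mid-range (N(0, 0.5)); the non-O effect (default 0.5 M
  units) is injected at promoter CpGs on the M scale and the matrix is
  emitted as β, keeping values strictly in (0, 1). Promoter CpGs are
  annotated inside the ABO promoter/enhancer region
  chr9:133,272,926–133,276,404 (GRCh38, 1-based inclusive; BED export
  converts to 0-based half-open).
- Proteins: two focal proteins (E-selectin-like, vWF-like) receive
  `b·M + c′·X` plus noise, with M the mediator CpG's M value — the
  generative model is linear on the M scale, so the true ACME is a·b
  exactly and parameter-recovery tests have a closed-form target. The
  truth table records a, b, c′, a·b and the total per focal pair.

One seed sequence is split into per-component streams (haplotypes,
covariates, methylation, proteins, FUT2), so identical seeds give
bit-identical cohorts and growing one component does not perturb the others.

What the generator does **not** emulate: genome-wide LD structure, array
noise (detection p values, probe cross-reactivity, batch effects), skewed
real cell-type compositions, or non-linear mediator–outcome relationships.
Passing tests demonstrate correctness of the statistical machinery under
the assumed linear model, not robustness to those real-data features.

## Problem sizes and numerical choices

The test suite runs cohorts of 100–10,000 donors: HWE checks at n=100,000
(haplotypes only), type-I error at n=500 donors × 2,000 CpGs, bootstrap
coverage over 200 replicates of n=400 with 500 resamples each — sizes at
which every check completes in seconds to a couple of minutes on one core.
EM convergence tolerance is 1e-10; OLS uses QR with a rank tolerance of
eps·max(n,p)·max|R_ii|; bootstrap Gram solves are adequate because designs
are small (≤ ~25 columns) and standardisation is unnecessary at these
condition numbers. Ties in the A1/A2/O gradient means are reported as
`ties` rather than folded into the monotonicity flag.
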