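"""End-to-end orchestration: typing → EWAS → protein models → attenuation →
mediation, with provenance-tagged TSV outputs.

Every output table carries a comment header recording the package version,
the run seed and a hash of the configuration, so a rerun with the same
config and inputs is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .attenuation import adjusted_effect_matrix
from .blood_groups import cohort_frequencies, type_cohort
from .io import export_bed, read_genotypes, read_table, read_yaml_config, write_table
from .mediation import mediation_screen
from .methylation import compare_cell_proportions, run_ewas
from .proteins import dosage_anova_screen, fit_protein_models, sex_stratified_models

__all__ = ["PipelineConfig", "PipelineError", "run_all"]

log = logging.getLogger("abomics")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        self.stage = stage
        self.code = code
        super().__init__(f"[{stage}/{code}] {message}")


@dataclass
class PipelineConfig:
    genotypes: str
    methylation: str
    cpg_annotation: str
    proteins: str
    covariates: str
    out_dir: str
    genotype_format: str | None = None  # "vcf" / "tsv" / infer
    q_threshold: float = 0.05
    gw_threshold: float = 5e-8
    fdr_scope: str = "row"
    ewas_scale: str = "beta"
    a2_allele: str = "A"
    dosage_model: str = "genotype"
    n_boot: int = 500
    ci_level: float = 0.95
    max_mediation_pairs: int | None = None
    seed: int = 0

    def validate(self) -> None:
        for thr in (self.q_threshold,):
            if not 0.0 < thr < 1.0:
                raise PipelineError("config", "bad-threshold",
                                    f"q threshold {thr} outside (0, 1)")
        if not 0.0 < self.gw_threshold < 1.0:
            raise PipelineError("config", "bad-threshold",
                                f"genome-wide threshold outside (0, 1)")
        for name in ("genotypes", "methylation", "cpg_annotation",
                     "proteins", "covariates"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise PipelineError("config", "missing-input",
                                    f"{name} file not found: {p}")

    def sha256(self) -> str:
        # out_dir does not affect the analysis, so it is not fingerprinted
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        return hashlib.sha256(
            yaml.safe_dump(payload, sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**read_yaml_config(path))


def _stage(name):
    log.info("stage=%s start", name)


def run_all(config: PipelineConfig) -> dict:
    """Execute the full analysis sequence and write all result tables.

    Returns a dict of the in-memory result frames keyed by stage.  Stage
    failures raise :class:`PipelineError` naming the stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "tool": f"abomics {__version__}",
        "seed": config.seed,
        "config_sha256": config.sha256(),
    }
    results: dict = {}

    _stage("read")
    try:
        genotypes = read_genotypes(config.genotypes, config.genotype_format)
        pheno = read_table(config.covariates)
        meth = read_table(config.methylation)
        annotation = read_table(config.cpg_annotation)
        proteins = read_table(config.proteins)
    except Exception as e:  # noqa: BLE001 - map to stage error
        raise PipelineError("read", "parse", str(e)) from e

    _stage("type-abo")
    try:
        calls = type_cohort(genotypes, a2_allele=config.a2_allele)
        freqs = cohort_frequencies(calls)
    except Exception as e:
        raise PipelineError("type-abo", "typing", str(e)) from e
    write_table(calls, out / "calls.tsv", meta=meta)
    write_table(freqs, out / "frequencies.tsv", meta=meta, index=False)
    results["calls"], results["frequencies"] = calls, freqs
    o_status = calls["o_status"]

    _stage("cell-proportions")
    try:
        cells = compare_cell_proportions(pheno, o_status)
    except Exception as e:
        raise PipelineError("cell-proportions", "model", str(e)) from e
    write_table(cells, out / "cell_proportions.tsv", meta=meta)
    results["cell_proportions"] = cells

    _stage("ewas")
    try:
        ewas = run_ewas(meth, pheno, o_status, scale=config.ewas_scale,
                        gw_threshold=config.gw_threshold)
        export_bed(ewas, annotation, out / "ewas_significant.bed",
                   threshold=config.q_threshold)
    except Exception as e:
        raise PipelineError("ewas", "model", str(e)) from e
    write_table(ewas, out / "ewas.tsv", meta=meta)
    results["ewas"] = ewas

    _stage("protein-de")
    try:
        prot = fit_protein_models(proteins, pheno, calls)
        prot_sex = sex_stratified_models(proteins, pheno, calls)
        dosage = dosage_anova_screen(proteins, calls, model=config.dosage_model)
    except Exception as e:
        raise PipelineError("protein-de", "model", str(e)) from e
    write_table(prot, out / "proteins.tsv", meta=meta)
    write_table(prot_sex, out / "proteins_by_sex.tsv", meta=meta, index=False)
    write_table(dosage, out / "dosage_anova.tsv", meta=meta)
    results["proteins"], results["proteins_by_sex"] = prot, prot_sex
    results["dosage_anova"] = dosage

    sig_cpgs = list(ewas.index[ewas["q"] < config.q_threshold])
    sig_prots = list(prot.index[prot["q"] < config.q_threshold])
    log.info("significant CpGs=%d proteins=%d", len(sig_cpgs), len(sig_prots))

    _stage("adjust")
    try:
        att = adjusted_effect_matrix(
            proteins, meth, pheno, calls, sig_cpgs,
            protein_set=sig_prots or None,
            q_threshold=config.q_threshold, fdr_scope=config.fdr_scope,
        )
    except Exception as e:
        raise PipelineError("adjust", "model", str(e)) from e
    write_table(att.long, out / "attenuation.tsv", meta=meta, index=False)
    results["attenuation"] = att

    _stage("mediate")
    try:
        cell_cols = [c for c in pheno.columns if c.startswith("cell_")]
        keep = o_status.isin(["O", "nonO"])
        x = (o_status[keep] == "nonO").astype(float)
        pairs = [(c, p) for c in sig_cpgs for p in sig_prots]
        if config.max_mediation_pairs is not None:
            pairs = pairs[: config.max_mediation_pairs]
        med = mediation_screen(
            meth, proteins, x,
            covariates_xm=pd.get_dummies(
                pheno[["sex", "age"] + cell_cols], columns=["sex"],
                drop_first=True, dtype=float),
            covariates_xmy=pd.get_dummies(
                pheno[["sex", "age"]], columns=["sex"], drop_first=True,
                dtype=float),
            pairs=pairs, n_boot=config.n_boot, seed=config.seed,
            ci_level=config.ci_level, scale="beta",
        )
    except Exception as e:
        raise PipelineError("mediate", "model", str(e)) from e
    write_table(med, out / "mediation.tsv", meta=meta, index=False)
    results["mediation"] = med

    log.info("pipeline complete: %s", out)
    return results
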