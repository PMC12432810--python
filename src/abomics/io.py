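"""Readers and writers for the interchange formats.

Canonical interchange is UTF-8 TSV with a header row and ``donor_id`` as the
first column; result tables carry provenance as leading ``#`` comment lines
(key: value).  Genotypes travel either as a minimal VCF 4.2 restricted to the
five tag loci or as a long TSV dialect (donor_id, locus, call), with the
rs8176719 single-base deletion written "-" in TSV and as an anchor-base indel
in VCF — the two encodings normalise to the same genotype table.
"""

from __future__ import annotations

import io as _io
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .blood_groups import ALL_LOCI

__all__ = [
    "ParseError",
    "read_table",
    "write_table",
    "read_genotypes",
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "read_genotypes_vcf",
    "write_genotypes_vcf",
    "export_bed",
    "read_yaml_config",
    "write_cohort",
]

MISSING_TOKENS = {"", ".", "./.", "NA", "nan"}

#: Nominal GRCh38 coordinates and REF/ALT used when writing the minimal VCF.
#: rs8176719 is the c.261delG indel in anchor-base notation: the longer
#: allele carries the G insertion (non-O), the shorter one the deletion.
VCF_SITES = {
    "rs8176747": ("chr9", 133_255_928, "C", "G"),
    "rs8176746": ("chr9", 133_255_935, "G", "T"),
    "rs1053878": ("chr9", 133_257_486, "G", "A"),
    "rs8176719": ("chr9", 133_257_521, "TC", "T"),
    "rs601338": ("chr19", 48_703_417, "G", "A"),
}


class ParseError(ValueError):
    """Malformed input line; carries the 1-based line number."""

    def __init__(self, path, line_no, message):
        self.line_no = line_no
        super().__init__(f"{path}:{line_no}: {message}")


# ---------------------------------------------------------------------------
# Generic provenance-tagged TSV tables


def write_table(df: pd.DataFrame, path, meta: Mapping | None = None,
                index: bool = True) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    for k, v in (meta or {}).items():
        buf.write(f"# {k}: {v}\n")
    df.to_csv(buf, sep="\t", index=index)
    path.write_text(buf.getvalue())


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


# ---------------------------------------------------------------------------
# Genotypes — long TSV dialect


def write_genotypes_tsv(genotypes: pd.DataFrame, path,
                        meta: Mapping | None = None) -> None:
    """Write a wide genotype table as the long (donor_id, locus, call) dialect."""
    long = genotypes.stack(future_stack=True).reset_index()
    long.columns = ["donor_id", "locus", "call"]
    long["call"] = long["call"].fillna(".")
    write_table(long, path, meta=meta, index=False)


def read_genotypes_tsv(path) -> pd.DataFrame:
    """Parse the long TSV genotype dialect into a wide donors × loci table.

    Unknown loci are ignored with a warning; a line with the wrong number of
    fields raises :class:`ParseError` with its line number.  An empty file
    yields an empty table.
    """
    rows = []
    donors: list = []
    seen = set()
    with open(path) as fh:
        header_seen = False
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(path, line_no, f"expected 3 fields, got {len(fields)}")
            if not header_seen:
                header_seen = True
                if fields == ["donor_id", "locus", "call"]:
                    continue
                raise ParseError(path, line_no, "missing header donor_id/locus/call")
            donor, locus, call = fields
            if locus not in ALL_LOCI:
                warnings.warn(f"ignoring unknown locus {locus!r}")
                continue
            if donor not in seen:
                seen.add(donor)
                donors.append(donor)
            rows.append((donor, locus, None if call in MISSING_TOKENS else call))
    wide = pd.DataFrame(index=pd.Index(donors, name="donor_id"),
                        columns=list(ALL_LOCI), dtype=object)
    for donor, locus, call in rows:
        wide.loc[donor, locus] = call
    return wide


# ---------------------------------------------------------------------------
# Genotypes — minimal VCF 4.2


def write_genotypes_vcf(genotypes: pd.DataFrame, path,
                        source: str = "abomics") -> None:
    genotypes = genotypes.copy()
    donors = list(genotypes.index)
    lines = [
        "##fileformat=VCFv4.2",
        f"##source={source}",
        "##contig=<ID=chr9>",
        "##contig=<ID=chr19>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(donors),
    ]
    order = sorted(VCF_SITES, key=lambda k: (VCF_SITES[k][0], VCF_SITES[k][1]))
    for rsid in order:
        chrom, pos, ref, alt = VCF_SITES[rsid]
        if rsid == "rs8176719":
            # anchor-base indel: allele 0 (longer) = G present, allele 1 = "-"
            allele_of = {"G": "0", "-": "1"}
        else:
            allele_of = {ref: "0", alt: "1"}
        gts = []
        col = genotypes[rsid] if rsid in genotypes.columns else None
        for donor in donors:
            call = None if col is None else col.loc[donor]
            if call is None or (isinstance(call, float) and np.isnan(call)) \
                    or call in MISSING_TOKENS:
                gts.append("./.")
            else:
                a, b = str(call).split("/")
                gts.append(f"{allele_of[a]}/{allele_of[b]}")
        lines.append(
            f"{chrom}\t{pos}\t{rsid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
            + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_genotypes_vcf(path) -> pd.DataFrame:
    """Read the five tag loci from a VCF 4.2 file (cyvcf2 backend).

    Records whose ID is not one of the known rsIDs are ignored with a
    warning.  For rs8176719, either indel orientation is accepted: the longer
    of REF/ALT normalises to the G-insertion allele, the shorter to "-".
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    donors = list(vcf.samples)
    wide = pd.DataFrame(index=pd.Index(donors, name="donor_id"),
                        columns=list(ALL_LOCI), dtype=object)
    for variant in vcf:
        rsid = variant.ID
        if rsid not in ALL_LOCI:
            warnings.warn(f"ignoring unknown VCF record {rsid!r}")
            continue
        alleles = [variant.REF] + list(variant.ALT)
        if rsid == "rs8176719":
            lengths = [len(a) for a in alleles]
            longer = int(np.argmax(lengths))
            norm = ["G" if i == longer else "-" for i in range(len(alleles))]
        else:
            norm = alleles
        for donor, gt in zip(donors, variant.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                continue
            wide.loc[donor, rsid] = "/".join(sorted((norm[a], norm[b])))
    return wide


def read_genotypes(path, fmt: str | None = None) -> pd.DataFrame:
    """Dispatch on format ("vcf" or "tsv"; inferred from the extension)."""
    if fmt is None:
        fmt = "vcf" if str(path).endswith((".vcf", ".vcf.gz")) else "tsv"
    if fmt == "vcf":
        return read_genotypes_vcf(path)
    if fmt == "tsv":
        return read_genotypes_tsv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


# ---------------------------------------------------------------------------
# BED export (1-based inclusive annotation -> 0-based half-open records)


def export_bed(results: pd.DataFrame, annotation: pd.DataFrame, path,
               threshold: float = 0.05, by: str = "q") -> pd.DataFrame:
    """Write CpGs passing ``results[by] < threshold`` as a sorted BED file."""
    hits = results.index[results[by] < threshold]
    ann = annotation.loc[annotation.index.intersection(hits)]
    bed = pd.DataFrame(
        {
            "chrom": ann["chrom"].astype(str),
            "start": ann["pos"].astype(int) - 1,
            "end": ann["pos"].astype(int),
            "name": ann.index,
        }
    ).sort_values(["chrom", "start"], kind="stable")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    bed.to_csv(path, sep="\t", header=False, index=False)
    return bed


def read_yaml_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    return data


# ---------------------------------------------------------------------------
# Cohort serialisation


def write_cohort(cohort, outdir, meta: Mapping | None = None) -> dict:
    """Write all components of a synthetic cohort under ``outdir``.

    Emits genotypes in both interchange encodings (VCF and long TSV), the
    covariate/methylation/protein matrices, the CpG annotation sidecar and
    the generating-truth ledger.  Returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes_vcf": outdir / "genotypes.vcf",
        "genotypes_tsv": outdir / "genotypes.tsv",
        "covariates": outdir / "covariates.tsv",
        "methylation": outdir / "methylation.tsv",
        "cpg_annotation": outdir / "cpg_annotation.tsv",
        "proteins": outdir / "proteins.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_genotypes_vcf(cohort.genotypes, paths["genotypes_vcf"])
    write_genotypes_tsv(cohort.genotypes, paths["genotypes_tsv"], meta=meta)
    write_table(cohort.covariates, paths["covariates"], meta=meta)
    write_table(cohort.methylation, paths["methylation"], meta=meta)
    write_table(cohort.cpg_annotation, paths["cpg_annotation"], meta=meta)
    write_table(cohort.proteins, paths["proteins"], meta=meta)
    write_table(cohort.truth, paths["truth"], meta=meta, index=False)
    return paths
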