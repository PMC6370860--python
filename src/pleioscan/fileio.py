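"""Readers and writers for the pipeline's file formats.

Genotypes travel as VCF v4.2 with a per-genotype ``DS`` (dosage) FORMAT
field and per-variant ``R2`` (imputation quality), ``ANN`` (functional
annotation) and ``GENE`` INFO fields, or as a plain dosage TSV.  Events,
measurements, demographics, relatedness and scan results are headered
TSV; the phecode map is CSV.  All coordinates are 1-based inclusive.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=pleioscan
##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation quality r-squared">
##INFO=<ID=ANN,Number=1,Type=String,Description="Functional annotation">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt allele dosage">
"""


def write_vcf(path, dosages: pd.DataFrame, variants: pd.DataFrame) -> None:
    """Write dosages + variant metadata as a plain-text VCF v4.2.

    One sample column per person (named ``P<person>``); GT is the rounded
    hard call, DS the dosage.  Variants are sorted by (chrom, pos).
    """
    path = Path(path)
    samples = [f"P{p}" for p in dosages.index]
    var = variants.copy()
    var["_order"] = np.arange(len(var))
    var = var.sort_values(["chrom", "pos"], kind="stable")
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in var["chrom"].astype(str).unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for rsid, row in var.iterrows():
            ds = dosages[rsid].to_numpy(dtype=float)
            info = f"R2={row['imputation_r2']:.4f};ANN={row['annotation']};GENE={row['gene']}"
            cells = [
                f"{gt_map[int(round(min(max(d, 0), 2)))]}:{d:.3f}" for d in ds
            ]
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{rsid}\t{row['ref']}\t{row['alt']}\t.\tPASS\t"
                f"{info}\tGT:DS\t" + "\t".join(cells) + "\n"
            )


def read_genotypes(path) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Read genotypes from VCF (``.vcf``/``.vcf.gz``) or a dosage TSV.

    For VCF, the DS FORMAT field is used when present, otherwise the
    additive alt-allele count from GT; a missing INFO R2 defaults to 1.0
    with a logged warning.  Multiallelic records are rejected.  Returns
    ``(dosages, variants)`` with persons as the dosage index.
    """
    path = Path(path)
    if path.suffix == ".tsv":
        return read_dosage_tsv(path)
    vcf = VCF(str(path))
    samples = vcf.samples
    persons = [int(s[1:]) if s.startswith("P") and s[1:].isdigit() else s for s in samples]
    if len(set(persons)) != len(persons):
        raise ValueError("conflicting sample ids in VCF")
    rows = []
    dosage_cols = {}
    for v in vcf:
        if v.ALT and len(v.ALT) > 1:
            raise ValueError(f"multiallelic record at {v.CHROM}:{v.POS}; split it first")
        rsid = v.ID or f"{v.CHROM}:{v.POS}"
        try:
            ds = v.format("DS")
        except KeyError:  # DS absent from the header entirely
            ds = None
        if ds is not None:
            dose = np.asarray(ds, dtype=float).reshape(-1)
        else:
            # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
            gt = np.asarray(v.gt_types)
            dose = np.where(gt == 3, 2.0, np.where(gt == 2, np.nan, gt.astype(float)))
        r2 = v.INFO.get("R2")
        if r2 is None:
            logger.warning("variant %s lacks INFO R2; assuming imputation r2 = 1.0", rsid)
            r2 = 1.0
        rows.append(
            dict(
                rsid=rsid,
                gene=v.INFO.get("GENE", ""),
                chrom=str(v.CHROM),
                pos=int(v.POS),
                ref=v.REF,
                alt=v.ALT[0] if v.ALT else ".",
                annotation=v.INFO.get("ANN", ""),
                imputation_r2=float(r2),
            )
        )
        dosage_cols[rsid] = dose
    variants = pd.DataFrame(rows).set_index("rsid")
    dosages = pd.DataFrame(dosage_cols, index=pd.Index(persons, name="person"))
    p = dosages.mean(axis=0) / 2.0
    variants["maf"] = np.minimum(p, 1.0 - p)
    return dosages, variants


def write_dosage_tsv(path, dosages: pd.DataFrame) -> None:
    dosages.to_csv(path, sep="\t", index_label="person")


def read_dosage_tsv(path) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Dosage matrix TSV (person column + one column per rsid); variant
    metadata is minimal, with imputation r2 defaulting to 1.0."""
    dosages = pd.read_csv(path, sep="\t").set_index("person")
    logger.warning("dosage TSV carries no imputation quality; assuming r2 = 1.0")
    p = dosages.mean(axis=0) / 2.0
    variants = pd.DataFrame(
        {
            "gene": "",
            "chrom": "",
            "pos": 0,
            "ref": "",
            "alt": "",
            "annotation": "",
            "imputation_r2": 1.0,
            "maf": np.minimum(p, 1.0 - p),
        },
        index=dosages.columns.rename("rsid"),
    )
    return dosages, variants


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------


def write_table(path, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"code": str})


def read_measurements(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_demographics(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").set_index("person")


def read_relatedness(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_phecode_map(path, pmap: pd.DataFrame) -> None:
    pmap.to_csv(path, index=False)


def read_phecode_map(path) -> pd.DataFrame:
    pmap = pd.read_csv(path, dtype={"icd9": str})
    required = {"icd9", "phecode", "exclusion_low", "exclusion_high"}
    missing = required - set(pmap.columns)
    if missing:
        raise ValueError(f"phecode map missing columns: {sorted(missing)}")
    return pmap


def read_regions(path) -> dict:
    """Gene regions from a 4-column TSV: gene, chrom, start, end
    (1-based, both ends inclusive)."""
    from .config import GeneRegion

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {
        r["gene"]: GeneRegion(r["gene"], str(r["chrom"]), int(r["start"]), int(r["end"]))
        for _, r in df.iterrows()
    }


def file_digest(path) -> str:
    """SHA-256 of a file, for run manifests."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
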