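"""Tabular and VCF I/O for the pipeline's file formats.

All coordinates are 1-based (VCF convention). Tables are plain TSV/CSV with
the column schemas documented on the reader/writer pairs; VCF 4.2 emission
and ingestion of variant tables goes through pysam.
"""

from __future__ import annotations

import pandas as pd
import pysam

from .filtering import VARIANT_COLUMNS


def write_variants_tsv(variants: pd.DataFrame, path) -> None:
    variants.to_csv(path, sep="\t", index=False)


def read_variants_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table {path} lacks columns {missing}")
    df["is_hotspot"] = df["is_hotspot"].astype(bool)
    df["in_superdup"] = df["in_superdup"].astype(bool)
    return df


_VCF_INFO = [
    ("GENE", "1", "String", "Gene symbol"),
    ("EFFECT", "1", "String", "Coding effect"),
    ("PFMAX", "1", "Float", "Maximum population allele frequency"),
    ("HOTSPOT", "0", "Flag", "Cancer hotspot"),
    ("SUPERDUP", "0", "Flag", "Segmental duplication region"),
    ("DP", "1", "Integer", "Total read depth"),
    ("AD", "1", "Integer", "Alt-supporting reads"),
    ("VAF", "1", "Float", "Variant allele fraction"),
]


def write_variants_vcf(variants: pd.DataFrame, path) -> None:
    """Emit a variant table as uncompressed VCF 4.2 (annotations in INFO)."""
    header = pysam.VariantHeader()
    for chrom in sorted(variants["chrom"].unique()):
        header.contigs.add(str(chrom))
    for name, number, typ, desc in _VCF_INFO:
        header.info.add(name, number, typ, desc)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for row in variants.sort_values(["chrom", "pos"], kind="stable").itertuples(index=False):
            rec = out.new_record(
                contig=str(row.chrom),
                start=int(row.pos) - 1,
                stop=int(row.pos) - 1 + len(str(row.ref)),
                alleles=(str(row.ref), str(row.alt)),
            )
            rec.info["GENE"] = str(row.gene)
            rec.info["EFFECT"] = str(row.effect)
            rec.info["PFMAX"] = float(row.popfreq_max)
            rec.info["DP"] = int(row.total_reads)
            rec.info["AD"] = int(row.alt_reads)
            rec.info["VAF"] = float(row.vaf)
            if bool(row.is_hotspot):
                rec.info["HOTSPOT"] = True
            if bool(row.in_superdup):
                rec.info["SUPERDUP"] = True
            out.write(rec)


def read_variants_vcf(path, patient_id: str | None = None) -> pd.DataFrame:
    """Read a VCF written by :func:`write_variants_vcf` back to the table."""
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            info = rec.info
            dp = int(info["DP"])
            ad = int(info["AD"])
            rows.append(
                {
                    "patient_id": patient_id,
                    "chrom": rec.contig,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0],
                    "gene": info["GENE"],
                    "effect": info["EFFECT"],
                    "alt_reads": ad,
                    "total_reads": dp,
                    "vaf": ad / dp if dp else 0.0,
                    "popfreq_max": float(info["PFMAX"]),
                    "is_hotspot": "HOTSPOT" in info,
                    "in_superdup": "SUPERDUP" in info,
                }
            )
    df = pd.DataFrame(rows)
    if patient_id is None and not df.empty:
        df = df.drop(columns=["patient_id"])
    return df


def write_ctdna_csv(ctdna: pd.DataFrame, path) -> None:
    ctdna.to_csv(path, index=False)


def read_ctdna_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_burden_csv(burden: pd.DataFrame, path) -> None:
    burden.to_csv(path, index=False)


def read_burden_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_outcomes_csv(outcomes: pd.DataFrame, path) -> None:
    outcomes.to_csv(path, index=False)


def read_outcomes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "event" in df.columns:
        df["event"] = df["event"].astype(bool)
    return df


def write_spectra_tsv(spectra: dict, path) -> None:
    """Cohort spectra as long-format patient/gene TSV."""
    with open(path, "w") as fh:
        fh.write("patient_id\tgene\n")
        for pid in spectra:
            for gene in sorted(spectra[pid]):
                fh.write(f"{pid}\t{gene}\n")


def read_spectra_tsv(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    return {pid: set(sub["gene"]) for pid, sub in df.groupby("patient_id")}
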