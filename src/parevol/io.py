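"""Readers and writers for the pipeline's standard text formats.

Count matrices travel as TSV (genes in rows, samples in columns, header row
of sample ids, optional sample-metadata sidecar); genotypes as minimal VCF
v4.2 with a GT-only FORMAT; annotation as 6-column BED (0-based, half-open);
gene sets as one-id-per-line text; population allele counts and all result
tables as TSV. Every writer round-trips losslessly through its reader.
VCF positions are 1-based and BED intervals 0-based half-open; the
conversion happens only at these boundaries.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .ase import GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING
from .diffexpr import CountMatrix

_GT_TO_CODE = {"0/0": HOM_REF, "0/1": HET, "1/0": HET, "1/1": HOM_ALT,
               "./.": MISSING, "0|0": HOM_REF, "0|1": HET, "1|0": HET,
               "1|1": HOM_ALT, ".|.": MISSING}
_CODE_TO_GT = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


class ParseError(ValueError):
    """Malformed record, annotated with the offending line number."""


# ---------------------------------------------------------------- counts TSV

def write_counts_tsv(cm: CountMatrix, path, meta_path=None) -> None:
    out = cm.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")
    if meta_path is not None:
        meta = cm.sample_meta.copy()
        meta.index.name = "sample_id"
        meta.to_csv(meta_path, sep="\t")


def read_counts_tsv(path, meta_path=None) -> CountMatrix:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts = counts.astype(int)
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        meta.index = meta.index.astype(str)
        meta = meta.where(meta.notna(), None)
    return CountMatrix(counts, meta)


# ----------------------------------------------------------------------- VCF

def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Minimal VCF v4.2, GT-only FORMAT field."""
    samples = list(gm.genotypes.columns)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for name, group in gm.sample_groups.items():
            fh.write(f"##SAMPLE=<ID={name},Group={group}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        geno = gm.genotypes.to_numpy()
        for i, row in enumerate(gm.snps.itertuples(index=False)):
            gts = "\t".join(_CODE_TO_GT[int(c)] for c in geno[i])
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path, sample_groups: dict | None = None) -> GenotypeMatrix:
    """Read a GT-only VCF; rejects non-biallelic records with their position.

    Sample groups are recovered from ##SAMPLE header lines when present, or
    may be supplied explicitly; otherwise every sample gets group 'unknown'.
    """
    snps, geno_rows = [], []
    header_groups: dict[str, str] = {}
    samples: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##SAMPLE=<"):
                body = line[len("##SAMPLE=<"):-1]
                kv = dict(part.split("=", 1) for part in body.split(","))
                if "ID" in kv and "Group" in kv:
                    header_groups[kv["ID"]] = kv["Group"]
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 10:
                raise ParseError(f"line {lineno}: fewer than 10 VCF columns")
            chrom, pos, _, ref, alt = parts[:5]
            if "," in alt or len(ref) != 1 or len(alt) != 1:
                raise ParseError(
                    f"line {lineno}: non-biallelic SNP record at {chrom}:{pos}"
                )
            fmt = parts[8].split(":")
            if fmt[0] != "GT":
                raise ParseError(f"line {lineno}: FORMAT must start with GT")
            codes = []
            for field in parts[9:]:
                gt = field.split(":")[0]
                if gt not in _GT_TO_CODE:
                    raise ParseError(f"line {lineno}: unparseable genotype {gt!r}")
                codes.append(_GT_TO_CODE[gt])
            snps.append((chrom, int(pos), ref, alt))
            geno_rows.append(codes)
    if not samples:
        raise ParseError("missing #CHROM header line")
    groups = sample_groups or header_groups
    sg = pd.Series([groups.get(s, "unknown") for s in samples],
                   index=pd.Index(samples))
    return GenotypeMatrix(
        pd.DataFrame(snps, columns=["chrom", "pos", "ref", "alt"]),
        pd.DataFrame(np.array(geno_rows, dtype=int).reshape(len(snps), -1),
                     columns=samples),
        sg,
    )


# ----------------------------------------------------------------------- BED

def write_bed(annotation: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end", "gene_id", "score", "strand"]
    ann = annotation.copy()
    if "score" not in ann:
        ann["score"] = 0
    if "strand" not in ann:
        ann["strand"] = "+"
    ann[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"line {lineno}: BED6 needs 6 columns")
            chrom, start, end, name, score, strand = parts[:6]
            start, end = int(start), int(end)
            if start >= end:
                raise ParseError(f"line {lineno}: start {start} >= end {end}")
            rows.append((chrom, start, end, name, int(score), strand))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "gene_id", "score", "strand"]
    )


# ----------------------------------------------------------- gene lists etc.

def write_gene_list(gene_ids, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in gene_ids))


def read_gene_list(path) -> list[str]:
    return [ln for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_pop_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_pop_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
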