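"""Readers and writers for the standard formats the pipeline touches.

FASTA/FASTQ go through Biopython; VCF reading goes through cyvcf2.
Internally everything is 0-based half-open; VCF and GFF3 positions are
converted at this boundary.

Truth metadata for simulated reads rides in the FASTQ read id under the
grammar ``<id>|<origin_class>|<chrom>:<pos>:<strand>`` so that external
aligners could be substituted without a side-channel file.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    ALT_HOM,
    HET,
    MISSING,
    REF_HOM,
    AnnotationSet,
    GenotypeMatrix,
    Read,
    ReadSet,
    ReferenceGenome,
)

__all__ = [
    "ParseError",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_genotypes",
    "write_genotypes",
    "read_gff3",
    "write_gff3",
    "write_bed",
]


class ParseError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | os.PathLike) -> ReferenceGenome:
    """Read a FASTA file; sequences are case-normalized to upper."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ParseError(
                        f"{path}: line {lineno}: expected '>' header, "
                        f"got {line.strip()[:20]!r}"
                    )
                break
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ParseError(f"{path}: line 1: no FASTA records found")
    return ReferenceGenome(records)


def write_fasta(genome: ReferenceGenome, path: str | os.PathLike, width: int = 70) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.chromosomes
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------- FASTQ

def _format_read_id(read: Read) -> str:
    if read.origin_class is None and read.truth_origin is None:
        return read.id
    chrom, pos, strand = read.truth_origin
    return f"{read.id}|{read.origin_class}|{chrom}:{pos}:{strand}"


def _parse_read_id(raw: str) -> tuple[str, str | None, tuple[str, int, str] | None]:
    parts = raw.split("|")
    if len(parts) != 3:
        return raw, None, None
    rid, oclass, origin = parts
    try:
        chrom, pos, strand = origin.rsplit(":", 2)
        return rid, oclass, (chrom, int(pos), strand)
    except ValueError:
        return raw, None, None


def read_fastq(path: str | os.PathLike, accession: str = "") -> ReadSet:
    """Read phred+33 FASTQ; truth metadata is recovered from the id grammar."""
    reads = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            rid, oclass, origin = _parse_read_id(rec.id)
            reads.append(
                Read(
                    id=rid,
                    accession=accession,
                    sequence=str(rec.seq).upper(),
                    qualities=np.asarray(
                        rec.letter_annotations["phred_quality"], dtype=np.int16
                    ),
                    truth_origin=origin,
                    origin_class=oclass,
                )
            )
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return ReadSet(reads)


def write_fastq(readset: ReadSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for read in readset:
            qual = "".join(chr(q + 33) for q in read.qualities)
            fh.write(f"@{_format_read_id(read)}\n{read.sequence}\n+\n{qual}\n")


# ------------------------------------------------------------ genotypes

_GT_TO_CODE = {0: REF_HOM, 1: HET, 2: MISSING, 3: ALT_HOM}  # cyvcf2 gt_types
_CODE_TO_GT = {REF_HOM: "0/0", HET: "0/1", ALT_HOM: "1/1", MISSING: "./."}


def _vtype(ref: str, alt: str) -> str:
    if len(ref) == len(alt) == 1:
        return "SNP"
    return "insertion" if len(alt) > len(ref) else "deletion"


def read_genotypes(path: str | os.PathLike, format: str = None) -> GenotypeMatrix:
    """Read a genotype matrix from VCF or TSV (one locus per row).

    VCF records must be biallelic; multiallelic records and duplicate
    loci raise errors.  VCF positions (1-based) are converted to the
    internal 0-based convention.
    """
    if format is None:
        format = "vcf" if str(path).endswith(".vcf") else "tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    accessions = list(vcf.samples)
    rows, codes, seen = [], [], set()
    for v in vcf:
        if len(v.ALT) != 1:
            raise ParseError(
                f"{path}: multiallelic record at {v.CHROM}:{v.POS}; "
                "split into biallelic records first"
            )
        key = (v.CHROM, v.POS)
        if key in seen:
            raise ParseError(f"{path}: duplicate locus {v.CHROM}:{v.POS}")
        seen.add(key)
        ref, alt = v.REF, v.ALT[0]
        rows.append((v.CHROM, v.POS - 1, ref, alt, _vtype(ref, alt)))
        codes.append([_GT_TO_CODE[g] for g in v.gt_types])
    loci = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "vtype"])
    return GenotypeMatrix(loci, accessions, np.asarray(codes, dtype=np.int8))


def _read_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = ["chrom", "pos", "ref", "alt", "vtype"]
    accessions = [c for c in df.columns if c not in meta_cols]
    name_to_code = {v: k for k, v in
                    {REF_HOM: "REF_HOM", HET: "HET", ALT_HOM: "ALT_HOM",
                     MISSING: "MISSING"}.items()}
    try:
        codes = df[accessions].apply(lambda col: col.map(name_to_code)).to_numpy()
    except KeyError as exc:
        raise ParseError(f"{path}: bad genotype code {exc}") from exc
    if pd.isna(codes).any():
        raise ParseError(f"{path}: unrecognized genotype code")
    keys = list(zip(df["chrom"], df["pos"]))
    if len(set(keys)) != len(keys):
        raise ParseError(f"{path}: duplicate locus")
    return GenotypeMatrix(df[meta_cols], accessions, codes.astype(np.int8))


def write_genotypes(matrix: GenotypeMatrix, path: str | os.PathLike,
                    format: str = None,
                    contig_lengths: dict[str, int] | None = None) -> None:
    if format is None:
        format = "vcf" if str(path).endswith(".vcf") else "tsv"
    if format == "tsv":
        df = matrix.loci.copy()
        names = np.array(["MISSING", "REF_HOM", "HET", "ALT_HOM"])
        for j, acc in enumerate(matrix.accessions):
            df[acc] = names[matrix.codes[:, j] + 1]
        df.to_csv(path, sep="\t", index=False)
        return
    if format != "vcf":
        raise ValueError(f"unknown genotype format {format!r}")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if contig_lengths:
            for c, l in contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={l}>\n")
        else:
            for c in matrix.loci["chrom"].unique():
                fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(matrix.accessions) + "\n")
        for i, row in enumerate(matrix.loci.itertuples(index=False)):
            gts = "\t".join(_CODE_TO_GT[c] for c in matrix.codes[i])
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t"
                f"VT={row.vtype}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------- GFF3

def write_gff3(annotation: AnnotationSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, f in enumerate(annotation.features.itertuples(index=False)):
            attrs = [f"ID=f{i}"]
            if f.gene_id:
                attrs.append(f"gene_id={f.gene_id}")
            if f.family_id:
                attrs.append(f"family_id={f.family_id}")
            phase = str(f.phase) if f.ftype == "CDS" else "."
            fh.write(
                f"{f.chrom}\tradgbs\t{f.ftype}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t{phase}\t{';'.join(attrs)}\n"
            )


def read_gff3(path: str | os.PathLike) -> AnnotationSet:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, phase, attrs = fields
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(start) - 1,
                    "end": int(end),
                    "strand": strand,
                    "ftype": ftype,
                    "phase": int(phase) if phase != "." else -1,
                    "gene_id": attr.get("gene_id", ""),
                    "family_id": attr.get("family_id", ""),
                }
            )
    return AnnotationSet(pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "strand", "ftype", "phase",
                 "gene_id", "family_id"],
    ))


# ----------------------------------------------------------------- BED

def write_bed(intervals: Iterable[tuple], path: str | os.PathLike) -> None:
    """Write (chrom, start, end[, name[, score]]) tuples as BED."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")
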