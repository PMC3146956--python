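"""Shared domain types for the RAD-seq analysis stack.

Coordinate convention: every position stored in these containers is
0-based, half-open.  The standard-format readers/writers in
:mod:`radgbs.io` convert to and from the 1-based conventions of VCF and
GFF3 at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "REF_HOM",
    "HET",
    "ALT_HOM",
    "MISSING",
    "CODE_NAMES",
    "IUPAC",
    "ValidationError",
    "ReferenceGenome",
    "Enzyme",
    "PSTI",
    "BSRFI",
    "HPAII",
    "AnnotationSet",
    "GenotypeMatrix",
    "Read",
    "ReadSet",
    "CoverageMap",
    "revcomp",
]

# Genotype codes.  The numeric values are chosen so that the per-locus
# allele identity between two homozygous-or-het calls is 2 - |a - b|
# (same hom vs same hom = 2, opposite homs = 0, hom vs het = 1).
REF_HOM: int = 0
HET: int = 1
ALT_HOM: int = 2
MISSING: int = -1

CODE_NAMES = {REF_HOM: "REF_HOM", HET: "HET", ALT_HOM: "ALT_HOM", MISSING: "MISSING"}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of a (possibly IUPAC-degenerate) sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


class ValidationError(ValueError):
    """Raised when a container violates one of its invariants."""


@dataclass
class ReferenceGenome:
    """An ordered set of named chromosome sequences over {A,C,G,T}."""

    chromosomes: list[tuple[str, str]]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate chromosome names")
        for name, seq in self.chromosomes:
            if not seq:
                raise ValidationError(f"chromosome {name!r} has empty sequence")
            if set(seq) - set("ACGT"):
                bad = sorted(set(seq) - set("ACGT"))
                raise ValidationError(
                    f"chromosome {name!r} contains non-ACGT characters {bad}"
                )

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    def sequence(self, name: str) -> str:
        for n, s in self.chromosomes:
            if n == name:
                return s
        raise KeyError(name)

    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self.chromosomes}

    def total_length(self) -> int:
        return sum(len(s) for _, s in self.chromosomes)


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: IUPAC recognition motif and top-strand cut offset.

    ``cut_offset`` is the position of the top-strand cut within the motif,
    so PstI (CTGCA^G) has offset 5 and BsrFI (R^CCGGY) has offset 1.
    """

    name: str
    motif: str
    cut_offset: int

    def __post_init__(self) -> None:
        if set(self.motif.upper()) - set(IUPAC):
            raise ValidationError(f"invalid IUPAC code in motif {self.motif!r}")
        if not (0 <= self.cut_offset <= len(self.motif)):
            raise ValidationError("cut_offset outside motif")

    @property
    def is_palindromic(self) -> bool:
        return revcomp(self.motif.upper()) == self.motif.upper()


PSTI = Enzyme("PstI", "CTGCAG", 5)
BSRFI = Enzyme("BsrFI", "RCCGGY", 1)
HPAII = Enzyme("HpaII", "CCGG", 1)

_FTYPES = {"gene", "exon", "CDS", "intron", "UTR", "repeat"}

_FEATURE_COLUMNS = [
    "chrom", "start", "end", "strand", "ftype", "phase", "gene_id", "family_id",
]


@dataclass
class AnnotationSet:
    """Genomic features (0-based half-open) as a DataFrame.

    Columns: chrom, start, end, strand, ftype, phase, gene_id, family_id.
    ``phase`` is 0/1/2 for CDS and -1 otherwise; ``family_id`` may be "".
    """

    features: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.features
        missing = [c for c in _FEATURE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"missing feature columns {missing}")
        self.features = df = df[_FEATURE_COLUMNS].reset_index(drop=True)
        if len(df) == 0:
            return
        if (df["start"] >= df["end"]).any():
            raise ValidationError("feature with start >= end")
        bad = set(df["ftype"]) - _FTYPES
        if bad:
            raise ValidationError(f"unknown feature types {sorted(bad)}")

    def validate_against(self, genome: ReferenceGenome) -> None:
        """Check chromosome bounds and CDS frame-completeness."""
        lengths = genome.lengths()
        for chrom, grp in self.features.groupby("chrom"):
            if chrom not in lengths:
                raise ValidationError(f"feature on unknown chromosome {chrom!r}")
            if (grp["end"] > lengths[chrom]).any():
                raise ValidationError(f"feature beyond end of {chrom!r}")
        cds = self.features[self.features["ftype"] == "CDS"]
        for gene_id, grp in cds.groupby("gene_id"):
            total = int((grp["end"] - grp["start"]).sum())
            if total % 3 != 0:
                raise ValidationError(
                    f"CDS of gene {gene_id!r} has total length {total}, "
                    "not divisible by 3"
                )

    def of_type(self, ftype: str) -> pd.DataFrame:
        return self.features[self.features["ftype"] == ftype]

    def gene_cds(self, gene_id: str) -> pd.DataFrame:
        """CDS segments of a gene in genomic coordinate order."""
        cds = self.features[
            (self.features["ftype"] == "CDS") & (self.features["gene_id"] == gene_id)
        ]
        return cds.sort_values("start").reset_index(drop=True)


_LOCUS_COLUMNS = ["chrom", "pos", "ref", "alt", "vtype"]
_VTYPES = {"SNP", "insertion", "deletion"}


@dataclass
class GenotypeMatrix:
    """Loci x accessions genotype codes plus locus metadata.

    ``loci`` is a DataFrame with columns chrom, pos (0-based), ref, alt,
    vtype; ``codes`` is an int8 array of shape (n_loci, n_accessions)
    over {REF_HOM, HET, ALT_HOM, MISSING}.
    """

    loci: pd.DataFrame
    accessions: list[str]
    codes: np.ndarray

    def __post_init__(self) -> None:
        df = self.loci
        missing = [c for c in _LOCUS_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"missing locus columns {missing}")
        self.loci = df = df[_LOCUS_COLUMNS].reset_index(drop=True)
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(df), len(self.accessions)):
            raise ValidationError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(df)} loci x {len(self.accessions)} accessions"
            )
        bad = set(np.unique(self.codes)) - {REF_HOM, HET, ALT_HOM, MISSING}
        if bad:
            raise ValidationError(f"invalid genotype codes {sorted(bad)}")
        if set(df["vtype"]) - _VTYPES:
            raise ValidationError("invalid vtype")
        keys = list(zip(df["chrom"], df["pos"]))
        if sorted(keys) != keys:
            raise ValidationError("loci not sorted by (chrom, pos)")
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate locus")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    def check_truth(self) -> None:
        """Truth-matrix invariant: every locus has >= 1 ALT_HOM or HET."""
        carried = ((self.codes == ALT_HOM) | (self.codes == HET)).any(axis=1)
        if not carried.all():
            raise ValidationError(
                f"{int((~carried).sum())} truth loci with no ALT_HOM/HET entry"
            )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.loci.copy(), list(self.accessions), self.codes.copy())

    def subset_loci(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.loci[mask].reset_index(drop=True), list(self.accessions),
            self.codes[mask],
        )


@dataclass
class Read:
    """A sequencing read with optional truth metadata.

    ``truth_origin`` is (chrom, pos, strand) of the simulated origin in
    reference coordinates; ``origin_class`` is cRS / ncRS / SR.
    """

    id: str
    accession: str
    sequence: str
    qualities: np.ndarray
    truth_origin: Optional[tuple[str, int, str]] = None
    origin_class: Optional[str] = None

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.int16)
        if len(self.sequence) != len(self.qualities):
            raise ValidationError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )
        if len(self.qualities) and (
            self.qualities.min() < 0 or self.qualities.max() > 41
        ):
            raise ValidationError(f"read {self.id!r}: phred scores outside [0, 41]")


@dataclass
class ReadSet:
    """An ordered collection of reads."""

    reads: list[Read] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return ReadSet(self.reads[i])
        return self.reads[i]

    def extend(self, other: Iterable[Read]) -> None:
        self.reads.extend(other)


class CoverageMap:
    """Per-accession base-level depth and the pairwise common-coverage matrix.

    ``B_pair[i, j]`` is the number of *bases* (twice the number of base
    pairs, i.e. 2x the count of positions) covered at depth >= 1 in both
    accessions i and j; the diagonal is twice each accession's covered
    base count.
    """

    def __init__(self, accessions: Sequence[str], chrom_lengths: dict[str, int]):
        self.accessions = list(accessions)
        self.chrom_lengths = dict(chrom_lengths)
        self.depth = {
            acc: {c: np.zeros(l, dtype=np.int32) for c, l in chrom_lengths.items()}
            for acc in self.accessions
        }

    def add_interval(self, accession: str, chrom: str, start: int, end: int) -> None:
        self.depth[accession][chrom][start:end] += 1

    def covered(self, accession: str, chrom: str) -> np.ndarray:
        return self.depth[accession][chrom] > 0

    def covered_bases(self, accession: str) -> int:
        return int(sum(np.count_nonzero(d > 0) for d in self.depth[accession].values()))

    def b_pair(self) -> pd.DataFrame:
        n = len(self.accessions)
        b = np.zeros((n, n), dtype=np.int64)
        for ci in self.chrom_lengths:
            cov = np.stack([self.covered(a, ci) for a in self.accessions])
            b += 2 * (cov.astype(np.int64) @ cov.T.astype(np.int64))
        return pd.DataFrame(b, index=self.accessions, columns=self.accessions)
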