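"""Read QC, minimal unique-best alignment, pileup and SNP calling.

The alignment step is an ungapped, mismatch-bounded exact-best aligner:
a read is kept only if its best placement (fewest mismatches, at most
``max_mismatches``) is achieved at exactly one genomic position over
both strands.  Candidate placements are found with a pigeonhole k-mer
seed index, so the search is exhaustive within the mismatch bound.

Two SNP filters mirror the two published rule sets:

* a simple filter — some single alternative base supported by at least
  6 reads whose supporting base qualities average >= 20;
* a quality-model filter — a phred-scaled variant quality equal to the
  probability that every alternative-supporting observation is a
  sequencing error under independent per-base error rates (floored),
  gated at minimum depth 3 and quality 20 (SNPs) / 50 (indels).

Indel calling from alignments is out of scope (the aligner is
ungapped); indel records reach downstream stages from truth or user
VCFs, where the indel-quality gate is honored by ``filter_candidates``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    ALT_HOM,
    HET,
    MISSING,
    REF_HOM,
    CoverageMap,
    GenotypeMatrix,
    ReadSet,
    ReferenceGenome,
    revcomp,
)

__all__ = [
    "preprocess_reads",
    "Alignment",
    "GenomeIndex",
    "align_unique",
    "Pileup",
    "build_pileup",
    "CandidateSet",
    "call_simple_filter",
    "call_quality_model",
    "filter_candidates",
    "ValidationReport",
    "validate",
    "validate_counts",
]


# ----------------------------------------------------------------- QC


def preprocess_reads(readset: ReadSet, trim_3prime: int = 4,
                     min_mean_quality: float = 25.0) -> ReadSet:
    """Trim 3' ends and drop reads whose mean phred is below threshold.

    Reads shorter than the trim are dropped; counts are recorded in the
    returned set's ``attrs``-style fields (``n_dropped_short``,
    ``n_dropped_quality``).
    """
    out = ReadSet()
    n_short = n_lowq = 0
    for read in readset:
        if trim_3prime >= len(read.sequence):
            n_short += 1
            continue
        n = len(read.sequence) - trim_3prime
        seq = read.sequence[:n]
        qual = read.qualities[:n]
        if qual.mean() < min_mean_quality:
            n_lowq += 1
            continue
        out.reads.append(
            type(read)(read.id, read.accession, seq, qual,
                       read.truth_origin, read.origin_class)
        )
    out.n_dropped_short = n_short  # type: ignore[attr-defined]
    out.n_dropped_quality = n_lowq  # type: ignore[attr-defined]
    return out


# ------------------------------------------------------------ aligner


@dataclass
class Alignment:
    read_index: int
    chrom: str
    pos: int
    strand: str
    n_mismatches: int
    # (genome position, read base, phred of the supporting base)
    mismatches: list[tuple[int, str, int]] = field(default_factory=list)
    length: int = 0


class GenomeIndex:
    """Exact k-mer position index over the top strand of a genome."""

    def __init__(self, genome: ReferenceGenome, k: int):
        self.genome = genome
        self.k = k
        self.arrays = {c: np.frombuffer(s.encode(), dtype=np.uint8)
                       for c, s in genome.chromosomes}
        index: dict[bytes, list[tuple[str, int]]] = {}
        for chrom, seq in genome.chromosomes:
            b = seq.encode()
            for i in range(len(b) - k + 1):
                index.setdefault(b[i:i + k], []).append((chrom, i))
        self.index = index

    def candidates(self, seq: bytes, max_mismatches: int):
        """Candidate start positions: by pigeonhole, a placement with at
        most ``max_mismatches`` mismatches leaves at least one of
        max_mismatches+1 read segments clean, and the k-prefix of a
        clean segment is an exact index hit."""
        n_seg = max_mismatches + 1
        L = len(seq)
        out = set()
        for j in range(n_seg):
            off = j * L // n_seg
            hit = self.index.get(seq[off:off + self.k])
            if hit:
                for chrom, p in hit:
                    start = p - off
                    if start >= 0 and start + L <= len(self.arrays[chrom]):
                        out.add((chrom, start))
        return out


def align_unique(genome: ReferenceGenome, readset: ReadSet,
                 max_mismatches: int = 2,
                 index: GenomeIndex | None = None) -> list[Alignment]:
    """Align each read to its unique best placement, if one exists.

    A read is discarded when its minimum-mismatch placement (within the
    bound) is achieved at more than one position over the two strands.
    Unalignable and non-unique reads are simply absent from the output.
    """
    if len(readset) == 0:
        return []
    min_len = min(len(r.sequence) for r in readset)
    k = max(4, min_len // (max_mismatches + 1))
    if index is None or index.k != k:
        index = GenomeIndex(genome, k)
    alignments = []
    for ri, read in enumerate(readset):
        placements = []  # (n_mm, chrom, pos, strand, mm_positions)
        best = max_mismatches + 1
        for strand in "+-":
            s = read.sequence if strand == "+" else revcomp(read.sequence)
            b = s.encode()
            arr = np.frombuffer(b, dtype=np.uint8)
            for chrom, start in index.candidates(b, max_mismatches):
                ref = index.arrays[chrom][start:start + len(arr)]
                diff = np.flatnonzero(ref != arr)
                if len(diff) <= best:
                    if len(diff) < best:
                        best = len(diff)
                        placements = []
                    placements.append((chrom, start, strand, diff))
        if best > max_mismatches or len(placements) != 1:
            continue
        chrom, start, strand, diff = placements[0]
        qual = read.qualities if strand == "+" else read.qualities[::-1]
        seq = read.sequence if strand == "+" else revcomp(read.sequence)
        mism = [(int(start + d), seq[d], int(qual[d])) for d in diff]
        alignments.append(Alignment(ri, chrom, int(start), strand,
                                    len(diff), mism, len(seq)))
    return alignments


# ------------------------------------------------------------- pileup


class Pileup:
    """Per-position evidence: depth per accession plus alternative-base
    observations (base, phred) at positions where any read disagrees
    with the reference."""

    def __init__(self, genome: ReferenceGenome, accessions: list[str]):
        self.genome = genome
        self.accessions = list(accessions)
        self.coverage = CoverageMap(accessions, genome.lengths())
        # (chrom, pos) -> accession -> base -> list of phreds
        self.alt_obs: dict[tuple[str, int], dict[str, dict[str, list[int]]]] = {}
        self.total_aligned_bases = 0

    def depth_at(self, chrom: str, pos: int) -> dict[str, int]:
        return {a: int(self.coverage.depth[a][chrom][pos])
                for a in self.accessions}

    def average_coverage(self) -> float:
        covered = 0
        for chrom, l in self.coverage.chrom_lengths.items():
            pooled = np.zeros(l, dtype=bool)
            for a in self.accessions:
                pooled |= self.coverage.covered(a, chrom)
            covered += int(pooled.sum())
        return self.total_aligned_bases / covered if covered else float("nan")


def build_pileup(genome: ReferenceGenome, alignments: list[Alignment],
                 readset: ReadSet) -> Pileup:
    accessions = sorted({r.accession for r in readset})
    pile = Pileup(genome, accessions)
    for aln in alignments:
        read = readset.reads[aln.read_index]
        pile.coverage.add_interval(read.accession, aln.chrom, aln.pos,
                                   aln.pos + aln.length)
        pile.total_aligned_bases += aln.length
        for pos, base, q in aln.mismatches:
            col = pile.alt_obs.setdefault((aln.chrom, pos), {})
            col.setdefault(read.accession, {}).setdefault(base, []).append(q)
    return pile


# ------------------------------------------------------------ callers


@dataclass
class CandidateSet:
    """Called variant candidates with per-accession genotypes.

    ``table`` columns: chrom, pos, ref, alt, vtype, score, depth;
    ``genotypes`` is an int8 array aligned with ``table`` rows and
    ``accessions`` columns.
    """

    table: pd.DataFrame
    accessions: list[str]
    genotypes: np.ndarray
    caller: str

    def keys(self) -> set[tuple[str, int, str]]:
        return set(zip(self.table["chrom"], self.table["pos"], self.table["alt"]))

    def to_genotype_matrix(self) -> GenotypeMatrix:
        loci = self.table[["chrom", "pos", "ref", "alt", "vtype"]].copy()
        order = np.lexsort((loci["pos"].to_numpy(), loci["chrom"].to_numpy()))
        return GenotypeMatrix(loci.iloc[order].reset_index(drop=True),
                              list(self.accessions), self.genotypes[order])

    def n_genotypes_called(self) -> int:
        return int((self.genotypes != MISSING).sum())


def _genotype(alt_count: int, depth: int, min_depth: int) -> int:
    if depth < min_depth:
        return MISSING
    frac = alt_count / depth
    if frac >= 0.8:
        return ALT_HOM
    if frac >= 0.2:
        return HET
    return REF_HOM


def _best_alt(col: dict[str, dict[str, list[int]]]):
    """Pool observations over accessions; return per-base pooled lists."""
    pooled: dict[str, list[int]] = {}
    for accmap in col.values():
        for base, quals in accmap.items():
            pooled.setdefault(base, []).extend(quals)
    return pooled


def _make_candidates(pile: Pileup, rows, genos, caller) -> CandidateSet:
    table = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "vtype", "score", "depth"]
    )
    genos = (np.asarray(genos, dtype=np.int8) if len(genos)
             else np.zeros((0, len(pile.accessions)), dtype=np.int8))
    order = np.lexsort((table["pos"].to_numpy(), table["chrom"].to_numpy()))
    return CandidateSet(table.iloc[order].reset_index(drop=True),
                        list(pile.accessions), genos[order], caller)


def call_simple_filter(pile: Pileup, min_alt_reads: int = 6,
                       min_mean_alt_quality: float = 20.0) -> CandidateSet:
    """Simple depth-and-quality filter.

    A column is a candidate iff some single alternative base is
    supported by >= ``min_alt_reads`` reads whose phreds average
    >= ``min_mean_alt_quality`` (counted per allele, pooled over
    accessions).  Score is the mean supporting phred.
    """
    seqs = dict(pile.genome.chromosomes)
    rows, genos = [], []
    for (chrom, pos), col in pile.alt_obs.items():
        pooled = _best_alt(col)
        passing = [
            (len(q), float(np.mean(q)), b)
            for b, q in pooled.items()
            if len(q) >= min_alt_reads and np.mean(q) >= min_mean_alt_quality
        ]
        if not passing:
            continue
        count, meanq, alt = max(passing)
        depths = pile.depth_at(chrom, pos)
        rows.append((chrom, pos, seqs[chrom][pos], alt, "SNP",
                     float(meanq), int(sum(depths.values()))))
        genos.append([
            _genotype(len(col.get(a, {}).get(alt, [])), depths[a], 1)
            for a in pile.accessions
        ])
    return _make_candidates(pile, rows, genos, "simple")


def call_quality_model(pile: Pileup, min_depth: int = 3,
                       min_snp_quality: float = 20.0,
                       min_indel_quality: float = 50.0,
                       error_floor: float = 0.001) -> CandidateSet:
    """Phred-scaled independent-errors variant quality.

    Variant quality is -10 log10 P(all alternative-supporting
    observations are errors), i.e. the sum of supporting phreds, each
    capped at -10 log10(error_floor); the total is capped at 255.  A
    column is a candidate iff pooled depth >= ``min_depth`` and quality
    >= ``min_snp_quality``.  (``min_indel_quality`` applies to indel
    records supplied externally; see :func:`filter_candidates`.)
    """
    qcap = -10.0 * np.log10(error_floor)
    seqs = dict(pile.genome.chromosomes)
    rows, genos = [], []
    for (chrom, pos), col in pile.alt_obs.items():
        pooled = _best_alt(col)
        scored = [
            (min(255.0, float(np.minimum(q, qcap).sum())), len(q), b)
            for b, q in pooled.items()
        ]
        quality, count, alt = max(scored)
        depths = pile.depth_at(chrom, pos)
        total_depth = int(sum(depths.values()))
        if total_depth < min_depth or quality < min_snp_quality:
            continue
        rows.append((chrom, pos, seqs[chrom][pos], alt, "SNP",
                     quality, total_depth))
        genos.append([
            _genotype(len(col.get(a, {}).get(alt, [])), depths[a], min_depth)
            for a in pile.accessions
        ])
    return _make_candidates(pile, rows, genos, "quality_model")


def filter_candidates(table: pd.DataFrame, min_snp_quality: float = 20.0,
                      min_indel_quality: float = 50.0) -> pd.DataFrame:
    """Apply the type-appropriate quality gate to a variant table
    (columns vtype and score), e.g. user-supplied indel records."""
    is_snp = table["vtype"] == "SNP"
    keep = (is_snp & (table["score"] >= min_snp_quality)) | (
        ~is_snp & (table["score"] >= min_indel_quality)
    )
    return table[keep].reset_index(drop=True)


# ---------------------------------------------------------- validation


@dataclass
class ValidationReport:
    n_true: int
    n_called: int
    n_confirmed: int

    @property
    def confirmation_rate(self) -> float:
        return self.n_confirmed / self.n_called if self.n_called else float("nan")

    @property
    def recall(self) -> float:
        return self.n_confirmed / self.n_true if self.n_true else float("nan")

    def __post_init__(self) -> None:
        if self.n_confirmed > min(self.n_true, self.n_called):
            raise ValueError("n_confirmed exceeds n_true or n_called")


def validate_counts(truth_keys: set, called_keys: set) -> ValidationReport:
    """Exact set arithmetic on (chrom, pos, alt) keys."""
    return ValidationReport(
        n_true=len(truth_keys),
        n_called=len(called_keys),
        n_confirmed=len(truth_keys & called_keys),
    )


def _in_region(chrom, pos, region) -> bool:
    if region is None:
        return True
    return any(c == chrom and a <= pos < b for c, a, b in region)


def validate(candidates: CandidateSet, truth: GenotypeMatrix,
             region: list[tuple[str, int, int]] | None = None,
             ) -> tuple[ValidationReport, pd.DataFrame]:
    """Score candidates against truth SNPs by (chrom, pos, alt).

    ``region`` optionally restricts both sets to a list of
    (chrom, start, end) intervals.  Also returns the
    confirmation-versus-score-threshold curve: n_called is
    non-increasing in the threshold.
    """
    truth_snps = truth.loci[truth.loci["vtype"] == "SNP"]
    truth_keys = {
        (r.chrom, r.pos, r.alt)
        for r in truth_snps.itertuples(index=False)
        if _in_region(r.chrom, r.pos, region)
    }
    cand = candidates.table
    keep = [
        _in_region(r.chrom, r.pos, region) for r in cand.itertuples(index=False)
    ]
    cand = cand[np.asarray(keep, dtype=bool)] if len(cand) else cand
    called_keys = set(zip(cand["chrom"], cand["pos"], cand["alt"]))
    report = validate_counts(truth_keys, called_keys)
    rows = []
    for t in sorted(cand["score"].unique()):
        sub = cand[cand["score"] >= t]
        keys = set(zip(sub["chrom"], sub["pos"], sub["alt"]))
        conf = len(keys & truth_keys) / len(keys) if keys else float("nan")
        rows.append((float(t), len(keys), conf))
    curve = pd.DataFrame(rows, columns=["threshold", "n_called",
                                        "confirmation_rate"])
    return report, curve
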