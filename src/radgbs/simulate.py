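"""Synthetic panel generator.

Produces a reference genome with annotated gene models and repeats, a
truth variant panel with block-structured allele sharing (pairs or
groups of genomically similar inbred accessions plus divergent
outgroups), and simulated RAD / semirandom (SR) read sets — so that
every downstream stage can be exercised without external data.

The allele-sharing model assigns each variant a carrier pattern by first
choosing a group with probability proportional to its size, then
including each group member with probability ``p_in`` and each outsider
with probability ``p_out``.  The pair (p_in, p_out) is calibrated from
the configured within/between-group similarity targets by a bounded
least-squares fit of the implied discordance moments; singleton
(rare-allele-skewed) variants arise naturally from the outgroup terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model import (
    ALT_HOM,
    HET,
    HPAII,
    IUPAC,
    REF_HOM,
    AnnotationSet,
    Enzyme,
    BSRFI,
    GenotypeMatrix,
    Read,
    ReadSet,
    ReferenceGenome,
    ValidationError,
    revcomp,
)

__all__ = [
    "PanelConfig",
    "LibraryConfig",
    "DEFAULT_INDEL_LENGTH_WEIGHTS",
    "generate_reference",
    "generate_panel_variants",
    "simulate_reads",
    "apply_variants",
    "calibrate_sharing",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
]

# Default indel length distribution: 80% of indels 1-3 bp long, tail to 13.
DEFAULT_INDEL_LENGTH_WEIGHTS = {
    1: 0.45, 2: 0.20, 3: 0.15, 4: 0.05, 5: 0.04, 6: 0.03, 7: 0.02,
    8: 0.02, 9: 0.01, 10: 0.01, 11: 0.01, 12: 0.005, 13: 0.005,
}


@dataclass
class PanelConfig:
    """Structure and density parameters of the truth variant panel.

    ``groups`` partitions the accessions; each entry is (members, s_in)
    where s_in is the target within-group pairwise genomic similarity.
    ``s_out`` is the target similarity across groups.  Densities are per
    kilobase.  ``exon_frame_bias`` multiplies the weight of
    multiple-of-3 indel lengths inside CDS.
    """

    accessions: list[str] = field(
        default_factory=lambda: [f"Sb{i}" for i in range(1, 9)]
    )
    groups: list[tuple[list[str], float]] = field(
        default_factory=lambda: [
            (["Sb1", "Sb2"], 0.9),
            (["Sb3", "Sb4"], 0.9),
            (["Sb5"], 1.0),
            (["Sb6"], 1.0),
            (["Sb7"], 1.0),
            (["Sb8"], 1.0),
        ]
    )
    s_out: float = 0.6
    snp_density: float = 50.0
    indel_density: float = 10.0
    indel_length_weights: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_INDEL_LENGTH_WEIGHTS)
    )
    exon_frame_bias: float = 3.0
    het_rate: float = 0.005
    transition_prob: float = 0.58
    seed: int = 0

    def __post_init__(self) -> None:
        members = [a for g, _ in self.groups for a in g]
        if sorted(members) != sorted(self.accessions):
            raise ValidationError("groups do not partition the accessions")
        if self.snp_density <= 0 or self.indel_density < 0:
            raise ValidationError("densities must be positive")
        w = sum(self.indel_length_weights.values())
        if abs(w - 1.0) > 1e-6:
            raise ValidationError("indel length weights must sum to 1")
        for _, s_in in self.groups:
            if s_in < self.s_out:
                raise ValidationError("s_in < s_out: impossible similarity targets")


@dataclass
class LibraryConfig:
    """Sequencing-library parameters for read simulation.

    RAD reads start at restriction cut sites of ``enzyme`` at negative-
    binomial per-site depth, with an ``ncrs_fraction`` of reads from
    noncanonical (star-activity) origins; SR reads start uniformly
    within size-selected fragments of an HpaII-style digest.  Raw read
    lengths are pre-trim (the QC stage trims 4 bases from 3' ends).
    """

    lib_type: str = "RAD"
    enzyme: Enzyme = BSRFI
    read_length: int = 60
    mean_site_depth: float = 12.0
    depth_dispersion: float = 3.0
    ncrs_fraction: float = 0.12
    site_dropout: float = 0.0
    reads_per_accession: int = 20000
    size_range: tuple[int, int] = (200, 2000)
    error_rate: float = 0.001
    mean_quality: float = 30.0
    sd_quality: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lib_type not in ("RAD", "SR"):
            raise ValidationError("lib_type must be RAD or SR")
        if not (0 <= self.ncrs_fraction < 1):
            raise ValidationError("ncrs_fraction must be in [0, 1)")
        if not (0 <= self.error_rate <= 0.1):
            raise ValidationError("error_rate must be in [0, 0.1]")
        if self.size_range[0] >= self.size_range[1]:
            raise ValidationError("size_range min must be < max")


# ------------------------------------------------------------ reference


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p).tobytes().decode()


def _make_gene(rng: np.random.Generator, gc: float) -> dict:
    """Build one gene in transcription orientation.

    Returns the forward-oriented sequence plus segment layout: 5' UTR,
    CDS exon segments separated by GT..AG introns, 3' UTR.
    """
    n_codons = int(rng.integers(50, 150))
    cds = "ATG" + "".join(rng.choice(_SENSE_CODONS, size=n_codons)) + \
        str(rng.choice(["TAA", "TAG", "TGA"]))
    n_exons = int(rng.integers(1, 5))
    # split CDS into n_exons parts, each >= 3 bases
    if n_exons > 1:
        cuts = np.sort(rng.choice(np.arange(3, len(cds) - 2), size=n_exons - 1,
                                  replace=False))
    else:
        cuts = np.array([], dtype=int)
    bounds = np.concatenate([[0], cuts, [len(cds)]])
    cds_parts = [cds[a:b] for a, b in zip(bounds[:-1], bounds[1:])]
    introns = [
        "GT" + _random_seq(rng, int(rng.integers(26, 120)), gc) + "AG"
        for _ in range(n_exons - 1)
    ]
    utr5 = _random_seq(rng, int(rng.integers(10, 60)), gc)
    utr3 = _random_seq(rng, int(rng.integers(10, 90)), gc)
    return {"utr5": utr5, "cds_parts": cds_parts, "introns": introns, "utr3": utr3}


def _pack_intervals(rng: np.random.Generator, chrom_len: int,
                    lengths: list[int], margin: int = 60) -> list[int]:
    """Place items of the given lengths without overlap, in random order
    with random gaps; returns start positions aligned with ``lengths``."""
    k = len(lengths)
    if k == 0:
        return []
    order = rng.permutation(k)
    needed = sum(lengths) + margin * (k + 1)
    if needed > chrom_len:
        raise ValidationError(
            f"cannot pack {k} features totalling {sum(lengths)} bases "
            f"(+margins) into a {chrom_len} base chromosome"
        )
    slack = chrom_len - needed
    gaps = rng.multinomial(slack, np.full(k + 1, 1 / (k + 1)))
    starts = [0] * k
    pos = 0
    for rank, idx in enumerate(order):
        pos += gaps[rank] + margin
        starts[idx] = pos
        pos += lengths[idx]
    return starts


def generate_reference(total_length: int, n_chroms: int = 1,
                       gc_content: float = 0.44, gene_density: float = 2.0,
                       repeat_density: float = 0.1, seed: int = 0,
                       ) -> tuple[ReferenceGenome, AnnotationSet]:
    """Generate a reference genome and annotation.

    ``gene_density`` is expected genes per 10 kb; ``repeat_density`` is
    the fraction of the genome covered by duplicated repeat elements
    (each repeat family appears at >= 2 identical copies, so flanking
    reads inside repeats are non-unique).  Genes have intact ORFs and
    canonical GT..AG introns.  Deterministic under ``seed``.
    """
    if total_length < 10_000:
        raise ValidationError("total_length must be >= 10 kb")
    rng = np.random.default_rng(seed)
    chrom_lens = [total_length // n_chroms] * n_chroms
    chrom_lens[-1] += total_length - sum(chrom_lens)
    chroms, feat_rows = [], []
    n_genes_total = int(round(gene_density * total_length / 10_000))
    genes_per_chrom = rng.multinomial(
        n_genes_total, np.asarray(chrom_lens) / total_length
    )
    gene_counter = 0
    n_families = max(3, n_genes_total // 3)
    for ci, clen in enumerate(chrom_lens):
        cname = f"chr{ci + 1}"
        seq = bytearray(_random_seq(rng, clen, gc_content).encode())
        items = []  # (kind, payload, length)
        for _ in range(int(genes_per_chrom[ci])):
            g = _make_gene(rng, gc_content)
            glen = (
                len(g["utr5"]) + sum(len(p) for p in g["cds_parts"])
                + sum(len(i) for i in g["introns"]) + len(g["utr3"])
            )
            items.append(("gene", g, glen))
        repeat_quota = int(repeat_density * clen)
        placed = 0
        while placed < repeat_quota:
            unit = _random_seq(rng, int(rng.integers(200, 500)), gc_content)
            copies = int(rng.integers(2, 4))
            fam = f"rep{ci}_{len(items)}"
            for _ in range(copies):
                items.append(("repeat", (fam, unit), len(unit)))
                placed += len(unit)
        starts = _pack_intervals(rng, clen, [l for _, _, l in items])
        for (kind, payload, length), start in zip(items, starts):
            if kind == "repeat":
                fam, unit = payload
                seq[start:start + length] = unit.encode()
                feat_rows.append((cname, start, start + length, "+", "repeat",
                                  -1, "", fam))
                continue
            g = payload
            strand = str(rng.choice(["+", "-"]))
            gene_counter += 1
            gid = f"g{gene_counter:04d}"
            fam = f"FAM{int(rng.integers(n_families)):03d}"
            # assemble forward-oriented gene sequence and local layout
            segs = []  # (local_start, local_end, label, cds_index)
            cursor = 0
            gene_seq_parts = []

            def push(s: str, label: str, idx: int = -1):
                nonlocal cursor
                segs.append((cursor, cursor + len(s), label, idx))
                gene_seq_parts.append(s)
                cursor += len(s)

            push(g["utr5"], "UTR")
            for k, part in enumerate(g["cds_parts"]):
                push(part, "CDS", k)
                if k < len(g["introns"]):
                    push(g["introns"][k], "intron")
            push(g["utr3"], "UTR")
            gene_seq = "".join(gene_seq_parts)
            if strand == "-":
                gene_seq = revcomp(gene_seq)
            seq[start:start + length] = gene_seq.encode()

            def to_genomic(a: int, b: int) -> tuple[int, int]:
                if strand == "+":
                    return start + a, start + b
                return start + length - b, start + length - a

            feat_rows.append((cname, start, start + length, strand, "gene",
                              -1, gid, fam))
            # exon features: maximal runs of UTR/CDS between introns
            run_start = None
            for a, b, label, _ in segs + [(cursor, cursor, "intron", -1)]:
                if label == "intron":
                    if run_start is not None:
                        ga, gb = to_genomic(run_start, a)
                        feat_rows.append((cname, ga, gb, strand, "exon", -1,
                                          gid, fam))
                        run_start = None
                    if b > a:
                        ga, gb = to_genomic(a, b)
                        feat_rows.append((cname, ga, gb, strand, "intron", -1,
                                          gid, fam))
                elif run_start is None:
                    run_start = a
            cum = 0
            for a, b, label, idx in segs:
                if label == "CDS":
                    phase = (3 - cum % 3) % 3
                    ga, gb = to_genomic(a, b)
                    feat_rows.append((cname, ga, gb, strand, "CDS", phase,
                                      gid, fam))
                    cum += b - a
                elif label == "UTR":
                    ga, gb = to_genomic(a, b)
                    feat_rows.append((cname, ga, gb, strand, "UTR", -1,
                                      gid, fam))
        chroms.append((cname, seq.decode()))
    ann = AnnotationSet(pd.DataFrame(
        feat_rows,
        columns=["chrom", "start", "end", "strand", "ftype", "phase",
                 "gene_id", "family_id"],
    ))
    genome = ReferenceGenome(chroms)
    ann.validate_against(genome)
    return genome, ann


# ------------------------------------------------------- variant panel


def calibrate_sharing(config: PanelConfig) -> tuple[float, float, np.ndarray]:
    """Solve for (p_in, p_out) and group-selection weights hitting the
    similarity targets.

    The discordance between two accessions at one variant is a mixture
    over which group sourced the variant.  Within-group and cross-group
    target discordances (1 - s) give moment equations; the carrier
    probabilities and the per-group selection weights (a simplex) are
    fitted jointly by bounded least squares, since fixed
    size-proportional weights cannot reach low cross-group similarity
    between small groups.
    """
    G = len(config.groups)

    def unpack(x):
        p_in, p_out = x[0], x[1]
        u = np.asarray(x[2:])
        u = u / u.sum()
        return p_in, p_out, u

    def residuals(x):
        p_in, p_out, u = unpack(x)
        a = 2 * p_in * (1 - p_in)
        b = 2 * p_out * (1 - p_out)
        c = p_in * (1 - p_out) + p_out * (1 - p_in)
        res = []
        for gi, (members, s_in) in enumerate(config.groups):
            if len(members) >= 2:
                res.append(u[gi] * a + (1 - u[gi]) * b - (1 - s_in))
        for gi in range(G):
            for gj in range(gi + 1, G):
                res.append(
                    (u[gi] + u[gj]) * c + (1 - u[gi] - u[gj]) * b
                    - (1 - config.s_out)
                )
        return np.asarray(res)

    x0 = np.concatenate([[0.9, 0.05], np.full(G, 1.0 / G)])
    sol = least_squares(
        residuals, x0=x0,
        bounds=(np.concatenate([[1e-4, 1e-4], np.full(G, 0.01)]),
                np.concatenate([[1 - 1e-4, 1 - 1e-4], np.full(G, 1.0)])),
    )
    p_in, p_out, u = unpack(sol.x)
    return float(p_in), float(p_out), u


def _cds_mask(genome: ReferenceGenome, annotation: AnnotationSet) -> dict[str, np.ndarray]:
    masks = {c: np.zeros(l, dtype=bool) for c, l in genome.lengths().items()}
    for f in annotation.of_type("CDS").itertuples(index=False):
        masks[f.chrom][f.start:f.end] = True
    return masks


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def generate_panel_variants(genome: ReferenceGenome, annotation: AnnotationSet,
                            config: PanelConfig) -> GenotypeMatrix:
    """Draw the truth variant panel.

    SNP and indel loci are placed uniformly (indels with a spacing
    buffer so footprints never overlap); alleles follow the configured
    transition bias and indel length weights (frame-preserving lengths
    reweighted inside CDS); carrier patterns follow the group sharing
    model; residual heterozygosity is applied to SNP loci at
    ``het_rate`` per cell.
    """
    rng = np.random.default_rng(config.seed)
    p_in, p_out, gw = calibrate_sharing(config)
    cds_masks = _cds_mask(genome, annotation)
    accs = config.accessions
    n = len(accs)
    group_of = {}
    for gi, (members, _) in enumerate(config.groups):
        for m in members:
            group_of[m] = gi
    group_idx = np.array([group_of[a] for a in accs])

    lengths = sorted(config.indel_length_weights)
    base_w = np.array([config.indel_length_weights[l] for l in lengths])
    cds_w = base_w * np.where(np.array(lengths) % 3 == 0,
                              config.exon_frame_bias, 1.0)
    cds_w = cds_w / cds_w.sum()

    rows, patterns = [], []
    for chrom, seq in genome.chromosomes:
        clen = len(seq)
        kb = clen / 1000.0
        n_snp = int(round(config.snp_density * kb))
        n_indel = int(round(config.indel_density * kb))
        # SNP and indel counts share one block-level intensity field, so
        # indel density tracks SNP density along the chromosome; indels
        # within a block sit on a jittered grid so footprints (anchor +
        # up to 13 deleted bases) never overlap
        block = 2000
        n_blocks = max(1, clen // block)
        bounds = np.linspace(0, clen, n_blocks + 1).astype(int)
        blens = np.diff(bounds)
        intensity = (rng.gamma(2.0, 1.0, n_blocks) + 0.2) * blens
        w = intensity / intensity.sum()
        caps = blens // 16
        if caps.sum() < n_indel:
            raise ValidationError("cannot place requested indel density")
        alloc = rng.multinomial(n_indel, w)
        # clip to per-block capacity, pushing any excess to open blocks
        for _ in range(100):
            excess = int(np.maximum(alloc - caps, 0).sum())
            alloc = np.minimum(alloc, caps)
            if excess == 0:
                break
            room = caps - alloc
            open_w = np.where(room > 0, w, 0.0)
            alloc = alloc + rng.multinomial(excess, open_w / open_w.sum())
        taken = np.zeros(clen, dtype=bool)
        indel_pos: list[int] = []
        for b, k in enumerate(alloc):
            if k == 0:
                continue
            stride = blens[b] // k
            jitter = rng.integers(0, max(stride - 14, 1), size=k)
            for i, j in enumerate(jitter):
                p = int(bounds[b] + i * stride + j)
                if p < clen - 15:
                    indel_pos.append(p)
                    taken[p:p + 14] = True
        snp_alloc = rng.multinomial(n_snp, w)
        snp_pos = []
        for b, k in enumerate(snp_alloc):
            free = np.flatnonzero(~taken[bounds[b]:bounds[b + 1]]) + bounds[b]
            if len(free) < k:
                raise ValidationError("cannot place requested SNP density")
            snp_pos.extend(rng.choice(free, size=k, replace=False).tolist())

        for p in sorted(snp_pos):
            ref = seq[p]
            if rng.random() < config.transition_prob:
                alt = _TRANSITION[ref]
            else:
                alt = _TRANSVERSIONS[ref][int(rng.integers(2))]
            rows.append((chrom, int(p), ref, alt, "SNP"))
        for p in sorted(indel_pos):
            in_cds = bool(cds_masks[chrom][p])
            l = int(rng.choice(lengths, p=cds_w if in_cds else base_w))
            anchor = seq[p]
            if rng.random() < 0.5 and p + 1 + l <= clen:
                rows.append((chrom, int(p), seq[p:p + 1 + l], anchor, "deletion"))
            else:
                ins = _random_seq(rng, l, 0.5)
                rows.append((chrom, int(p), anchor, anchor + ins, "insertion"))

    loci = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "vtype"])
    loci = loci.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    m = len(loci)
    codes = np.empty((m, n), dtype=np.int8)
    for i in range(m):
        while True:
            g = int(rng.choice(len(gw), p=gw))
            p_acc = np.where(group_idx == g, p_in, p_out)
            carriers = rng.random(n) < p_acc
            if carriers.any():
                break
        codes[i] = np.where(carriers, ALT_HOM, REF_HOM)
    # residual heterozygosity at SNP loci
    if config.het_rate > 0:
        snp_rows = (loci["vtype"] == "SNP").to_numpy()
        flip = (rng.random(codes.shape) < config.het_rate) & snp_rows[:, None]
        codes[flip] = HET
    matrix = GenotypeMatrix(loci, list(accs), codes)
    matrix.check_truth()
    return matrix


# ----------------------------------------------------------- sequencing


def apply_variants(seq: str, variants: pd.DataFrame):
    """Apply a set of variant alleles (rows: pos, ref, alt, vtype) to one
    chromosome sequence.

    Returns (new_seq, blocks) where blocks is an ndarray of
    (acc_start, acc_end, ref_start, is_insert) rows mapping accession
    coordinates back to reference coordinates (positions inside an
    insertion map to the insertion anchor).
    """
    snps = variants[variants["vtype"] == "SNP"]
    buf = bytearray(seq.encode())
    for row in snps.itertuples(index=False):
        assert seq[row.pos] == row.ref, "SNP ref mismatch"
        buf[row.pos] = ord(row.alt)
    indels = variants[variants["vtype"] != "SNP"].sort_values("pos")
    pieces, blocks = [], []
    cur_ref, acc_len = 0, 0

    def push(piece: bytes, ref_start: int, is_insert: bool):
        nonlocal acc_len
        if not piece:
            return
        pieces.append(piece)
        blocks.append((acc_len, acc_len + len(piece), ref_start, is_insert))
        acc_len += len(piece)

    for row in indels.itertuples(index=False):
        push(bytes(buf[cur_ref:row.pos + 1]), cur_ref, False)
        if row.vtype == "insertion":
            push(row.alt[1:].encode(), row.pos, True)
            cur_ref = row.pos + 1
        else:  # deletion
            cur_ref = row.pos + len(row.ref)
    push(bytes(buf[cur_ref:]), cur_ref, False)
    return b"".join(pieces).decode(), np.asarray(blocks, dtype=np.int64)


def _map_to_ref(blocks: np.ndarray, acc_pos: int) -> int:
    i = int(np.searchsorted(blocks[:, 0], acc_pos, side="right")) - 1
    a0, _a1, r0, is_ins = blocks[i]
    return int(r0) if is_ins else int(r0 + (acc_pos - a0))


def _neighborhood_candidates(seq: str, enzyme: Enzyme) -> pd.DataFrame:
    """Positions whose window violates the motif at exactly one position.

    Returns columns (start, swap) where swap marks windows matching the
    motif with its degenerate codes complemented in place (for RCCGGY
    this is the YCCGGR star-activity pattern the enzyme favors).
    """
    motif = enzyme.motif.upper()
    m = len(motif)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n_win = len(arr) - m + 1
    if n_win <= 0:
        return pd.DataFrame(columns=["start", "swap"])
    ok = np.zeros((m, n_win), dtype=bool)
    for i, code in enumerate(motif):
        allowed = np.frombuffer(IUPAC[code].encode(), dtype=np.uint8)
        ok[i] = np.isin(arr[i:i + n_win], allowed)
    viol = m - ok.sum(axis=0)
    cand = np.flatnonzero(viol == 1)
    swap_motif = "".join(
        c if c in "ACGT" else revcomp(c) for c in motif
    )
    ok2 = np.zeros((m, n_win), dtype=bool)
    for i, code in enumerate(swap_motif):
        allowed = np.frombuffer(IUPAC[code].encode(), dtype=np.uint8)
        ok2[i] = np.isin(arr[i:i + n_win], allowed)
    is_swap = ok2.all(axis=0)
    return pd.DataFrame({"start": cand, "swap": is_swap[cand]})


def _draw_qualities(rng, n, mean_q, sd_q):
    q = np.rint(rng.normal(mean_q, sd_q, size=n)).astype(np.int16)
    return np.clip(q, 2, 41)


def _inject_errors(rng, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(len(arr)) < error_rate)
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_reads(genome: ReferenceGenome, truth: GenotypeMatrix,
                   library: LibraryConfig, accession: str,
                   seed: Optional[int] = None) -> ReadSet:
    """Simulate one accession's reads for one library.

    RAD canonical (cRS) reads start exactly at the enzyme's cut
    positions on the accession's haplotype, in both orientations, at
    negative-binomial depth; noncanonical (ncRS) reads start at
    one-substitution motif neighborhoods, with the complement-swap
    pattern receiving 27% of the ncRS mass; SR reads start uniformly
    within size-selected HpaII fragments.  Reads carry the accession's
    variant alleles, phred qualities with mean ~ ``mean_quality`` and
    substitution errors at ``error_rate``.  ``truth_origin`` is the
    reference coordinate of the read's leftmost aligned base.
    """
    if seed is None:
        acc_idx = truth.accessions.index(accession)
        seed_key = [library.seed, acc_idx]
    else:
        seed_key = [seed]
    rng = np.random.default_rng(seed_key)
    L = library.read_length
    acc_col = truth.accessions.index(accession)
    reads: list[Read] = []
    counter = 0

    for chrom, seq in genome.chromosomes:
        if L > len(seq):
            raise ValidationError("read_length exceeds chromosome length")
        sub = truth.loci["chrom"] == chrom
        vloci = truth.loci[sub].copy()
        vcodes = truth.codes[sub.to_numpy(), acc_col]
        hom_rows = vcodes == ALT_HOM
        het_rows = vcodes == HET
        acc_seq, blocks = apply_variants(seq, vloci[hom_rows])
        # het haplotype: het SNP alt bases layered on the homozygous sequence
        het_snps = vloci[het_rows & (vloci["vtype"] == "SNP").to_numpy()]
        het_buf = bytearray(acc_seq.encode())
        ref_starts_noins = blocks[blocks[:, 3] == 0]
        for row in het_snps.itertuples(index=False):
            # map reference pos -> accession pos (inverse of block map)
            i = np.searchsorted(ref_starts_noins[:, 2], row.pos, side="right") - 1
            a0, a1, r0, _ = ref_starts_noins[i]
            ap = a0 + (row.pos - r0)
            if ap < a1 and het_buf[ap] == ord(row.ref):
                het_buf[ap] = ord(row.alt)
        het_seq = het_buf.decode()
        has_het = len(het_snps) > 0

        def emit(acc_start: int, strand: str, origin_class: str):
            nonlocal counter
            hap = het_seq if (has_het and rng.random() < 0.5) else acc_seq
            raw = hap[acc_start:acc_start + L]
            if strand == "-":
                raw = revcomp(raw)
            raw = _inject_errors(rng, raw, library.error_rate)
            origin = (chrom, _map_to_ref(blocks, acc_start), strand)
            counter += 1
            reads.append(Read(
                id=f"{accession}_{library.lib_type}_{counter:07d}",
                accession=accession,
                sequence=raw,
                qualities=_draw_qualities(rng, L, library.mean_quality,
                                          library.sd_quality),
                truth_origin=origin,
                origin_class=origin_class,
            ))

        if library.lib_type == "SR":
            from .digest import find_sites, fragment_table
            acc_genome = ReferenceGenome([(chrom, acc_seq)])
            digest = fragment_table(find_sites(acc_genome, HPAII), acc_genome)
            frags = digest.fragments
            lo, hi = library.size_range
            eligible = frags[(frags["length"] >= max(lo, L)) &
                             (frags["length"] <= hi)]
            if len(eligible):
                weights = (eligible["length"] - L + 1).to_numpy(dtype=float)
                weights /= weights.sum()
                n_reads = library.reads_per_accession
                picks = rng.choice(len(eligible), size=n_reads, p=weights)
                starts = eligible["start"].to_numpy()
                lens = eligible["length"].to_numpy()
                for k in picks:
                    s = int(starts[k] + rng.integers(lens[k] - L + 1))
                    emit(s, "+" if rng.random() < 0.5 else "-", "SR")
            continue

        # RAD library
        from .digest import find_sites
        acc_genome = ReferenceGenome([(chrom, acc_seq)])
        cuts = find_sites(acc_genome, library.enzyme).cut_positions(chrom)
        if library.site_dropout > 0:
            cuts = cuts[rng.random(len(cuts)) >= library.site_dropout]
        k = library.depth_dispersion
        mdepth = library.mean_site_depth

        def depth():
            if k >= 1e6:
                return int(rng.poisson(mdepth))
            return int(rng.negative_binomial(k, k / (k + mdepth)))

        n_crs = 0
        for cut in cuts:
            d = depth()
            for _ in range(d):
                if cut + L <= len(acc_seq):
                    emit(int(cut), "+", "cRS")
                    n_crs += 1
            d = depth()
            for _ in range(d):
                if cut - L >= 0:
                    emit(int(cut - L), "-", "cRS")
                    n_crs += 1
        f = library.ncrs_fraction
        if f > 0 and n_crs > 0:
            n_ncrs = int(round(n_crs * f / (1 - f)))
            cand = _neighborhood_candidates(acc_seq, library.enzyme)
            if len(cand):
                w = np.ones(len(cand), dtype=float)
                n_swap = int(cand["swap"].sum())
                n_other = len(cand) - n_swap
                if n_swap and n_other:
                    w[cand["swap"].to_numpy()] = (
                        0.27 / 0.73 * n_other / n_swap
                    )
                w /= w.sum()
                m = len(library.enzyme.motif)
                offs = library.enzyme.cut_offset
                starts_arr = cand["start"].to_numpy()
                emitted = tries = 0
                while emitted < n_ncrs and tries < 10 * n_ncrs + 100:
                    tries += 1
                    s = int(starts_arr[rng.choice(len(cand), p=w)])
                    if rng.random() < 0.5:
                        if s + offs + L <= len(acc_seq):
                            emit(s + offs, "+", "ncRS")
                            emitted += 1
                    else:
                        pos = s + m - offs
                        if pos - L >= 0:
                            emit(pos - L, "-", "ncRS")
                            emitted += 1
    return ReadSet(reads)
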