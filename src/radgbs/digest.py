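"""In-silico restriction digestion.

Site discovery scans both strands with the enzyme's IUPAC-degenerate
motif (overlapping matches included), tabulates fragment sizes, tests
whether the reads flanking each cut site would align uniquely, and
computes site-coverage saturation curves for read sets.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import IUPAC, Enzyme, ReadSet, ReferenceGenome, revcomp

__all__ = [
    "DigestResult",
    "iupac_regex",
    "find_sites",
    "find_sites_brute",
    "fragment_table",
    "site_read_uniqueness",
    "coverage_saturation",
]


def iupac_regex(motif: str) -> re.Pattern:
    """Compile an IUPAC motif into a regex character-class pattern."""
    return re.compile("".join(f"[{IUPAC[c]}]" for c in motif.upper()))


@dataclass
class DigestResult:
    """Restriction sites and fragments for one enzyme on one genome.

    ``sites`` has columns chrom, match_start, strand, cut_pos; cut
    positions are 0-based top-strand coordinates.  ``fragments`` tile
    each chromosome exactly.
    """

    enzyme: Enzyme
    sites: pd.DataFrame
    fragments: pd.DataFrame = field(default_factory=pd.DataFrame)
    uniqueness: pd.DataFrame = field(default_factory=pd.DataFrame)

    def cut_positions(self, chrom: str) -> np.ndarray:
        sub = self.sites[self.sites["chrom"] == chrom]
        return np.unique(sub["cut_pos"].to_numpy())


def _scan(seq: str, pattern: re.Pattern) -> list[int]:
    """All (overlapping) match start positions of pattern in seq."""
    out, pos = [], 0
    while True:
        m = pattern.search(seq, pos)
        if m is None:
            return out
        out.append(m.start())
        pos = m.start() + 1


def find_sites(genome: ReferenceGenome, enzyme: Enzyme) -> DigestResult:
    """Find every recognition-site match on either strand.

    A match of the motif on the top strand is recorded with strand '+'
    and cut position ``start + cut_offset``; a match of the motif's
    reverse complement (i.e. a bottom-strand recognition) is recorded
    with strand '-' and top-strand cut position
    ``start + len(motif) - cut_offset``.  For palindromic motifs the two
    scans find the same intervals and are deduplicated.
    """
    motif = enzyme.motif.upper()
    fwd = iupac_regex(motif)
    m = len(motif)
    rows = []
    for chrom, seq in genome.chromosomes:
        starts = _scan(seq, fwd)
        for s in starts:
            rows.append((chrom, s, "+", s + enzyme.cut_offset))
        if not enzyme.is_palindromic:
            rev = iupac_regex(revcomp(motif))
            for s in _scan(seq, rev):
                rows.append((chrom, s, "-", s + m - enzyme.cut_offset))
    sites = pd.DataFrame(rows, columns=["chrom", "match_start", "strand", "cut_pos"])
    sites = sites.sort_values(["chrom", "match_start", "strand"]).reset_index(drop=True)
    return DigestResult(enzyme=enzyme, sites=sites)


def find_sites_brute(genome: ReferenceGenome, enzyme: Enzyme) -> pd.DataFrame:
    """Brute-force position-by-position IUPAC scan (test oracle)."""
    motif = enzyme.motif.upper()
    rc = revcomp(motif)
    m = len(motif)
    rows = []
    for chrom, seq in genome.chromosomes:
        for s in range(len(seq) - m + 1):
            window = seq[s:s + m]
            if all(b in IUPAC[c] for b, c in zip(window, motif)):
                rows.append((chrom, s, "+", s + enzyme.cut_offset))
            if not enzyme.is_palindromic and all(
                b in IUPAC[c] for b, c in zip(window, rc)
            ):
                rows.append((chrom, s, "-", s + m - enzyme.cut_offset))
    df = pd.DataFrame(rows, columns=["chrom", "match_start", "strand", "cut_pos"])
    return df.sort_values(["chrom", "match_start", "strand"]).reset_index(drop=True)


def fragment_table(digest: DigestResult, genome: ReferenceGenome) -> DigestResult:
    """Tabulate the fragments produced by cutting at every site.

    Per chromosome with k distinct cut positions there are k+1 fragments
    which tile the chromosome; lengths sum to the chromosome length.
    """
    rows = []
    for chrom, seq in genome.chromosomes:
        cuts = digest.cut_positions(chrom)
        cuts = cuts[(cuts > 0) & (cuts < len(seq))]
        bounds = np.concatenate([[0], cuts, [len(seq)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            rows.append((chrom, int(a), int(b)))
    digest.fragments = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    digest.fragments["length"] = digest.fragments["end"] - digest.fragments["start"]
    return digest


def _occurrences(haystacks: list[str], needle: str) -> int:
    """Count exact (overlapping) occurrences of needle over all haystacks."""
    n = 0
    for hay in haystacks:
        pos = hay.find(needle)
        while pos != -1:
            n += 1
            pos = hay.find(needle, pos + 1)
    return n


def site_read_uniqueness(genome: ReferenceGenome, enzyme: Enzyme,
                         read_length: int) -> pd.DataFrame:
    """For each cut site, test whether its two flanking reads are unique.

    The rightward read is the top-strand sequence starting at the cut;
    the leftward read is the bottom-strand sequence ending at the cut.
    A read is unique iff its sequence occurs exactly once in the genome
    counting both strands.  Reads running off the chromosome end are
    non-extractable and reported as such (unique = NA).
    """
    if read_length < 20:
        raise ValueError("read_length must be >= 20")
    digest = find_sites(genome, enzyme)
    texts = [seq for _, seq in genome.chromosomes]
    texts += [revcomp(seq) for _, seq in genome.chromosomes]
    rows = []
    for chrom, seq in genome.chromosomes:
        for cut in digest.cut_positions(chrom):
            for direction in ("right", "left"):
                if direction == "right":
                    ok = cut + read_length <= len(seq)
                    read = seq[cut:cut + read_length] if ok else None
                else:
                    ok = cut - read_length >= 0
                    read = revcomp(seq[cut - read_length:cut]) if ok else None
                unique = (_occurrences(texts, read) == 1) if ok else None
                rows.append((chrom, int(cut), direction, ok, unique))
    df = pd.DataFrame(
        rows, columns=["chrom", "cut_pos", "direction", "extractable", "unique"]
    )
    extract = df[df["extractable"]]
    df.attrs["unique_fraction"] = (
        float(extract["unique"].mean()) if len(extract) else float("nan")
    )
    df.attrs["n_non_extractable"] = int((~df["extractable"]).sum())
    return df


def coverage_saturation(readset: ReadSet, depth_thresholds: tuple[int, ...],
                        seed: int, n_points: int = 20) -> pd.DataFrame:
    """Distinct sites covered at depth >= d versus number of reads sampled.

    Reads are matched to sites by start-coordinate equality: a read on
    the '+' strand starts at its site's cut position, a '-' read ends
    there, so both directions of one cut collapse to the same site key.
    Reads are shuffled under the given seed and the curve is evaluated
    at ``n_points`` evenly spaced sample sizes.  Returns a table
    (reads_sampled, threshold, distinct_sites) that is monotone
    non-decreasing in reads_sampled for each threshold.
    """
    rng = np.random.default_rng(seed)
    key_index: dict[tuple, int] = {}
    idx_list = []
    for r in readset:
        if r.truth_origin is None:
            continue
        chrom, pos, strand = r.truth_origin
        site = (chrom, pos if strand == "+" else pos + len(r.sequence))
        idx_list.append(key_index.setdefault(site, len(key_index)))
    if not idx_list:
        return pd.DataFrame(columns=["reads_sampled", "threshold", "distinct_sites"])
    idx = np.asarray(idx_list)
    rng.shuffle(idx)
    checkpoints = np.unique(
        np.linspace(0, len(idx), n_points + 1).round().astype(int)[1:]
    )
    rows = []
    counts = np.zeros(len(key_index), dtype=np.int64)
    prev = 0
    for n in checkpoints:
        np.add.at(counts, idx[prev:n], 1)
        prev = n
        for d in depth_thresholds:
            rows.append((int(n), int(d), int((counts >= d).sum())))
    return pd.DataFrame(rows, columns=["reads_sampled", "threshold", "distinct_sites"])
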