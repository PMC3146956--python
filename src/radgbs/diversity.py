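"""Panel-level diversity statistics.

Pairwise genomic similarity is the sum over the N loci genotyped in
both accessions of the per-locus allele identity (0..2, disregarding
linkage phase), divided by 2N; pairwise SNP density is the sum of
allele differences divided by the number of bases sequenced in common
(B, twice the number of base pairs).  The site-frequency spectrum is
binned by alternative-allele (unfolded) or minor-allele (folded)
accession counts, with the folded expectation from the neutral
infinite-sites model: bin i proportional to (1/i + 1/(n-i)) /
(1 + [i = n-i]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ALT_HOM, HET, MISSING, REF_HOM, CoverageMap, GenotypeMatrix

__all__ = [
    "SimilarityMatrix",
    "pairwise_similarity",
    "pairwise_snp_density",
    "accession_coverage_spectrum",
    "SfsResult",
    "expected_folded_sfs",
    "sfs",
    "alt_allele_sharing_profile",
    "haplotype_sharing_windows",
]


@dataclass
class SimilarityMatrix:
    accessions: list[str]
    n_shared: np.ndarray     # loci genotyped in both members of the pair
    identity_sum: np.ndarray
    similarity: np.ndarray   # identity_sum / (2 n_shared); nan if undefined
    differences: np.ndarray  # S: sum of allele differences

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.similarity, index=self.accessions,
                            columns=self.accessions)

    def mean_pairwise(self, members: list[str] | None = None) -> float:
        idx = (
            [self.accessions.index(a) for a in members]
            if members is not None else range(len(self.accessions))
        )
        vals = [
            self.similarity[i, j]
            for k, i in enumerate(idx) for j in list(idx)[k + 1:]
        ]
        return float(np.nanmean(vals)) if vals else float("nan")


def pairwise_similarity(matrix: GenotypeMatrix,
                        include_reference: bool = False) -> SimilarityMatrix:
    """All-pairs similarity.

    Per locus, identity = 2 - |g_i - g_j| with codes REF_HOM=0, HET=1,
    ALT_HOM=2 (same hom/same hom 2, opposite homs 0, hom/het 1, het/het
    2); loci missing in either accession are excluded from that pair.
    ``include_reference`` appends a virtual all-REF_HOM reference row.
    """
    codes = matrix.codes.astype(np.int16)
    accs = list(matrix.accessions)
    if include_reference:
        codes = np.hstack([np.zeros((codes.shape[0], 1), dtype=np.int16), codes])
        accs = ["REF"] + accs
    n = len(accs)
    present = codes != MISSING
    n_shared = present.T.astype(np.int64) @ present.astype(np.int64)
    ident = np.zeros((n, n), dtype=np.float64)
    diffs = np.zeros((n, n), dtype=np.float64)
    for i in range(n):
        for j in range(i, n):
            both = present[:, i] & present[:, j]
            d = np.abs(codes[both, i] - codes[both, j]).sum()
            diffs[i, j] = diffs[j, i] = d
            ident[i, j] = ident[j, i] = 2 * both.sum() - d
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(n_shared > 0, ident / (2 * n_shared), np.nan)
    return SimilarityMatrix(accs, n_shared, ident, sim, diffs)


def pairwise_snp_density(matrix: GenotypeMatrix,
                         coverage: CoverageMap) -> pd.DataFrame:
    """SNP density S_ij / B_ij per accession pair (differences per base).

    Only loci genotyped in both pair members contribute to S; pairs with
    B = 0 are undefined (NaN).
    """
    sim = pairwise_similarity(matrix)
    b = coverage.b_pair().loc[matrix.accessions, matrix.accessions].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        dens = np.where(b > 0, sim.differences / b, np.nan)
    return pd.DataFrame(dens, index=matrix.accessions, columns=matrix.accessions)


def accession_coverage_spectrum(presence: np.ndarray) -> np.ndarray:
    """Histogram over 1..n accessions of per-item presence flags.

    ``presence`` is a boolean items x accessions array (e.g. read start
    sites per accession, or SNPs covered per accession); items present
    in zero accessions are not binned.
    """
    presence = np.asarray(presence, dtype=bool)
    n = presence.shape[1]
    counts = presence.sum(axis=1)
    return np.bincount(counts[counts > 0], minlength=n + 1)[1:]


@dataclass
class SfsResult:
    unfolded: np.ndarray          # bins 1..n
    folded: np.ndarray            # bins 1..floor(n/2)
    expected_folded: np.ndarray   # proportions, bins 1..floor(n/2)
    n_excluded: int


def expected_folded_sfs(n: int) -> np.ndarray:
    """Neutral infinite-sites folded spectrum for n sequences.

    eta_i proportional to (1/i + 1/(n-i)) / (1 + [i = n-i]),
    normalized to sum to 1 over i = 1..floor(n/2).
    """
    i = np.arange(1, n // 2 + 1)
    raw = (1.0 / i + 1.0 / (n - i)) / (1.0 + (i == n - i))
    return raw / raw.sum()


def sfs(matrix: GenotypeMatrix, include_het_as_half: bool = False) -> SfsResult:
    """Site-frequency spectra of the panel's biallelic loci.

    The alternative-allele count of a locus is the number of accessions
    carrying the alternative allele homozygously (HET counts 0 by
    default — the panel is inbred and heterozygotes are rare — or 0.5,
    rounded to nearest, under ``include_het_as_half``).  Loci with
    count 0 or all-missing are excluded and counted in ``n_excluded``.
    """
    n = matrix.n_accessions
    alt = (matrix.codes == ALT_HOM).sum(axis=1).astype(float)
    if include_het_as_half:
        alt = alt + 0.5 * (matrix.codes == HET).sum(axis=1)
    counts = np.rint(alt).astype(int)
    keep = counts > 0
    unfolded = np.bincount(counts[keep], minlength=n + 1)[1:]
    folded = np.zeros(n // 2, dtype=np.int64)
    for i in range(1, n + 1):
        f = min(i, n - i)
        if f >= 1:
            folded[f - 1] += unfolded[i - 1]
    # alt in all n accessions has minor count 0; tracked as excluded too
    n_excluded = int((~keep).sum()) + int(unfolded[n - 1])
    return SfsResult(unfolded, folded, expected_folded_sfs(n), n_excluded)


def alt_allele_sharing_profile(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per accession: SNP counts at each panel alternative-allele
    frequency in which that accession carries the alternative allele.

    Rows are accessions, columns frequencies 1..n.
    """
    n = matrix.n_accessions
    alt = matrix.codes == ALT_HOM
    freq = alt.sum(axis=1)
    prof = np.zeros((n, n), dtype=np.int64)
    for f in range(1, n + 1):
        at_f = alt[freq == f]
        prof[:, f - 1] = at_f.sum(axis=0)
    return pd.DataFrame(prof, index=matrix.accessions,
                        columns=np.arange(1, n + 1))


def haplotype_sharing_windows(matrix: GenotypeMatrix, window_snps: int = 50,
                              thresholds: tuple[float, ...] = (0.3, 0.5, 0.7),
                              match_class: str = "ref_hom") -> pd.DataFrame:
    """Shared-genotype fractions in consecutive windows of loci.

    Windows are non-overlapping runs of ``window_snps`` loci per
    chromosome (final partial window kept and flagged).  The shared
    fraction of a pair is the proportion of window loci at which both
    accessions carry the match-class genotype (REF_HOM or ALT_HOM);
    tier is the highest threshold met, else NaN.
    """
    if window_snps < 1:
        raise ValueError("window_snps must be >= 1")
    target = {"ref_hom": REF_HOM, "alt_hom": ALT_HOM}[match_class]
    hits = matrix.codes == target
    accs = matrix.accessions
    thresholds = sorted(thresholds)
    rows = []
    chrom_arr = matrix.loci["chrom"].to_numpy()
    for chrom in pd.unique(chrom_arr):
        idx = np.flatnonzero(chrom_arr == chrom)
        for w0 in range(0, len(idx), window_snps):
            win = idx[w0:w0 + window_snps]
            partial = len(win) < window_snps
            for i in range(len(accs)):
                for j in range(i + 1, len(accs)):
                    shared = int((hits[win, i] & hits[win, j]).sum())
                    frac = shared / window_snps
                    tier = max((t for t in thresholds if frac >= t),
                               default=float("nan"))
                    rows.append((chrom, w0 // window_snps, accs[i], accs[j],
                                 len(win), partial, frac, tier))
    return pd.DataFrame(rows, columns=[
        "chrom", "window", "acc_i", "acc_j", "n_loci", "partial",
        "shared_fraction", "tier",
    ])
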