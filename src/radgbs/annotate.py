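"""Variant annotation.

Assigns each variant to a single genomic feature class under the
precedence splice_site > CDS > UTR > intron > repeat > intergenic
(splice sites are the canonical first/last two bases of an intron),
classifies coding effects of SNPs through the spliced CDS and the
standard genetic code, and computes the summary statistics: Ts/Tv,
indel length-by-feature with the frame-preservation test, large-effect
SNP density per gene family, and sliding-window density tracks.

A large-effect SNP is a CDS or splice-site SNP expected to alter
protein structure: a sense<->nonsense codon shift or splicing
disruption.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from statsmodels.stats.proportion import proportions_ztest

from .model import AnnotationSet, CoverageMap, ReferenceGenome, ValidationError, revcomp

__all__ = [
    "FEATURE_CLASSES",
    "FeatureIndex",
    "EffectCall",
    "classify_feature",
    "coding_effect",
    "ts_tv",
    "indel_feature_stats",
    "large_effect_density_by_family",
    "window_density",
]

# painted priority codes; higher wins
FEATURE_CLASSES = ["intergenic", "repeat", "intron", "UTR", "CDS", "splice_site"]
_PRIORITY = {name: i for i, name in enumerate(FEATURE_CLASSES)}

LARGE_EFFECT = {"stop_gained", "stop_lost", "splice_disrupting"}


class FeatureIndex:
    """Per-chromosome feature-class paint with gene lookup."""

    def __init__(self, genome: ReferenceGenome, annotation: AnnotationSet):
        annotation.validate_against(genome)
        self.annotation = annotation
        self.cls = {c: np.zeros(l, dtype=np.uint8)
                    for c, l in genome.lengths().items()}
        self.gene_at = {c: np.full(l, -1, dtype=np.int32)
                        for c, l in genome.lengths().items()}
        genes = annotation.of_type("gene").reset_index(drop=True)
        self.genes = genes
        for gi, g in enumerate(genes.itertuples(index=False)):
            self.gene_at[g.chrom][g.start:g.end] = gi
        for name in ("repeat", "intron", "UTR", "CDS"):
            code = _PRIORITY[name]
            for f in annotation.of_type(name).itertuples(index=False):
                arr = self.cls[f.chrom]
                np.maximum(arr[f.start:f.end], code, out=arr[f.start:f.end])
        code = _PRIORITY["splice_site"]
        for f in annotation.of_type("intron").itertuples(index=False):
            arr = self.cls[f.chrom]
            arr[f.start:min(f.start + 2, f.end)] = code
            arr[max(f.end - 2, f.start):f.end] = code

    def classify(self, chrom: str, pos: int) -> str:
        if chrom not in self.cls or not (0 <= pos < len(self.cls[chrom])):
            raise ValidationError(f"locus {chrom}:{pos} outside the genome")
        return FEATURE_CLASSES[self.cls[chrom][pos]]

    def gene_id(self, chrom: str, pos: int) -> tuple[str, str]:
        gi = self.gene_at[chrom][pos]
        if gi < 0:
            return "", ""
        g = self.genes.iloc[int(gi)]
        return str(g["gene_id"]), str(g["family_id"])


def classify_feature(index: FeatureIndex, chrom: str, pos: int) -> str:
    """Feature class of a locus under the stated precedence."""
    return index.classify(chrom, pos)


@dataclass
class EffectCall:
    chrom: str
    pos: int
    ref: str
    alt: str
    feature_class: str
    coding_effect: str
    large_effect: bool
    gene_id: str = ""
    family_id: str = ""


def _spliced_cds(genome: ReferenceGenome, annotation: AnnotationSet,
                 gene_id: str) -> tuple[str, list, str]:
    """Spliced CDS in transcription order plus genomic segment layout."""
    segs = annotation.gene_cds(gene_id)
    if len(segs) == 0:
        raise ValidationError(f"gene {gene_id!r} has no CDS")
    strand = segs["strand"].iloc[0]
    seq = dict(genome.chromosomes)[segs["chrom"].iloc[0]]
    parts = [seq[s:e] for s, e in zip(segs["start"], segs["end"])]
    if strand == "-":
        cds = "".join(revcomp(p) for p in reversed(parts))
    else:
        cds = "".join(parts)
    if len(cds) % 3 != 0:
        raise ValidationError(f"CDS of {gene_id!r} not divisible by 3")
    return cds, list(segs.itertuples(index=False)), strand


def _cds_offset(segs: list, strand: str, pos: int) -> int:
    """Transcription-order offset of a genomic position within the CDS."""
    if strand == "+":
        off = 0
        for s in segs:
            if s.start <= pos < s.end:
                return off + (pos - s.start)
            off += s.end - s.start
    else:
        off = 0
        for s in reversed(segs):
            if s.start <= pos < s.end:
                return off + (s.end - 1 - pos)
            off += s.end - s.start
    raise ValidationError("position not inside any CDS segment of the gene")


def coding_effect(genome: ReferenceGenome, annotation: AnnotationSet,
                  index: FeatureIndex, chrom: str, pos: int,
                  ref: str, alt: str) -> EffectCall:
    """Classify a SNP's coding effect.

    Splice-site SNPs (first/last 2 intron bases) are splice_disrupting.
    CDS SNPs are classified by the codon change in the spliced CDS:
    sense->same aa synonymous, sense->different sense nonsynonymous,
    sense->stop stop_gained, stop->sense stop_lost.  Any other feature
    class yields not_applicable.
    """
    fclass = index.classify(chrom, pos)
    gene_id, family_id = index.gene_id(chrom, pos)
    if fclass == "splice_site":
        return EffectCall(chrom, pos, ref, alt, fclass, "splice_disrupting",
                          True, gene_id, family_id)
    if fclass != "CDS":
        return EffectCall(chrom, pos, ref, alt, fclass, "not_applicable",
                          False, gene_id, family_id)
    cds, segs, strand = _spliced_cds(genome, annotation, gene_id)
    off = _cds_offset(segs, strand, pos)
    ref_t = ref if strand == "+" else revcomp(ref)
    alt_t = alt if strand == "+" else revcomp(alt)
    if cds[off] != ref_t:
        raise ValidationError(
            f"reference allele mismatch at {chrom}:{pos} in {gene_id!r}"
        )
    ci = off // 3
    codon = cds[3 * ci:3 * ci + 3]
    alt_codon = codon[:off % 3] + alt_t + codon[off % 3 + 1:]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if aa_ref == "*" and aa_alt != "*":
        effect = "stop_lost"
    elif aa_ref != "*" and aa_alt == "*":
        effect = "stop_gained"
    elif aa_ref == aa_alt:
        effect = "synonymous"
    else:
        effect = "nonsynonymous"
    return EffectCall(chrom, pos, ref, alt, fclass, effect,
                      effect in LARGE_EFFECT, gene_id, family_id)


# ---------------------------------------------------------- statistics

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def ts_tv(snps: pd.DataFrame) -> float:
    """Transition/transversion ratio of a SNP table (ref, alt columns).

    Returns inf when there are no transversions; raises on empty input.
    """
    if len(snps) == 0:
        raise ValueError("empty SNP set")
    pairs = list(zip(snps["ref"], snps["alt"]))
    ts = sum(p in _TRANSITIONS for p in pairs)
    tv = len(pairs) - ts
    return ts / tv if tv else float("inf")


def indel_feature_stats(indels: pd.DataFrame, index: FeatureIndex) -> dict:
    """Indel lengths by feature class, frame-preservation fractions, and
    the two-proportion z-test of multiple-of-3 fraction CDS vs intergenic.

    ``indels`` columns: chrom, pos, ref, alt.  Length is the number of
    inserted/deleted bases.
    """
    df = indels.copy()
    df["length"] = (df["ref"].str.len() - df["alt"].str.len()).abs()
    df["feature_class"] = [
        index.classify(c, p) for c, p in zip(df["chrom"], df["pos"])
    ]
    df["frame_preserving"] = df["length"] % 3 == 0
    hist = (
        df.groupby(["feature_class", "length"]).size().rename("count").reset_index()
    )
    fractions = df.groupby("feature_class")["frame_preserving"].agg(["mean", "size"])
    out = {"table": df, "histograms": hist, "fractions": fractions}
    cds = df[df["feature_class"] == "CDS"]
    inter = df[df["feature_class"] == "intergenic"]
    if len(cds) and len(inter):
        z, p = proportions_ztest(
            [cds["frame_preserving"].sum(), inter["frame_preserving"].sum()],
            [len(cds), len(inter)],
        )
        out["z"] = float(z)
        out["p_value"] = float(p)
    else:
        out["z"] = out["p_value"] = float("nan")
    return out


def _union_length_covered(intervals: list[tuple[int, int]],
                          covered: np.ndarray) -> int:
    merged = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(e, merged[-1][1]))
        else:
            merged.append((s, e))
    return int(sum(covered[s:e].sum() for s, e in merged))


def large_effect_density_by_family(effects: list[EffectCall],
                                   annotation: AnnotationSet,
                                   coverage: CoverageMap,
                                   min_covered: int = 100_000) -> pd.DataFrame:
    """Large-effect SNP density per gene family.

    Only families whose genic regions have strictly more than
    ``min_covered`` bases covered by reads (any accession) are
    retained; density is large-effect SNPs per covered kilobase,
    sorted descending.
    """
    pooled = {}
    for chrom, l in coverage.chrom_lengths.items():
        cov = np.zeros(l, dtype=bool)
        for a in coverage.accessions:
            cov |= coverage.covered(a, chrom)
        pooled[chrom] = cov
    genes = annotation.of_type("gene")
    rows = []
    for fam, grp in genes.groupby("family_id"):
        if not fam:
            continue
        covered = sum(
            _union_length_covered(
                [(s, e) for s, e in zip(sub["start"], sub["end"])],
                pooled[chrom],
            )
            for chrom, sub in grp.groupby("chrom")
        )
        if covered <= min_covered:
            continue
        n_le = sum(1 for e in effects if e.large_effect and e.family_id == fam)
        rows.append((fam, len(grp), covered, n_le, n_le / (covered / 1000)))
    df = pd.DataFrame(rows, columns=["family_id", "n_genes", "covered_bases",
                                     "n_large_effect", "density_per_kb"])
    return df.sort_values("density_per_kb", ascending=False).reset_index(drop=True)


def window_density(variants: pd.DataFrame, chrom_lengths: dict[str, int],
                   window_kb: float, offset_kb: float = 10.0) -> pd.DataFrame:
    """Counts of variants in overlapping windows at fixed offsets.

    Windows of ``window_kb`` kb start every ``offset_kb`` kb from 0;
    an interior variant is counted in ceil(window/offset) windows.
    """
    window = int(window_kb * 1000)
    offset = int(offset_kb * 1000)
    if window < offset:
        raise ValueError("window must be >= offset")
    rows = []
    for chrom, clen in chrom_lengths.items():
        pos = np.sort(
            variants.loc[variants["chrom"] == chrom, "pos"].to_numpy()
        )
        start = 0
        while start < clen:
            end = start + window
            n = int(np.searchsorted(pos, end) - np.searchsorted(pos, start))
            rows.append((chrom, start, end, n))
            start += offset
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])
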