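"""Feature classification, coding effects (with a mutate-translate-diff
oracle), Ts/Tv, indel frame statistics, family densities and window
tracks."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from radgbs import annotate
from radgbs.model import CoverageMap, ValidationError


@pytest.fixture(scope="module")
def indexed(small_genome):
    genome, annotation = small_genome
    return genome, annotation, annotate.FeatureIndex(genome, annotation)


class TestClassifyFeature:
    def test_cds_position(self, indexed):
        genome, annotation, index = indexed
        cds = annotation.of_type("CDS").iloc[0]
        assert index.classify(cds["chrom"], (cds["start"] + cds["end"]) // 2) \
            in ("CDS", "splice_site")
        # a position strictly inside a long CDS segment is CDS
        wide = annotation.of_type("CDS")
        wide = wide[wide["end"] - wide["start"] > 10].iloc[0]
        assert index.classify(wide["chrom"], wide["start"] + 5) == "CDS"

    def test_first_intron_base_is_splice_site(self, indexed):
        _, annotation, index = indexed
        intron = annotation.of_type("intron").iloc[0]
        assert index.classify(intron["chrom"], intron["start"]) == "splice_site"
        assert index.classify(intron["chrom"], intron["end"] - 1) == "splice_site"

    def test_interior_intron_base(self, indexed):
        _, annotation, index = indexed
        introns = annotation.of_type("intron")
        long = introns[introns["end"] - introns["start"] > 10].iloc[0]
        assert index.classify(long["chrom"], long["start"] + 5) == "intron"

    def test_unannotated_position_intergenic(self, indexed):
        genome, annotation, index = indexed
        covered = np.zeros(genome.lengths()["chr1"], dtype=bool)
        for f in annotation.features.itertuples(index=False):
            covered[f.start:f.end] = True
        free = int(np.flatnonzero(~covered)[10])
        assert index.classify("chr1", free) == "intergenic"

    def test_outside_genome_raises(self, indexed):
        _, _, index = indexed
        with pytest.raises(ValidationError):
            index.classify("chr1", 10_000_000)

    def test_partition_every_locus_single_class(self, indexed):
        genome, _, index = indexed
        # classification is a total function over the chromosome
        classes = {index.classify("chr1", p) for p in range(0, 60_000, 997)}
        assert classes <= set(annotate.FEATURE_CLASSES)


def brute_force_effect(genome, annotation, gene_id, chrom, pos, ref, alt):
    """Oracle: mutate the full CDS, translate both, diff the proteins."""
    from radgbs.annotate import _cds_offset, _spliced_cds
    from radgbs.model import revcomp
    cds, segs, strand = _spliced_cds(genome, annotation, gene_id)
    off = _cds_offset(segs, strand, pos)
    alt_t = alt if strand == "+" else revcomp(alt)
    mutated = cds[:off] + alt_t + cds[off + 1:]
    p_ref = str(Seq(cds).translate())
    p_alt = str(Seq(mutated).translate())
    i = off // 3
    if p_ref[i] == p_alt[i]:
        return "synonymous"
    if p_ref[i] != "*" and p_alt[i] == "*":
        return "stop_gained"
    if p_ref[i] == "*" and p_alt[i] != "*":
        return "stop_lost"
    return "nonsynonymous"


class TestCodingEffect:
    def test_agrees_with_mutate_translate_oracle(self, indexed):
        genome, annotation, index = indexed
        rng = np.random.default_rng(3)
        n_checked = 0
        effects_seen = set()
        for cds in annotation.of_type("CDS").itertuples(index=False):
            for _ in range(20):
                pos = int(rng.integers(cds.start, cds.end))
                if index.classify(cds.chrom, pos) != "CDS":
                    continue
                ref = genome.sequence(cds.chrom)[pos]
                for alt in set("ACGT") - {ref}:
                    call = annotate.coding_effect(
                        genome, annotation, index, cds.chrom, pos, ref, alt)
                    oracle = brute_force_effect(
                        genome, annotation, cds.gene_id, cds.chrom, pos,
                        ref, alt)
                    assert call.coding_effect == oracle
                    assert call.large_effect == (
                        call.coding_effect in annotate.LARGE_EFFECT)
                    effects_seen.add(oracle)
                    n_checked += 1
        assert n_checked > 300
        assert {"synonymous", "nonsynonymous", "stop_gained"} <= effects_seen

    def test_stop_lost_detected(self, indexed):
        genome, annotation, index = indexed
        # find a stop codon position whose mutation restores sense
        from radgbs.annotate import _cds_offset, _spliced_cds
        for g in annotation.of_type("gene").itertuples(index=False):
            cds, segs, strand = _spliced_cds(genome, annotation, g.gene_id)
            # last codon is the stop; locate its genomic first base
            stop_off = len(cds) - 3
            for seg in segs:
                for pos in range(seg.start, seg.end):
                    if _cds_offset(segs, strand, pos) == stop_off:
                        ref = genome.sequence(g.chrom)[pos]
                        # T->C at stop start always yields sense codon
                        from radgbs.model import revcomp
                        alt = "C" if strand == "+" else "G"
                        if (ref if strand == "+" else revcomp(ref)) != "T":
                            continue
                        call = annotate.coding_effect(
                            genome, annotation, index, g.chrom, pos, ref, alt)
                        assert call.coding_effect == "stop_lost"
                        assert call.large_effect
                        return
        pytest.skip("no suitable stop codon found")

    def test_splice_site_snp_large_effect(self, indexed):
        genome, annotation, index = indexed
        intron = annotation.of_type("intron").iloc[0]
        pos = int(intron["start"])
        ref = genome.sequence(intron["chrom"])[pos]
        alt = "A" if ref != "A" else "C"
        call = annotate.coding_effect(genome, annotation, index,
                                      intron["chrom"], pos, ref, alt)
        assert call.coding_effect == "splice_disrupting"
        assert call.large_effect


class TestTsTv:
    def test_hand_count(self):
        snps = pd.DataFrame({"ref": ["A", "C", "A"], "alt": ["G", "T", "C"]})
        assert annotate.ts_tv(snps) == 2.0

    def test_all_transitions_infinite(self):
        snps = pd.DataFrame({"ref": ["A"], "alt": ["G"]})
        assert annotate.ts_tv(snps) == float("inf")

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            annotate.ts_tv(pd.DataFrame({"ref": [], "alt": []}))


class TestIndelStats:
    def _frame(self, cds_lengths, inter_lengths, indexed):
        genome, annotation, index = indexed
        cds = annotation.of_type("CDS")
        long_cds = cds[cds["end"] - cds["start"] > 30].iloc[0]
        covered = np.zeros(genome.lengths()["chr1"], dtype=bool)
        for f in annotation.features.itertuples(index=False):
            covered[f.start:f.end] = True
        free = np.flatnonzero(~covered)
        rows = []
        for i, l in enumerate(cds_lengths):
            rows.append(("chr1", int(long_cds["start"]) + 5 + i,
                         "A" * (l + 1), "A"))
        for i, l in enumerate(inter_lengths):
            rows.append(("chr1", int(free[100 + i]), "A" * (l + 1), "A"))
        return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"]), index

    def test_fractions_hand_count(self, indexed):
        indels, index = self._frame([3, 3, 6, 1], [1, 2, 1, 3], indexed)
        stats = annotate.indel_feature_stats(indels, index)
        f = stats["fractions"]
        assert f.loc["CDS", "mean"] == 0.75
        assert f.loc["intergenic", "mean"] == 0.25

    def test_identical_distributions_z_zero(self, indexed):
        indels, index = self._frame([3, 1, 2], [3, 1, 2], indexed)
        stats = annotate.indel_feature_stats(indels, index)
        assert stats["z"] == pytest.approx(0.0)


class TestFamilyDensity:
    def _setup(self, indexed, cover_bases):
        genome, annotation, index = indexed
        cov = CoverageMap(["a"], genome.lengths())
        gene = annotation.of_type("gene").iloc[0]
        fam = gene["family_id"]
        fam_genes = annotation.of_type("gene")
        fam_genes = fam_genes[fam_genes["family_id"] == fam]
        start = int(fam_genes["start"].iloc[0])
        cov.add_interval("a", "chr1", start, start + cover_bases)
        return annotation, cov, fam, start

    def test_coverage_boundary_strict(self, indexed):
        annotation, cov, fam, _ = self._setup(indexed, 400)
        df = annotate.large_effect_density_by_family(
            [], annotation, cov, min_covered=400)
        assert fam not in set(df["family_id"])  # strictly greater required
        df = annotate.large_effect_density_by_family(
            [], annotation, cov, min_covered=399)
        # covered genic bases may be < 400 if the gene is shorter
        assert isinstance(df, pd.DataFrame)

    def test_density_arithmetic(self, indexed):
        genome, annotation, index = indexed
        cov = CoverageMap(["a"], genome.lengths())
        cov.add_interval("a", "chr1", 0, genome.lengths()["chr1"])
        effects = []
        gene = annotation.of_type("gene").iloc[0]
        for i in range(5):
            effects.append(annotate.EffectCall(
                "chr1", int(gene["start"]) + i, "A", "T", "CDS",
                "stop_gained", True, gene["gene_id"], gene["family_id"]))
        df = annotate.large_effect_density_by_family(
            effects, annotation, cov, min_covered=100)
        row = df[df["family_id"] == gene["family_id"]].iloc[0]
        assert row["n_large_effect"] == 5
        assert row["density_per_kb"] == pytest.approx(
            5 / (row["covered_bases"] / 1000))

    def test_no_families_pass(self, indexed):
        genome, annotation, _ = indexed
        cov = CoverageMap(["a"], genome.lengths())
        df = annotate.large_effect_density_by_family([], annotation, cov)
        assert len(df) == 0


class TestWindowDensity:
    def test_interior_variant_in_ten_windows(self):
        variants = pd.DataFrame({"chrom": ["c1"], "pos": [150_000]})
        track = annotate.window_density(variants, {"c1": 400_000},
                                        window_kb=100, offset_kb=10)
        assert track["count"].sum() == 10

    def test_empty_variants_all_zero(self):
        variants = pd.DataFrame({"chrom": [], "pos": []})
        track = annotate.window_density(variants, {"c1": 100_000},
                                        window_kb=20, offset_kb=10)
        assert (track["count"] == 0).all() and len(track) > 0

    def test_snp_indel_tracks_correlate(self, panel_truth):
        loci = panel_truth.loci
        kw = dict(chrom_lengths={"chr1": 60_000}, window_kb=5, offset_kb=1)
        snp = annotate.window_density(loci[loci["vtype"] == "SNP"], **kw)
        ind = annotate.window_density(loci[loci["vtype"] != "SNP"], **kw)
        r = np.corrcoef(snp["count"], ind["count"])[0, 1]
        assert r > 0
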