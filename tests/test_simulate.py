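"""Synthetic-panel generator: determinism, gene-model integrity,
similarity structure, indel frame bias, and read-simulation truth."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from radgbs import digest, diversity, simulate
from radgbs.model import (
    ALT_HOM,
    HET,
    GenotypeMatrix,
    ReferenceGenome,
    ValidationError,
    revcomp,
)


class TestGenerateReference:
    def test_deterministic_under_seed(self):
        a = simulate.generate_reference(50_000, 1, 0.44, 2.0, 0.1, seed=7)
        b = simulate.generate_reference(50_000, 1, 0.44, 2.0, 0.1, seed=7)
        assert a[0].chromosomes == b[0].chromosomes
        assert a[1].features.equals(b[1].features)

    def test_orfs_intact(self, small_genome):
        genome, annotation = small_genome
        from radgbs.annotate import _spliced_cds
        genes = annotation.of_type("gene")["gene_id"]
        assert len(genes) > 0
        for gid in genes:
            cds, _, _ = _spliced_cds(genome, annotation, gid)
            protein = str(Seq(cds).translate())
            assert protein.startswith("M")
            assert protein.endswith("*")
            assert "*" not in protein[:-1]

    def test_introns_canonical_gt_ag(self, small_genome):
        genome, annotation = small_genome
        seq = dict(genome.chromosomes)
        introns = annotation.of_type("intron")
        assert len(introns) > 0
        for f in introns.itertuples(index=False):
            s = seq[f.chrom][f.start:f.end]
            if f.strand == "-":
                s = revcomp(s)
            assert s[:2] == "GT" and s[-2:] == "AG"

    def test_gene_density_zero_only_repeats(self):
        _, annotation = simulate.generate_reference(
            20_000, 1, gene_density=0.0, repeat_density=0.1, seed=3)
        assert set(annotation.features["ftype"]) == {"repeat"}

    def test_packing_error_when_overfull(self):
        with pytest.raises(ValidationError, match="pack"):
            simulate.generate_reference(10_000, 1, gene_density=50.0,
                                        repeat_density=0.5, seed=0)


class TestPanelVariants:
    def test_group_similarity_ordering(self, panel_truth):
        sim = diversity.pairwise_similarity(panel_truth).to_frame()
        assert sim.loc["Sb1", "Sb2"] > sim.loc["Sb1", "Sb3"]
        assert sim.loc["Sb3", "Sb4"] > sim.loc["Sb3", "Sb5"]

    def test_similarity_targets_within_tolerance(self):
        genome, annotation = simulate.generate_reference(
            120_000, 1, gene_density=1.0, repeat_density=0.02, seed=21)
        config = simulate.PanelConfig(seed=5, snp_density=50.0,
                                      indel_density=2.0)
        truth = simulate.generate_panel_variants(genome, annotation, config)
        assert truth.n_loci >= 5000
        sim = diversity.pairwise_similarity(truth).to_frame()
        assert abs(sim.loc["Sb1", "Sb2"] - 0.9) < 0.05
        assert abs(sim.loc["Sb5", "Sb6"] - 0.6) < 0.05
        assert abs(sim.loc["Sb1", "Sb5"] - 0.6) < 0.05
        # heterozygosity close to configured rate (+-50% relative)
        het_frac = (truth.codes == HET).mean()
        assert 0.5 * config.het_rate < het_frac < 1.5 * config.het_rate

    def test_seed_contract(self, small_genome):
        genome, annotation = small_genome
        cfg = dict(snp_density=20.0, indel_density=2.0)
        t1 = simulate.generate_panel_variants(
            genome, annotation, simulate.PanelConfig(seed=1, **cfg))
        t2 = simulate.generate_panel_variants(
            genome, annotation, simulate.PanelConfig(seed=2, **cfg))
        assert not t1.loci["pos"].equals(t2.loci["pos"])
        s1 = diversity.pairwise_similarity(t1).to_frame().loc["Sb1", "Sb2"]
        s2 = diversity.pairwise_similarity(t2).to_frame().loc["Sb1", "Sb2"]
        assert abs(s1 - s2) < 0.05

    def test_impossible_targets_rejected(self):
        with pytest.raises(ValidationError, match="s_in < s_out"):
            simulate.PanelConfig(groups=[(["Sb1", "Sb2"], 0.5)] + [
                ([a], 1.0) for a in ("Sb3", "Sb4", "Sb5", "Sb6", "Sb7", "Sb8")
            ], s_out=0.8)

    @pytest.mark.parametrize("bias,expect_enriched", [(1.0, False), (8.0, True)])
    def test_exon_frame_bias(self, bias, expect_enriched):
        genome, annotation = simulate.generate_reference(
            100_000, 1, gene_density=4.0, repeat_density=0.0, seed=13)
        config = simulate.PanelConfig(seed=17, snp_density=1.0,
                                      indel_density=20.0,
                                      exon_frame_bias=bias)
        truth = simulate.generate_panel_variants(genome, annotation, config)
        from radgbs.annotate import FeatureIndex, indel_feature_stats
        indels = truth.loci[truth.loci["vtype"] != "SNP"]
        assert len(indels) >= 1500
        stats = indel_feature_stats(indels, FeatureIndex(genome, annotation))
        if expect_enriched:
            assert stats["p_value"] < 0.01
            f = stats["fractions"]
            assert f.loc["CDS", "mean"] > f.loc["intergenic", "mean"]
        else:
            assert stats["p_value"] > 0.01


def _two_accession_truth(genome, seed=0, n_snps=60):
    """Accession REFACC identical to the reference; ALTACC homozygous
    alternative at every SNP."""
    rng = np.random.default_rng(seed)
    seq = genome.sequence("chr1")
    pos = np.sort(rng.choice(len(seq) - 10, n_snps, replace=False))
    rows = []
    for p in pos:
        ref = seq[p]
        alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
        rows.append(("chr1", int(p), ref, alt, "SNP"))
    loci = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "vtype"])
    codes = np.zeros((n_snps, 2), dtype=np.int8)
    codes[:, 1] = ALT_HOM
    return GenotypeMatrix(loci, ["REFACC", "ALTACC"], codes)


class TestSimulateReads:
    def test_deterministic(self, small_genome, panel_truth):
        genome, _ = small_genome
        lib = simulate.LibraryConfig(seed=9, mean_site_depth=4.0)
        r1 = simulate.simulate_reads(genome, panel_truth, lib, "Sb3")
        r2 = simulate.simulate_reads(genome, panel_truth, lib, "Sb3")
        assert [r.sequence for r in r1] == [r.sequence for r in r2]
        assert all((a.qualities == b.qualities).all()
                   for a, b in zip(r1, r2))

    def test_crs_reads_start_at_cut_positions(self, small_genome):
        genome, _ = small_genome
        truth = _two_accession_truth(genome)
        lib = simulate.LibraryConfig(seed=1, ncrs_fraction=0.0,
                                     error_rate=0.0, mean_site_depth=3.0)
        reads = simulate.simulate_reads(genome, truth, lib, "REFACC")
        cuts = set(digest.find_sites(genome, lib.enzyme)
                   .cut_positions("chr1").tolist())
        assert len(reads) > 0
        assert all(r.origin_class == "cRS" for r in reads)
        for r in reads:
            chrom, pos, strand = r.truth_origin
            start_site = pos if strand == "+" else pos + len(r.sequence)
            assert start_site in cuts

    def test_error_free_reference_accession_reads_are_exact_substrings(
            self, small_genome):
        genome, _ = small_genome
        truth = _two_accession_truth(genome)
        seq = genome.sequence("chr1")
        lib = simulate.LibraryConfig(seed=2, error_rate=0.0,
                                     mean_site_depth=3.0)
        reads = simulate.simulate_reads(genome, truth, lib, "REFACC")
        for r in reads:
            assert r.sequence in seq or revcomp(r.sequence) in seq

    def test_alt_hom_reads_carry_alt_base(self, small_genome):
        genome, _ = small_genome
        truth = _two_accession_truth(genome)
        lib = simulate.LibraryConfig(seed=3, error_rate=0.0,
                                     mean_site_depth=5.0, ncrs_fraction=0.0)
        reads = simulate.simulate_reads(genome, truth, lib, "ALTACC")
        snps = dict(zip(truth.loci["pos"], truth.loci["alt"]))
        n_checked = 0
        for r in reads:
            chrom, pos, strand = r.truth_origin
            seq = r.sequence if strand == "+" else revcomp(r.sequence)
            for sp, alt in snps.items():
                if pos <= sp < pos + len(seq):
                    assert seq[sp - pos] == alt
                    n_checked += 1
        assert n_checked > 0

    def test_realized_ncrs_fraction(self):
        genome, ann = simulate.generate_reference(
            100_000, 1, gene_density=0.5, repeat_density=0.0, seed=31)
        truth = _two_accession_truth(genome, seed=1)
        lib = simulate.LibraryConfig(seed=4, ncrs_fraction=0.15,
                                     mean_site_depth=90.0,
                                     depth_dispersion=1e9)
        reads = simulate.simulate_reads(genome, truth, lib, "REFACC")
        assert len(reads) >= 10_000
        frac = sum(r.origin_class == "ncRS" for r in reads) / len(reads)
        assert abs(frac - 0.15) < 0.02

    def test_sr_reads_respect_size_selection(self, small_genome):
        genome, _ = small_genome
        truth = _two_accession_truth(genome)
        lib = simulate.LibraryConfig(lib_type="SR", seed=5, error_rate=0.0,
                                     reads_per_accession=500,
                                     read_length=36, size_range=(200, 2000))
        reads = simulate.simulate_reads(genome, truth, lib, "REFACC")
        assert len(reads) == 500
        assert all(r.origin_class == "SR" for r in reads)
        seq = genome.sequence("chr1")
        for r in reads[:50]:
            assert r.sequence in seq or revcomp(r.sequence) in seq

    def test_read_length_exceeding_chromosome_raises(self):
        genome = ReferenceGenome([("c1", "ACGT" * 30)])
        truth = _two_accession_truth(genome.__class__([("chr1", "ACGT" * 30)]))
        lib = simulate.LibraryConfig(seed=0, read_length=500)
        with pytest.raises(ValidationError):
            simulate.simulate_reads(
                ReferenceGenome([("chr1", "ACGT" * 30)]), truth, lib, "REFACC")


class TestApplyVariants:
    def test_snp_and_indel_with_coordinate_map(self):
        seq = "AAAACCCCGGGGTTTT"
        variants = pd.DataFrame([
            ("c1", 1, "A", "G", "SNP"),
            ("c1", 5, "CCC", "C", "deletion"),
            ("c1", 10, "G", "GTT", "insertion"),
        ], columns=["chrom", "pos", "ref", "alt", "vtype"])
        new, blocks = simulate.apply_variants(seq, variants)
        assert new == "AGAACC" + "GGG" + "TT" + "GTTTT"
        # position after the deletion maps back correctly
        from radgbs.simulate import _map_to_ref
        assert _map_to_ref(blocks, 0) == 0
        assert _map_to_ref(blocks, 6) == 8   # first G after deleted CC
        assert _map_to_ref(blocks, len(new) - 1) == len(seq) - 1
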