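"""Simulate the study panel: an annotated 200 kb genome, a structured
8-accession truth panel (two similar pairs plus four divergent
accessions), and BsrFI RAD reads for every accession.

Writes genome.fa, annotation.gff3, truth.{vcf,tsv}, reads.fastq and
read_origins.bed under results/analysis/.
"""

from pathlib import Path

from radgbs import io, simulate
from radgbs.model import ReadSet

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"
SEED = 20_110_707  # fixed study seed


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome, annotation = simulate.generate_reference(
        200_000, n_chroms=2, gc_content=0.44, gene_density=1.5,
        repeat_density=0.02, seed=SEED)
    io.write_fasta(genome, OUT / "genome.fa")
    io.write_gff3(annotation, OUT / "annotation.gff3")

    panel = simulate.PanelConfig(seed=SEED + 1, snp_density=50.0,
                                 indel_density=10.0)
    truth = simulate.generate_panel_variants(genome, annotation, panel)
    io.write_genotypes(truth, OUT / "truth.vcf",
                       contig_lengths=genome.lengths())
    io.write_genotypes(truth, OUT / "truth.tsv")

    library = simulate.LibraryConfig(seed=SEED + 2, mean_site_depth=12.0,
                                     ncrs_fraction=0.12)
    reads = ReadSet()
    for acc in panel.accessions:
        reads.extend(simulate.simulate_reads(genome, truth, library, acc))
    io.write_fastq(reads, OUT / "reads.fastq")
    io.write_bed(
        ((r.truth_origin[0], r.truth_origin[1],
          r.truth_origin[1] + len(r.sequence), r.id, r.origin_class)
         for r in reads),
        OUT / "read_origins.bed")

    n_snp = int((truth.loci["vtype"] == "SNP").sum())
    n_ncrs = sum(r.origin_class == "ncRS" for r in reads)
    print(f"genome: {genome.total_length()} bp over "
          f"{len(genome.chromosomes)} chromosomes, "
          f"{len(annotation.of_type('gene'))} genes")
    print(f"truth panel: {truth.n_loci} loci ({n_snp} SNPs, "
          f"{truth.n_loci - n_snp} indels) x {truth.n_accessions} accessions")
    print(f"reads: {len(reads)} "
          f"(realized ncRS fraction {n_ncrs / len(reads):.3f})")


if __name__ == "__main__":
    main()
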