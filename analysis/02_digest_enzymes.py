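"""In-silico digestion of the simulated genome with PstI and BsrFI:
site counts, fragment-size tables, flanking-read uniqueness, and the
site-coverage saturation curve of the simulated RAD reads.
"""

from pathlib import Path

from radgbs import digest, io
from radgbs.model import BSRFI, PSTI

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"


def main() -> None:
    genome = io.read_fasta(OUT / "genome.fa")
    for enzyme in (PSTI, BSRFI):
        result = digest.fragment_table(digest.find_sites(genome, enzyme),
                                       genome)
        result.fragments.to_csv(OUT / f"fragments_{enzyme.name}.tsv",
                                sep="\t", index=False)
        uniq = digest.site_read_uniqueness(genome, enzyme, read_length=36)
        uniq.to_csv(OUT / f"uniqueness_{enzyme.name}.tsv", sep="\t",
                    index=False)
        print(f"{enzyme.name}: {len(result.sites)} recognition sites, "
              f"median fragment {result.fragments['length'].median():.0f} bp, "
              f"unique 36-base flank fraction "
              f"{uniq.attrs['unique_fraction']:.3f}")

    reads = io.read_fastq(OUT / "reads.fastq")
    curve = digest.coverage_saturation(reads, depth_thresholds=(1, 4),
                                       seed=1)
    curve.to_csv(OUT / "site_saturation.tsv", sep="\t", index=False)
    final = curve[curve["threshold"] == 1]["distinct_sites"].iloc[-1]
    print(f"saturation: {final} distinct read-start sites at full depth")


if __name__ == "__main__":
    main()
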