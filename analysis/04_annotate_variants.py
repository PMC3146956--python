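"""Functional annotation of the truth panel: feature classes, coding
effects and large-effect SNPs, Ts/Tv, indel frame statistics by
feature, per-family large-effect density and window density tracks.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from radgbs import annotate, io

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"


def main() -> None:
    genome = io.read_fasta(OUT / "genome.fa")
    annotation = io.read_gff3(OUT / "annotation.gff3")
    truth = io.read_genotypes(OUT / "truth.tsv")
    index = annotate.FeatureIndex(genome, annotation)

    snps = truth.loci[truth.loci["vtype"] == "SNP"]
    effects = [annotate.coding_effect(genome, annotation, index,
                                      r.chrom, r.pos, r.ref, r.alt)
               for r in snps.itertuples(index=False)]
    eff = pd.DataFrame([vars(e) for e in effects])
    eff.to_csv(OUT / "effects.tsv", sep="\t", index=False)
    counts = eff["coding_effect"].value_counts()
    n_syn = counts.get("synonymous", 0)
    n_nonsyn = counts.get("nonsynonymous", 0)
    n_le = int(eff["large_effect"].sum())
    print(f"{len(eff)} SNPs: {n_nonsyn} nonsynonymous / {n_syn} synonymous "
          f"(ratio {n_nonsyn / max(n_syn, 1):.2f}), "
          f"{n_le} large-effect")
    print(f"Ts/Tv: {annotate.ts_tv(snps):.2f}")

    indels = truth.loci[truth.loci["vtype"] != "SNP"]
    stats = annotate.indel_feature_stats(indels, index)
    stats["histograms"].to_csv(OUT / "indel_lengths.tsv", sep="\t",
                               index=False)
    f = stats["fractions"]
    print("multiple-of-3 indel fraction: "
          f"CDS {f.loc['CDS', 'mean']:.2f} vs intergenic "
          f"{f.loc['intergenic', 'mean']:.2f} "
          f"(two-proportion z = {stats['z']:.1f}, p = {stats['p_value']:.2g})")

    # coverage proxy for family densities: everything covered
    from radgbs.model import CoverageMap
    cov = CoverageMap(truth.accessions, genome.lengths())
    for a in truth.accessions:
        for c, l in genome.lengths().items():
            cov.add_interval(a, c, 0, l)
    fam = annotate.large_effect_density_by_family(
        effects, annotation, cov, min_covered=10_000)
    fam.to_csv(OUT / "family_density.tsv", sep="\t", index=False)
    if len(fam):
        top = fam.iloc[0]
        print(f"densest family: {top['family_id']} "
              f"({top['density_per_kb']:.3f} large-effect SNPs/kb)")

    snp_track = annotate.window_density(snps, genome.lengths(), 20, 10)
    ind_track = annotate.window_density(indels, genome.lengths(), 20, 10)
    snp_track.to_csv(OUT / "density_snp.tsv", sep="\t", index=False)
    ind_track.to_csv(OUT / "density_indel.tsv", sep="\t", index=False)
    r = np.corrcoef(snp_track["count"], ind_track["count"])[0, 1]
    print(f"SNP vs indel window-density correlation: r = {r:.2f}")


if __name__ == "__main__":
    main()
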