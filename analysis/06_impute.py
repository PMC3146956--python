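"""Imputation evaluation on the truth panel: window sweep, accession
subset analysis (accuracy versus panel similarity and size), SNP
subsampling, and the read-resampling genotype-yield curve.
"""

from pathlib import Path

import numpy as np

from radgbs import impute, io

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"
SEED = 20_110_708


def main() -> None:
    truth = io.read_genotypes(OUT / "truth.tsv")
    params = impute.ImputeParams(window=10)

    sweep = impute.window_sweep(truth, [0, 1, 2, 5, 10, 15, 20, 50, 100],
                                mask_fraction=0.10, seed=SEED, params=params)
    sweep.to_csv(OUT / "window_sweep.tsv", sep="\t", index=False)
    at0 = sweep.loc[sweep["window"] == 0].iloc[0]
    best = sweep.loc[sweep["accuracy_all"].idxmax()]
    print(f"window 0 (all-reference) accuracy: {at0['accuracy_all']:.3f}")
    print(f"best window {int(best['window'])}: accuracy "
          f"{best['accuracy_all']:.3f}")

    subsets = impute.subset_analysis(truth, 0.10, seed=SEED + 1,
                                     params=impute.ImputeParams(window=5))
    subsets.to_csv(OUT / "subset_analysis.tsv", sep="\t", index=False)
    slope_sim = np.polyfit(subsets["mean_similarity"],
                           subsets["accuracy_all"], 1)[0]
    r_sim = np.corrcoef(subsets["mean_similarity"],
                        subsets["accuracy_all"])[0, 1]
    r_size = np.corrcoef(subsets["size"], subsets["accuracy_all"])[0, 1]
    print(f"subset accuracy vs similarity: slope {slope_sim:.2f}, "
          f"r^2 {r_sim**2:.2f}; vs size alone r^2 {r_size**2:.2f}")

    sub = impute.snp_subsample_accuracy(truth, [0.05, 0.1, 0.25, 0.5, 1.0],
                                        0.10, seed=SEED + 2, params=params)
    sub.to_csv(OUT / "snp_subsample.tsv", sep="\t", index=False)
    print("accuracy by SNP subsample proportion: "
          + ", ".join(f"{p:.0%}={a:.3f}"
                      for p, a in zip(sub["proportion"],
                                      sub["accuracy_all"])))

    genome = io.read_fasta(OUT / "genome.fa")
    reads = io.read_fastq(OUT / "reads.fastq")
    for r in reads:
        r.accession = r.id.split("_")[0]
    curve = impute.read_resample_yield(genome, reads,
                                       increment=len(reads) // 8,
                                       seed=SEED + 3)
    curve.to_csv(OUT / "read_resample_yield.tsv", sep="\t", index=False)
    half = curve.iloc[len(curve) // 2 - 1]
    full = curve.iloc[-1]
    print(f"genotype yield: {half['n_genotypes'] / full['n_genotypes']:.0%} "
          f"of genotypes from {half['reads_sampled'] / full['reads_sampled']:.0%} "
          "of reads")


if __name__ == "__main__":
    main()
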