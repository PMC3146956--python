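"""Panel diversity: pairwise similarity, site-frequency spectra with
the neutral folded expectation, allele-sharing profiles, and
haplotype-sharing windows.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from radgbs import diversity, io

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"


def main() -> None:
    truth = io.read_genotypes(OUT / "truth.tsv")
    sim = diversity.pairwise_similarity(truth, include_reference=True)
    sim.to_frame().round(4).to_csv(OUT / "similarity.tsv", sep="\t")
    pairs = sim.to_frame()
    print(f"mean pairwise similarity (accessions only): "
          f"{diversity.pairwise_similarity(truth).mean_pairwise():.3f}")
    print(f"similar pairs: Sb1-Sb2 {pairs.loc['Sb1', 'Sb2']:.3f}, "
          f"Sb3-Sb4 {pairs.loc['Sb3', 'Sb4']:.3f}; "
          f"outgroup pair Sb7-Sb8 {pairs.loc['Sb7', 'Sb8']:.3f}")

    spectrum = diversity.sfs(truth)
    n = truth.n_accessions
    pd.DataFrame({
        "alt_count": np.arange(1, n + 1), "n_snps": spectrum.unfolded,
    }).to_csv(OUT / "sfs_unfolded.tsv", sep="\t", index=False)
    pd.DataFrame({
        "minor_count": np.arange(1, n // 2 + 1),
        "n_snps": spectrum.folded,
        "expected_proportion": spectrum.expected_folded,
        "observed_proportion": spectrum.folded / spectrum.folded.sum(),
    }).to_csv(OUT / "sfs_folded.tsv", sep="\t", index=False)
    single = spectrum.unfolded[0] / spectrum.unfolded.sum()
    print(f"singleton fraction: {single:.2f} "
          f"(neutral folded expectation for bin 1: "
          f"{spectrum.expected_folded[0]:.2f})")

    prof = diversity.alt_allele_sharing_profile(truth)
    prof.to_csv(OUT / "allele_sharing_profile.tsv", sep="\t")
    windows = diversity.haplotype_sharing_windows(
        truth, window_snps=50, thresholds=(0.1, 0.2, 0.3),
        match_class="alt_hom")
    windows.to_csv(OUT / "haplotype_windows.tsv", sep="\t", index=False)
    tiered = windows.dropna(subset=["tier"])
    top_pairs = (tiered.groupby(["acc_i", "acc_j"]).size()
                 .sort_values(ascending=False).head(2))
    print("pairs with most shared alt-homozygote windows:")
    for (a, b), k in top_pairs.items():
        print(f"  {a}-{b}: {k} windows above the lowest tier")


if __name__ == "__main__":
    main()
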