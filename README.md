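# radgbs

Reduced-representation (RAD) SNP discovery, panel diversity statistics and
local-haplotype genotype imputation for small inbred panels — with a
synthetic-panel generator so the whole analysis is reproducible end to end
without external data.

## The problem

Genotyping-by-sequencing of a small, diverse inbred panel (for example
eight sorghum accessions against a reference genome) raises three coupled
questions:

1. **Where does the sequencing go?** RAD libraries start reads at the
   recognition sites of a restriction enzyme (for example BsrFI, motif
   `RCCGGY`), concentrating coverage on a repeatable genome fraction — but
   a minority of reads ("star activity") start at noncanonical,
   motif-like sites, and semirandom (SR) libraries spread coverage thinly.
2. **Which variants are real?** Candidate SNPs must pass depth/quality
   filters; validation against a confirmed set yields a confirmation rate
   (precision) and a recall (1 − false-negative rate).
3. **Can missing genotypes be imputed?** With shallow multiplexed
   sequencing most genotype cells are missing. The imputation algorithm
   fills a missing genotype of a target accession from the donor haplotype
   most similar to the target over a window of `w` flanking SNP loci,
   optionally including the reference genome as an all-reference-homozygote
   donor, and accepting the donor only above a similarity threshold.

The panel-level statistics are standard: pairwise genomic similarity
`sim(i,j) = Σ identities / 2N` over the `N` loci genotyped in both
accessions (allele identity 0–2 per locus, phase disregarded); pairwise
SNP density `S_ij / B_ij` with `B_ij` the bases sequenced in common; and
the site-frequency spectrum, whose folded neutral infinite-sites
expectation for bin `i` of `n` sequences is proportional to
`(1/i + 1/(n−i)) / (1 + [i = n−i])`.

## Layout

- `src/radgbs/` — the library: `model` (domain types), `io` (FASTA,
  FASTQ, VCF, GFF3, TSV, BED), `simulate` (genome/panel/read generator),
  `digest` (in-silico restriction digestion), `calling` (QC, unique-best
  ungapped alignment, pileup, two SNP filters, validation), `annotate`
  (feature classes, coding effects, large-effect SNPs), `diversity`
  (similarity, SFS, haplotype sharing), `impute` (windowed imputation and
  its evaluation machinery), `pipeline` + `cli` (orchestration).
- `analysis/01…06_*.py` — numbered drivers that run the study on a
  simulated panel and write tables under `results/analysis/`.
- `tests/` — the pytest suite, including system-level acceptance tests.

## Worked example

```bash
python analysis/01_simulate_panel.py
python analysis/06_impute.py
```

prints (abbreviated):

```
truth panel: 12000 loci (10000 SNPs, 2000 indels) x 8 accessions
reads: 26022 (realized ncRS fraction 0.120)
...
window 0 (all-reference) accuracy: 0.776
best window 100: accuracy 0.830
subset accuracy vs similarity: slope 0.45, r^2 0.29; vs size alone r^2 0.00
genotype yield: 57% of genotypes from 50% of reads
```

Reading: with window 0 every missing genotype is imputed as the reference
homozygote, so accuracy equals the reference-genotype fraction among the
masked cells (0.776 here); haplotype windows raise accuracy to 0.83; and
across all 254 accession subsets, accuracy tracks within-panel genomic
similarity while panel *size* alone explains essentially nothing — the
panel-design conclusion that pairs or groups of genomically similar
entries, not more entries, are what make shallow genotyping imputable.

The same library functions drive each stage; for a one-shot run there is
also a CLI (`radgbs run-all --config cfg.yaml --out run/`) with
per-stage subcommands (`simulate-genome`, `digest`, `call`, `impute`).

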