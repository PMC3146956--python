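# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the package. Internal coordinates are 0-based half-open
throughout; VCF/GFF3 conversion happens only in `radgbs.io`.

## Synthetic reference genome

`simulate.generate_reference(total_length, n_chroms, gc_content,
gene_density, repeat_density, seed)` draws i.i.d. background sequence at
the requested GC content (default 0.44, a typical grass genome value) and
packs two kinds of features without overlap:

- **Genes** (density in genes per 10 kb, default 2): an ORF of 50–150
  sense codons starting with ATG and ending with a stop, split into 1–4
  CDS segments by introns of 26–120 bp carrying canonical `GT..AG`
  dinucleotides, flanked by short UTRs; strand random. CDS phases follow
  the GFF3 convention. Every generated gene translates without internal
  stop codons (tested).
- **Repeats** (fraction of the genome, default 0.05–0.1): families of
  200–500 bp units pasted at 2–3 identical copies, deliberately creating
  non-unique regions that exercise the alignment-uniqueness machinery.

Feature packing places items in random order with random gaps; impossible
densities raise a packing error rather than silently overlapping.

## Truth variant panel

`generate_panel_variants` draws SNPs and short indels and assigns carrier
patterns across an inbred panel.

**Placement.** SNP and indel counts per 2 kb block follow a single
Gamma(2)-distributed intensity field, so indel density tracks SNP density
along the genome (observed window-density correlation r ≈ 0.8–0.98,
emulating the strong SNP–indel spatial correlation in real panels).
Indel anchors sit on a jittered per-block grid so that no two footprints
(anchor + up to 13 deleted bases) overlap and the genotype matrix stays
biallelic and well defined.

**Alleles.** SNPs are transitions with probability 0.58 (giving Ts/Tv
≈ 1.35–1.45, the range reported for grass panels). Indel lengths 1–13 bp
follow a default weight table with 80% of mass on 1–3 bp; inside CDS the
weights of multiple-of-3 lengths are multiplied by `exon_frame_bias`
(default 3) and renormalized, reproducing the frame-preservation
enrichment of exonic indels. Insertions and deletions are equally likely.

**Carrier patterns.** Each variant first selects a source group, then
includes each group member with probability `p_in` and each outsider with
`p_out`; empty patterns are redrawn. The defaults encode the study
conditions: 8 accessions as two similar pairs (target within-pair
similarity `s_in` = 0.9) plus four mutually divergent accessions
(`s_out` = 0.6). `(p_in, p_out)` *and the per-group selection weights*
are calibrated jointly by bounded least squares on the implied pairwise
discordance moments — size-proportional selection weights cannot reach
low cross-group similarity between small groups, so the weights are free
calibration parameters (they come out near-uniform for the default
panel). Realized similarities land within ±0.02 of target for
cross-group pairs and within ≈0.015 of target for within-pair values at
≥5 000 loci (the residual offset comes from conditioning on non-empty
patterns). Rare alleles arise naturally: ≈40% of loci are singletons
under the defaults.

**Heterozygosity.** Residual heterozygosity is applied cell-wise at SNP
loci at `het_rate` (default 0.005, i.e. low, as expected for inbred
lines). Heterozygous *indel* cells are not modeled; this keeps the two
read haplotypes coordinate-compatible.

Carrier patterns are i.i.d. across loci: there is **no linkage decay**.
Consequence: imputation-window sweeps on generated panels keep improving
slowly with window size instead of peaking at a small window, because a
larger window only averages noise and never dilutes local haplotype
signal. The similarity/subset conclusions are unaffected, but the
location of the window optimum on real data (small windows) is not
reproduced by this generator.

## Read simulation

`simulate_reads` builds the accession's haplotype by applying its
homozygous variants to the reference (with an explicit block map back to
reference coordinates, used for truth labels), plus a second haplotype
differing at heterozygous SNPs; each read picks a haplotype uniformly.

- **RAD**: reads start exactly at the enzyme's cut positions on the
  accession sequence, in both orientations, with per-site per-direction
  depth ~ negative binomial (mean `mean_site_depth`, dispersion
  `depth_dispersion`; dispersion ≥ 10⁶ falls back to Poisson). An
  optional `site_dropout` probability removes whole sites, standing in
  for biological undersampling of restriction sites (e.g. methylation),
  which is not modeled mechanistically.
- **ncRS (star activity)**: a configurable fraction of RAD reads
  (default 0.12) originates at genome positions whose motif-length window
  violates the recognition motif at exactly one position; windows
  matching the motif with its degenerate codes complemented in place
  (YCCGGR for RCCGGY) are up-weighted so they receive 27% of the ncRS
  mass — the one distributional fact known about star-activity origins.
  The reported spatial correlation of ncRS with canonical sites is *not*
  modeled.
- **SR (semirandom)**: an HpaII (`CCGG`) digest of the accession
  sequence, fragments size-selected to 200–2000 bp, read starts uniform
  within eligible fragments.
- **Errors and qualities**: per-base substitution at `error_rate`
  (default 0.001); phreds from a discretized normal (mean 30, sd 5,
  clipped to [2, 41]). Erroneous bases are *not* flagged by low quality —
  the conservative choice for testing quality filters.

Raw read length defaults to 60 so that the 4-base 3'-trim in QC yields
56-base reads, the trimmed length of the study's BsrFI library (the SR
default of 36 trims to 32 likewise).

## Digestion

Site discovery compiles the IUPAC motif to a character-class regex and
scans both strands with overlapping matches; palindromic motifs are
scanned once. A brute-force position-by-position scan serves as the test
oracle. "Unique best alignment" of a site's two flanking reads is
implemented as exact-occurrence uniqueness over both strands (count = 1);
mismatch-tolerant realignment would change little at synthetic scale and
exact matching is oracle-checkable. Cut offsets: PstI `CTGCA^G` → 5,
BsrFI `R^CCGGY` → 1.

## Alignment and SNP calling

The aligner is ungapped and exhaustive within its mismatch bound: a
pigeonhole k-mer index (k = ⌊L/3⌋ for the default bound of 2 mismatches)
proposes every placement that could have ≤ 2 mismatches; a read is kept
only if the minimum-mismatch placement is unique over both strands.
Because it is ungapped, reads spanning indels misalign; indel calling
from alignments is therefore out of scope and indels reach downstream
stages from truth or user VCFs. Calling experiments that require exact
truth recovery use SNP-only panels.

Two filters mirror the published parameter sets:

- **simple**: some single alternative base with ≥ 6 supporting reads
  (pooled over accessions, counted per allele) whose phreds average
  ≥ 20; score = mean supporting phred.
- **quality model**: variant quality = −10 log₁₀ P(all alternative
  observations are errors) under independent per-base error rates
  floored at 10⁻³ — i.e. the sum of supporting phreds capped at 30
  each, total capped at 255 — gated at pooled depth ≥ 3 and quality ≥ 20
  (SNPs) or ≥ 50 (externally supplied indel records).

Per-accession genotypes use alternative-allele fraction cutoffs 0.2/0.8
(HET between them), with the caller's minimum depth per accession;
these cutoffs are plumbing, not a published rule. Note the quality model
ignores reference-supporting evidence by construction, so on
error-containing data a single high-quality error read can reach the
score threshold; its genome-wide precision at threshold 20 is
correspondingly modest, while the confirmation-versus-threshold curve
machinery quantifies the trade-off.

Validation is exact set arithmetic on (chrom, pos, alt) keys, optionally
restricted to regions; confirmation = confirmed/called, recall =
confirmed/true.

## Annotation

Feature classification paints per-chromosome priority arrays
(splice_site > CDS > UTR > intron > repeat > intergenic); splice sites
are the canonical first/last two intron bases. Coding effects assemble
the spliced CDS in transcription order (reverse-complemented for minus
strand) and classify the codon change with the standard genetic code;
large effect ⇔ stop_gained, stop_lost or splice_disrupting. "Exons" in
the large-effect definition means CDS — only there can a sense/nonsense
shift occur. A full-CDS mutate-translate-diff oracle backs the tests.

Because the generator applies no selection, the nonsynonymous/synonymous
ratio of unbiased synthetic SNPs is the codon-opportunity ratio (~2.4–3),
not the sub-1 ratios seen in real panels under purifying selection; the
package reports the ratio but the generator makes no attempt to emulate
selection.

Family large-effect densities use covered genic kilobases as the
denominator and retain families with strictly more than `min_covered`
covered bases (default 100 kb; desk-scale analyses pass a smaller value).
The two-proportion frame-preservation test uses the pooled z statistic
(statsmodels).

## Diversity statistics

Similarity, SNP density, coverage spectra, SFS/FSFS, allele-sharing
profiles and haplotype-sharing windows follow the definitions in the
README. Implementation notes: per-locus allele identity is
`2 − |g_i − g_j|` under the coding REF_HOM = 0, HET = 1, ALT_HOM = 2;
SFS counts HET as not carrying the alternative allele by default (a
half-count mode exists); the reference accession is only the polarity
anchor, not an SFS sample; loci fixed for the alternative allele appear
in unfolded bin n but have no folded bin (minor count 0), so the folded
total equals the unfolded total over bins 1..n−1. Haplotype-sharing
windows are non-overlapping runs of 50 loci with tier thresholds
(default 0.3/0.5/0.7) on the shared-genotype fraction of a chosen
homozygote class.

## Imputation

For each missing cell (accession a, locus t): every other accession —
plus an all-REF_HOM reference row when `include_reference` — that is
non-missing at t is a candidate donor. Donor similarity is the match
fraction over up to `window` loci non-missing in both a and the donor on
each side of t within the same chromosome (t itself excluded); zero
comparable loci define similarity 0. Donors below `min_similarity` are
rejected; the maximum-similarity donor wins, ties resolved by fixed
priority (reference first, then accession order) — which uniquely makes
window 0 impute everything as the reference homozygote, reproducing the
all-reference baseline whose accuracy is exactly the reference-genotype
fraction of the masked cells. Heterozygous cells are neither targets nor
donors and pass through unchanged. The scan is vectorized per
(target, donor) pair with cumulative-sum window queries, so the
exhaustive 2⁸-subset analysis on a 12 000-locus panel runs in seconds.

Evaluation: masking draws uniformly from homozygous non-missing cells
(5% or 10%); `accuracy_imputed` = correct / (masked ∩ imputed) and
`accuracy_all` = correct / masked (unfilled cells count as errors) are
both reported because the single published "proportion correctly
imputed" does not distinguish them (they coincide at threshold 0).
Window sweeps reuse one mask across windows; subset analysis imputes
each subset member from the other members plus the reference and reports
the subset's mean pairwise similarity including the reference row; SNP
subsampling reruns mask-and-score on seeded locus subsets; the
read-resampling curve reruns QC → pileup → call on cumulative seeded
read samples (alignment is per-read and computed once — a pure-function
cache, not an approximation).

## Problem sizes and seeds

All analyses and tests run on generated data: genomes of 40–200 kb, 1–2
chromosomes, panels of 8 accessions with ~1 000–12 000 loci, read sets of
10⁴–10⁵ reads. These sizes were chosen so each analysis completes in
seconds while every statistic retains enough resolution for its
tolerance (e.g. ±0.05 on similarity targets at ≥5 000 loci). Every
stochastic entry point takes an explicit seed, and (config, seed) →
byte-identical outputs is enforced by the pipeline's checksum manifest.

## Known limitations

- No linkage decay in carrier patterns (window-optimum location not
  reproduced; see above).
- No selection (nonsynonymous/synonymous ratio reflects codon
  opportunity only).
- Ungapped aligner: indel-spanning reads misalign; indel discovery from
  reads is out of scope.
- ncRS origins are spatially uniform; their reported clustering near
  canonical sites is not modeled.
- No paired-end reads, PCR duplicates, quality-by-cycle decay, or
  methylation-state modeling (site dropout is a single probability).
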