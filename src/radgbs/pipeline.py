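"""End-to-end orchestration of the synthetic RAD-seq study.

``run_pipeline`` executes the full stage order — simulate a panel and
its libraries, digest, QC/align/call, validate against truth, annotate,
compute diversity statistics, impute with masking evaluation — writing
every table under a run directory with a checksum MANIFEST.tsv, so a
rerun with the same configuration reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann_mod
from . import calling, digest, diversity, impute, io, simulate
from .model import MISSING, ReadSet, ValidationError

__all__ = ["RunConfig", "load_config", "run_pipeline", "report"]

log = logging.getLogger("radgbs")


@dataclass
class RunConfig:
    """Flat configuration for a pipeline run; every stochastic stage
    derives its seed from ``seed``."""

    seed: int
    genome_length: int = 200_000
    n_chroms: int = 2
    gc_content: float = 0.44
    gene_density: float = 2.0
    repeat_density: float = 0.05
    panel: dict = field(default_factory=dict)       # PanelConfig overrides
    library: dict = field(default_factory=dict)     # LibraryConfig overrides
    mask_fraction: float = 0.10
    impute_window: int = 10
    min_similarity: float = 0.0
    windows: list[int] = field(default_factory=lambda: [0, 2, 5, 10, 20, 50])
    run_subset_analysis: bool = False
    run_sr_library: bool = False


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in raw:
        raise ValidationError("config must set a seed")
    return RunConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage; returns the in-memory results keyed by stage."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": config}
    rng_seed = int(config.seed)

    log.info("stage simulate: genome %d bp", config.genome_length)
    genome, annotation = simulate.generate_reference(
        config.genome_length, config.n_chroms, config.gc_content,
        config.gene_density, config.repeat_density, seed=rng_seed,
    )
    io.write_fasta(genome, out / "genome.fa")
    io.write_gff3(annotation, out / "annotation.gff3")
    panel = simulate.PanelConfig(seed=rng_seed + 1, **config.panel)
    truth = simulate.generate_panel_variants(genome, annotation, panel)
    io.write_genotypes(truth, out / "truth.vcf", contig_lengths=genome.lengths())
    io.write_genotypes(truth, out / "truth.tsv")
    library = simulate.LibraryConfig(seed=rng_seed + 2, **config.library)
    reads = ReadSet()
    for acc in panel.accessions:
        reads.extend(simulate.simulate_reads(genome, truth, library, acc))
    io.write_fastq(reads, out / "reads.fastq")
    results.update(genome=genome, annotation=annotation, truth=truth,
                   reads=reads, panel=panel, library=library)

    log.info("stage digest: %s", library.enzyme.name)
    dig = digest.fragment_table(digest.find_sites(genome, library.enzyme),
                                genome)
    dig.fragments.to_csv(out / "fragments.tsv", sep="\t", index=False)
    uniq = digest.site_read_uniqueness(genome, library.enzyme,
                                       read_length=min(36, library.read_length))
    uniq.to_csv(out / "site_uniqueness.tsv", sep="\t", index=False)
    sat = digest.coverage_saturation(reads, (1, 2), seed=rng_seed + 3)
    sat.to_csv(out / "site_saturation.tsv", sep="\t", index=False)
    results.update(digest=dig, uniqueness=uniq, saturation=sat)

    log.info("stage call: %d raw reads", len(reads))
    clean = calling.preprocess_reads(reads)
    alignments = calling.align_unique(genome, clean)
    pile = calling.build_pileup(genome, alignments, clean)
    simple = calling.call_simple_filter(pile)
    model = calling.call_quality_model(pile)
    rep_simple, curve_simple = calling.validate(simple, truth)
    rep_model, curve_model = calling.validate(model, truth)
    pd.DataFrame([
        ("simple", rep_simple.n_true, rep_simple.n_called,
         rep_simple.n_confirmed, rep_simple.confirmation_rate,
         rep_simple.recall),
        ("quality_model", rep_model.n_true, rep_model.n_called,
         rep_model.n_confirmed, rep_model.confirmation_rate,
         rep_model.recall),
    ], columns=["caller", "n_true", "n_called", "n_confirmed",
                "confirmation_rate", "recall"]
    ).to_csv(out / "validation.tsv", sep="\t", index=False)
    curve_model.to_csv(out / "confirmation_curve.tsv", sep="\t", index=False)
    called = model.to_genotype_matrix()
    io.write_genotypes(called, out / "called.tsv")
    results.update(pileup=pile, simple=simple, model=model,
                   validation={"simple": rep_simple, "quality_model": rep_model},
                   called=called, alignments=alignments)

    log.info("stage annotate")
    index = ann_mod.FeatureIndex(genome, annotation)
    snps = truth.loci[truth.loci["vtype"] == "SNP"]
    effects = [
        ann_mod.coding_effect(genome, annotation, index, r.chrom, r.pos,
                              r.ref, r.alt)
        for r in snps.itertuples(index=False)
    ]
    eff_df = pd.DataFrame([vars(e) for e in effects])
    eff_df.to_csv(out / "effects.tsv", sep="\t", index=False)
    indels = truth.loci[truth.loci["vtype"] != "SNP"]
    indel_stats = ann_mod.indel_feature_stats(indels, index)
    indel_stats["histograms"].to_csv(out / "indel_lengths.tsv", sep="\t",
                                     index=False)
    fam = ann_mod.large_effect_density_by_family(
        effects, annotation, pile.coverage, min_covered=10_000)
    fam.to_csv(out / "family_density.tsv", sep="\t", index=False)
    tstv = ann_mod.ts_tv(snps)
    density = ann_mod.window_density(truth.loci, genome.lengths(),
                                     window_kb=20, offset_kb=10)
    density.to_csv(out / "window_density.tsv", sep="\t", index=False)
    results.update(effects=eff_df, indel_stats=indel_stats, ts_tv=tstv,
                   family_density=fam)

    log.info("stage diversity")
    sim = diversity.pairwise_similarity(truth, include_reference=True)
    sim.to_frame().to_csv(out / "similarity.tsv", sep="\t")
    dens = diversity.pairwise_snp_density(truth, pile.coverage)
    dens.to_csv(out / "snp_density.tsv", sep="\t")
    spectrum = diversity.sfs(truth)
    pd.DataFrame({
        "alt_count": np.arange(1, truth.n_accessions + 1),
        "unfolded": spectrum.unfolded,
    }).to_csv(out / "sfs.tsv", sep="\t", index=False)
    results.update(similarity=sim, snp_density=dens, sfs=spectrum)

    log.info("stage impute")
    params = impute.ImputeParams(window=config.impute_window,
                                 min_similarity=config.min_similarity)
    observed = _observed_matrix(truth, called)
    masked = impute.mask_and_score(observed, config.mask_fraction,
                                   seed=rng_seed + 4, params=params)
    sweep = impute.window_sweep(observed, config.windows,
                                config.mask_fraction, seed=rng_seed + 4,
                                params=params)
    sweep.to_csv(out / "window_sweep.tsv", sep="\t", index=False)
    results.update(imputation=masked, window_sweep=sweep)
    if config.run_subset_analysis:
        subsets = impute.subset_analysis(observed, config.mask_fraction,
                                         seed=rng_seed + 4, params=params)
        subsets.to_csv(out / "subset_analysis.tsv", sep="\t", index=False)
        results["subset_analysis"] = subsets

    report(results, out)
    manifest = pd.DataFrame(
        sorted((p.name, _sha256(p)) for p in out.iterdir()
               if p.is_file() and p.name != "MANIFEST.tsv"),
        columns=["file", "sha256"],
    )
    manifest.to_csv(out / "MANIFEST.tsv", sep="\t", index=False)
    results["manifest"] = manifest
    return results


def _observed_matrix(truth, called):
    """Truth loci with genotypes observed by the caller; unobserved
    genotypes are MISSING, which is what imputation then fills."""
    obs = truth.copy()
    key_to_row = {
        (r.chrom, r.pos): i
        for i, r in enumerate(called.loci.itertuples(index=False))
    }
    codes = np.full_like(obs.codes, MISSING)
    acc_idx = [called.accessions.index(a) if a in called.accessions else -1
               for a in obs.accessions]
    for i, r in enumerate(obs.loci.itertuples(index=False)):
        j = key_to_row.get((r.chrom, r.pos))
        if j is not None:
            for k, aj in enumerate(acc_idx):
                if aj >= 0:
                    codes[i, k] = called.codes[j, aj]
    obs.codes = codes
    return obs


def report(results: dict, outdir) -> Path:
    """Human-readable run summary; every number restates a stage table."""
    out = Path(outdir)
    lines = ["# radgbs run summary", ""]
    truth = results.get("truth")
    if truth is not None:
        lines += [f"truth loci: {truth.n_loci} "
                  f"({int((truth.loci['vtype'] == 'SNP').sum())} SNPs), "
                  f"accessions: {truth.n_accessions}"]
    if "reads" in results:
        reads = results["reads"]
        n_ncrs = sum(r.origin_class == "ncRS" for r in reads)
        lines += [f"reads: {len(reads)} (ncRS fraction "
                  f"{n_ncrs / max(len(reads), 1):.3f})"]
    if "validation" in results:
        for caller, rep in results["validation"].items():
            lines += [
                f"{caller}: called {rep.n_called}, confirmed "
                f"{rep.n_confirmed}/{rep.n_true} true "
                f"(confirmation {rep.confirmation_rate:.3f}, "
                f"recall {rep.recall:.3f})"
            ]
    if "ts_tv" in results:
        lines += [f"Ts/Tv: {results['ts_tv']:.3f}"]
    if "similarity" in results:
        lines += ["mean pairwise similarity: "
                  f"{results['similarity'].mean_pairwise():.3f}"]
    if "imputation" in results:
        imp = results["imputation"]
        lines += [f"imputation: accuracy_all {imp.accuracy_all:.3f}, "
                  f"accuracy_imputed {imp.accuracy_imputed:.3f}, "
                  f"call rate {imp.call_rate:.3f}"]
    if "window_sweep" in results:
        ws = results["window_sweep"]
        best = ws.loc[ws["accuracy_all"].idxmax()]
        lines += [f"best window: {int(best['window'])} "
                  f"(accuracy_all {best['accuracy_all']:.3f})"]
    text = "\n".join(lines) + "\n"
    path = out / "summary.txt"
    path.write_text(text)
    return path
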