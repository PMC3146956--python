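"""Windowed local-haplotype genotype imputation and its evaluation.

Each missing genotype in a target accession is filled from the donor
accession (optionally including an all-reference-homozygote row) whose
genotypes best match the target's over a window of up to ``window``
nonmissing-in-both loci on each side of the target locus, within the
same chromosome.  Donors below ``min_similarity`` are rejected; ties
are broken by a fixed priority (reference first, then accession
order), which uniquely reproduces the window-0 behavior of imputing
every missing genotype as the reference homozygote.

Heterozygous calls are never used: they are neither imputation targets
nor donor evidence (an inbred panel's rare heterozygotes can neither
be imputed nor inform imputation), and they pass through unchanged.

Evaluation machinery: random masking of homozygous cells with exact
accuracy bookkeeping, window sweeps, exhaustive accession-subset
analysis, SNP subsampling, and read-resampling saturation curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd

from .model import ALT_HOM, HET, MISSING, REF_HOM, GenotypeMatrix, ReadSet, ReferenceGenome

__all__ = [
    "ImputeParams",
    "ImputationResult",
    "impute",
    "mask_and_score",
    "window_sweep",
    "subset_analysis",
    "snp_subsample_accuracy",
    "read_resample_yield",
]

REFERENCE_ID = "REF"


@dataclass
class ImputeParams:
    """window: loci on either side of the target used for donor scoring;
    min_similarity: acceptance threshold on the donor match fraction;
    include_reference: add the all-REF_HOM reference haplotype as a donor."""

    window: int = 10
    min_similarity: float = 0.0
    include_reference: bool = True

    def __post_init__(self) -> None:
        if self.window < 0:
            raise ValueError("window must be non-negative")
        if not (0.0 <= self.min_similarity <= 1.0):
            raise ValueError("min_similarity must be in [0, 1]")


@dataclass
class ImputationResult:
    matrix: GenotypeMatrix
    provenance: pd.DataFrame  # accession, chrom, pos, donor, similarity, n_compared
    n_missing: int
    n_imputed: int
    accuracy_imputed: float = float("nan")
    accuracy_all: float = float("nan")
    n_masked: int = 0
    masked_cells: Optional[np.ndarray] = None

    @property
    def call_rate(self) -> float:
        return self.n_imputed / self.n_missing if self.n_missing else float("nan")


def _impute_codes(codes: np.ndarray, chrom_arr: np.ndarray,
                  accessions: list[str], params: ImputeParams,
                  donor_cols: Optional[list[int]] = None,
                  target_cols: Optional[list[int]] = None,
                  ) -> tuple[np.ndarray, list[tuple]]:
    """Fill MISSING cells of ``codes`` in place on a copy; returns the
    filled array and provenance tuples (col, row, donor, sim, n_comp).

    ``donor_cols`` restricts which accession columns may donate
    (targets are still all columns).  HET cells are treated as missing
    for both donor and target purposes but are never overwritten.
    """
    work = codes.copy()
    work[work == HET] = MISSING
    filled = codes.copy()
    prov: list[tuple] = []
    n_acc = codes.shape[1]
    if donor_cols is None:
        donor_cols = list(range(n_acc))
    w = params.window
    # process per chromosome block (loci are sorted by chrom)
    blocks = []
    start = 0
    for i in range(1, len(chrom_arr) + 1):
        if i == len(chrom_arr) or chrom_arr[i] != chrom_arr[start]:
            blocks.append((start, i))
            start = i
    if target_cols is None:
        target_cols = list(range(n_acc))
    for b0, b1 in blocks:
        sub = work[b0:b1]
        for a in target_cols:
            targets = np.flatnonzero(codes[b0:b1, a] == MISSING)
            if len(targets) == 0:
                continue
            a_present = sub[:, a] != MISSING
            best_sim = np.full(len(targets), -1.0)
            best_val = np.full(len(targets), MISSING, dtype=np.int8)
            best_donor = np.full(len(targets), -1, dtype=np.int64)
            best_ncmp = np.zeros(len(targets), dtype=np.int64)
            donors: list[tuple[int, Optional[np.ndarray]]] = []
            if params.include_reference:
                donors.append((-1, None))  # virtual reference row
            donors += [(d, sub[:, d]) for d in donor_cols if d != a]
            for rank, (d, dcol) in enumerate(donors):
                if d == -1:
                    comp = np.flatnonzero(a_present)
                    match = sub[comp, a] == REF_HOM
                    eligible = np.ones(len(targets), dtype=bool)
                    dvals = np.full(len(targets), REF_HOM, dtype=np.int8)
                else:
                    comp = np.flatnonzero(a_present & (dcol != MISSING))
                    match = sub[comp, a] == dcol[comp]
                    dvals = dcol[targets]
                    eligible = dvals != MISSING
                if w > 0 and len(comp):
                    cs = np.concatenate([[0], np.cumsum(match)])
                    pos = np.searchsorted(comp, targets)
                    lo = np.maximum(pos - w, 0)
                    hi = np.minimum(pos + w, len(comp))
                    matched = cs[hi] - cs[lo]
                    n_comp = hi - lo
                    with np.errstate(invalid="ignore"):
                        sim = np.where(n_comp > 0, matched / np.maximum(n_comp, 1),
                                       0.0)
                else:
                    sim = np.zeros(len(targets))
                    n_comp = np.zeros(len(targets), dtype=np.int64)
                ok = eligible & (sim >= params.min_similarity) & (sim > best_sim)
                best_val[ok] = dvals[ok]
                best_sim[ok] = sim[ok]
                best_donor[ok] = rank
                best_ncmp[ok] = n_comp[ok] if np.ndim(n_comp) else 0
            won = best_donor >= 0
            rows = targets[won]
            filled[b0 + rows, a] = best_val[won]
            donor_ids = [
                REFERENCE_ID if donors[r][0] == -1 else accessions[donors[r][0]]
                for r in best_donor[won]
            ]
            prov.extend(zip(
                [a] * len(rows), (b0 + rows).tolist(), donor_ids,
                best_sim[won].tolist(), best_ncmp[won].tolist(),
            ))
    return filled, prov


def impute(matrix: GenotypeMatrix, params: ImputeParams) -> ImputationResult:
    """Impute every MISSING cell that some acceptable donor can fill.

    Deterministic; originally nonmissing cells (including HET) are
    never overwritten, and provenance records the winning donor, its
    similarity and the number of loci compared for every filled cell.
    """
    chrom_arr = matrix.loci["chrom"].to_numpy()
    filled, prov = _impute_codes(matrix.codes, chrom_arr,
                                 matrix.accessions, params)
    n_missing = int((matrix.codes == MISSING).sum())
    n_imputed = int(((matrix.codes == MISSING) & (filled != MISSING)).sum())
    pos_arr = matrix.loci["pos"].to_numpy()
    prov_df = pd.DataFrame(
        [(matrix.accessions[a], chrom_arr[r], int(pos_arr[r]), d, s, int(nc))
         for a, r, d, s, nc in prov],
        columns=["accession", "chrom", "pos", "donor", "similarity",
                 "n_compared"],
    )
    out = GenotypeMatrix(matrix.loci.copy(), list(matrix.accessions), filled)
    return ImputationResult(out, prov_df, n_missing, n_imputed)


def _draw_mask(matrix: GenotypeMatrix, mask_fraction: float,
               rng: np.random.Generator,
               cols: Optional[list[int]] = None) -> np.ndarray:
    hom = (matrix.codes == REF_HOM) | (matrix.codes == ALT_HOM)
    if cols is not None:
        keep = np.zeros(matrix.n_accessions, dtype=bool)
        keep[cols] = True
        hom &= keep[None, :]
    flat = np.flatnonzero(hom.ravel())
    n_mask = int(round(mask_fraction * len(flat)))
    if n_mask < 1 or n_mask >= len(flat):
        raise ValueError(
            f"mask of {n_mask} cells infeasible with {len(flat)} eligible cells"
        )
    return rng.choice(flat, size=n_mask, replace=False)


def _score(result_codes: np.ndarray, truth_codes: np.ndarray,
           masked_flat: np.ndarray) -> tuple[float, float, int]:
    truth_vals = truth_codes.ravel()[masked_flat]
    imput_vals = result_codes.ravel()[masked_flat]
    imputed = imput_vals != MISSING
    correct = imput_vals == truth_vals
    acc_imp = (correct[imputed].mean() if imputed.any() else float("nan"))
    acc_all = correct.mean()
    return float(acc_imp), float(acc_all), int(len(masked_flat))


def mask_and_score(matrix: GenotypeMatrix, mask_fraction: float, seed: int,
                   params: ImputeParams,
                   mask_flat: Optional[np.ndarray] = None) -> ImputationResult:
    """Hold out homozygous cells, impute, and score against the truth.

    ``accuracy_imputed`` is correct / (masked and imputed);
    ``accuracy_all`` is correct / masked (cells left missing count as
    errors).  The mask is drawn uniformly from homozygous nonmissing
    cells under ``seed`` (or supplied via ``mask_flat``).
    """
    rng = np.random.default_rng(seed)
    if mask_flat is None:
        mask_flat = _draw_mask(matrix, mask_fraction, rng)
    masked = matrix.copy()
    masked.codes.ravel()[mask_flat] = MISSING
    result = impute(masked, params)
    acc_imp, acc_all, n_masked = _score(result.matrix.codes, matrix.codes,
                                        mask_flat)
    result.accuracy_imputed = acc_imp
    result.accuracy_all = acc_all
    result.n_masked = n_masked
    result.masked_cells = mask_flat
    return result


def window_sweep(matrix: GenotypeMatrix, windows, mask_fraction: float,
                 seed: int, params: ImputeParams) -> pd.DataFrame:
    """Accuracy versus window size, reusing one mask across windows."""
    rng = np.random.default_rng(seed)
    mask_flat = _draw_mask(matrix, mask_fraction, rng)
    rows = []
    for w in windows:
        p = ImputeParams(window=int(w), min_similarity=params.min_similarity,
                         include_reference=params.include_reference)
        res = mask_and_score(matrix, mask_fraction, seed, p,
                             mask_flat=mask_flat)
        rows.append((int(w), res.call_rate, res.accuracy_imputed,
                     res.accuracy_all))
    return pd.DataFrame(rows, columns=["window", "call_rate",
                                       "accuracy_imputed", "accuracy_all"])


def subset_analysis(matrix: GenotypeMatrix, mask_fraction: float, seed: int,
                    params: ImputeParams, max_n: int = 12) -> pd.DataFrame:
    """Imputation accuracy for every non-empty proper accession subset.

    Each subset member is imputed using only the other subset members
    (plus the reference); accuracy is scored over the masked cells
    belonging to subset members.  Also reports the subset's mean
    pairwise genomic similarity including the reference row.
    """
    from .diversity import pairwise_similarity

    n = matrix.n_accessions
    if n > max_n:
        raise ValueError(
            f"{n} accessions would enumerate 2^{n} subsets; "
            "sample subsets instead"
        )
    rng = np.random.default_rng(seed)
    mask_flat = _draw_mask(matrix, mask_fraction, rng)
    masked = matrix.copy()
    masked.codes.ravel()[mask_flat] = MISSING
    sim = pairwise_similarity(matrix, include_reference=True)
    chrom_arr = matrix.loci["chrom"].to_numpy()
    cols_of_mask = mask_flat % n
    rows = []
    for size in range(1, n):
        for subset in combinations(range(n), size):
            filled, _ = _impute_codes(masked.codes, chrom_arr,
                                      matrix.accessions, params,
                                      donor_cols=list(subset),
                                      target_cols=list(subset))
            in_subset = np.isin(cols_of_mask, subset)
            cells = mask_flat[in_subset]
            if len(cells) == 0:
                continue
            acc_imp, acc_all, n_masked = _score(filled, matrix.codes, cells)
            members = [matrix.accessions[i] for i in subset]
            mean_sim = sim.mean_pairwise([REFERENCE_ID] + members)
            rows.append((",".join(members), size, mean_sim, acc_imp,
                         acc_all, n_masked))
    return pd.DataFrame(rows, columns=[
        "subset", "size", "mean_similarity", "accuracy_imputed",
        "accuracy_all", "n_masked",
    ])


def snp_subsample_accuracy(matrix: GenotypeMatrix, proportions,
                           mask_fraction: float, seed: int,
                           params: ImputeParams) -> pd.DataFrame:
    """Imputation accuracy on random locus subsamples.

    Each proportion keeps that fraction of loci (seeded, without
    replacement), reruns mask-and-score, and reports accuracy with its
    binomial standard error.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for p in proportions:
        if not (0 < p <= 1):
            raise ValueError("proportions must be in (0, 1]")
        if p == 1.0:
            sub = matrix
        else:
            keep = np.zeros(matrix.n_loci, dtype=bool)
            k = max(1, int(round(p * matrix.n_loci)))
            keep[rng.choice(matrix.n_loci, size=k, replace=False)] = True
            sub = matrix.subset_loci(keep)
        eff = params
        if sub.n_loci <= params.window:
            warnings.warn("subsample smaller than window; truncating window")
            eff = ImputeParams(window=max(sub.n_loci - 1, 0),
                               min_similarity=params.min_similarity,
                               include_reference=params.include_reference)
        res = mask_and_score(sub, mask_fraction, seed, eff)
        se = float(np.sqrt(res.accuracy_all * (1 - res.accuracy_all)
                           / res.n_masked))
        rows.append((float(p), sub.n_loci, res.accuracy_imputed,
                     res.accuracy_all, se, res.n_masked))
    return pd.DataFrame(rows, columns=[
        "proportion", "n_loci", "accuracy_imputed", "accuracy_all",
        "se", "n_masked",
    ])


def read_resample_yield(genome: ReferenceGenome, readset: ReadSet,
                        increment: int, seed: int,
                        caller: str = "quality_model",
                        caller_kwargs: Optional[dict] = None) -> pd.DataFrame:
    """SNP genotypes called versus number of reads sampled.

    Reads are shuffled under ``seed`` and accumulated in increments;
    for each cumulative sample the QC -> align -> pileup -> call path
    is evaluated (alignment is per-read and therefore computed once)
    and the number of nonmissing genotype calls at candidate SNP loci
    recorded.
    """
    from .calling import (align_unique, build_pileup, call_quality_model,
                          call_simple_filter, preprocess_reads)

    caller_kwargs = caller_kwargs or {}
    clean = preprocess_reads(readset)
    alignments = align_unique(genome, clean)
    by_read = {a.read_index: a for a in alignments}
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(clean))
    rows = []
    checkpoints = list(range(increment, len(clean), increment)) + [len(clean)]
    for n in checkpoints:
        chosen = order[:n]
        sub_reads = ReadSet([clean.reads[i] for i in chosen])
        sub_aln = []
        for new_idx, old_idx in enumerate(chosen):
            a = by_read.get(int(old_idx))
            if a is not None:
                sub_aln.append(type(a)(new_idx, a.chrom, a.pos, a.strand,
                                       a.n_mismatches, a.mismatches, a.length))
        pile = build_pileup(genome, sub_aln, sub_reads)
        if caller == "simple":
            cands = call_simple_filter(pile, **caller_kwargs)
        else:
            cands = call_quality_model(pile, **caller_kwargs)
        rows.append((int(n), len(cands.table), cands.n_genotypes_called()))
    return pd.DataFrame(rows, columns=["reads_sampled", "n_candidates",
                                       "n_genotypes"])
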