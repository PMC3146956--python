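"""Windowed local-haplotype imputation: window-0 reference behavior,
donor selection, masking accuracy bookkeeping, sweeps, subset analysis,
SNP subsampling and read-resampling yield."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from radgbs import impute, simulate
from radgbs.model import ALT_HOM, HET, MISSING, REF_HOM
from tests.conftest import make_matrix


@pytest.fixture(scope="module")
def structured_matrix(small_genome):
    genome, annotation = small_genome
    config = simulate.PanelConfig(seed=23, snp_density=40.0, indel_density=0.5)
    truth = simulate.generate_panel_variants(genome, annotation, config)
    return truth


class TestImpute:
    def test_window_zero_with_reference_fills_ref_hom(self, structured_matrix):
        m = structured_matrix.copy()
        rng = np.random.default_rng(0)
        holes = rng.choice(m.codes.size, 200, replace=False)
        m.codes.ravel()[holes] = MISSING
        res = impute.impute(m, impute.ImputeParams(window=0))
        filled = res.matrix.codes.ravel()[holes]
        assert (filled == REF_HOM).all()
        assert (res.provenance["donor"] == impute.REFERENCE_ID).all()
        assert res.call_rate == 1.0

    def test_identical_donor_wins(self):
        # accession 1's row equals donor 2 over the window; donor 3 differs
        codes = np.array([
            [ALT_HOM, ALT_HOM, REF_HOM],
            [ALT_HOM, ALT_HOM, REF_HOM],
            [MISSING, ALT_HOM, REF_HOM],
            [ALT_HOM, ALT_HOM, REF_HOM],
        ], dtype=np.int8)
        m = make_matrix(codes)
        res = impute.impute(m, impute.ImputeParams(window=2,
                                                   include_reference=False))
        assert res.matrix.codes[2, 0] == ALT_HOM
        assert res.provenance["donor"].item() == "A1"
        assert res.provenance["similarity"].item() == 1.0

    def test_min_similarity_gate(self):
        codes = np.array([
            [ALT_HOM, REF_HOM],
            [ALT_HOM, ALT_HOM],
            [MISSING, ALT_HOM],
            [ALT_HOM, REF_HOM],
            [ALT_HOM, ALT_HOM],
        ], dtype=np.int8)
        m = make_matrix(codes)
        res = impute.impute(m, impute.ImputeParams(
            window=2, min_similarity=0.9, include_reference=False))
        assert res.matrix.codes[2, 0] == MISSING
        assert res.n_imputed == 0 and res.call_rate == 0.0

    def test_het_cells_neither_target_nor_donor(self):
        codes = np.array([
            [ALT_HOM, ALT_HOM],
            [MISSING, HET],
            [ALT_HOM, ALT_HOM],
        ], dtype=np.int8)
        m = make_matrix(codes)
        res = impute.impute(m, impute.ImputeParams(window=1,
                                                   include_reference=False))
        # the donor's HET at the target locus cannot donate
        assert res.matrix.codes[1, 0] == MISSING
        # and the donor's HET itself is left untouched
        assert res.matrix.codes[1, 1] == HET

    def test_never_overwrites_nonmissing(self, structured_matrix):
        res = impute.impute(structured_matrix,
                            impute.ImputeParams(window=10))
        nonmissing = structured_matrix.codes != MISSING
        assert (res.matrix.codes[nonmissing]
                == structured_matrix.codes[nonmissing]).all()


class TestMaskAndScore:
    def test_window0_accuracy_equals_masked_ref_fraction(self,
                                                         structured_matrix):
        res = impute.mask_and_score(structured_matrix, 0.10, seed=5,
                                    params=impute.ImputeParams(window=0))
        truth_vals = structured_matrix.codes.ravel()[res.masked_cells]
        ref_frac = (truth_vals == REF_HOM).mean()
        assert res.accuracy_all == pytest.approx(ref_frac, abs=0)
        assert res.accuracy_imputed == pytest.approx(ref_frac, abs=0)

    def test_identical_accessions_perfectly_imputed(self):
        rng = np.random.default_rng(1)
        row = rng.choice([REF_HOM, ALT_HOM], 400)
        codes = np.stack([row, row, rng.choice([REF_HOM, ALT_HOM], 400)],
                         axis=1).astype(np.int8)
        m = make_matrix(codes)
        rng2 = np.random.default_rng(2)
        mask = impute._draw_mask(m, 0.10, rng2, cols=[0])
        res = impute.mask_and_score(
            m, 0.10, seed=2,
            params=impute.ImputeParams(window=10, include_reference=False),
            mask_flat=mask)
        assert res.accuracy_imputed == 1.0

    def test_same_seed_reproducible(self, structured_matrix):
        p = impute.ImputeParams(window=5)
        a = impute.mask_and_score(structured_matrix, 0.05, seed=9, params=p)
        b = impute.mask_and_score(structured_matrix, 0.05, seed=9, params=p)
        assert (a.masked_cells == b.masked_cells).all()
        assert a.accuracy_all == b.accuracy_all

    def test_mask_draws_only_homozygous_cells(self, structured_matrix):
        res = impute.mask_and_score(structured_matrix, 0.10, seed=3,
                                    params=impute.ImputeParams(window=5))
        truth_vals = structured_matrix.codes.ravel()[res.masked_cells]
        assert set(np.unique(truth_vals)) <= {REF_HOM, ALT_HOM}

    def test_infeasible_mask_errors(self):
        m = make_matrix(np.zeros((4, 2), dtype=np.int8))
        with pytest.raises(ValueError):
            impute.mask_and_score(m, 0.001, seed=0,
                                  params=impute.ImputeParams(window=1))


class TestWindowSweep:
    def test_window0_row_matches_direct_call(self, structured_matrix):
        p = impute.ImputeParams(window=0)
        sweep = impute.window_sweep(structured_matrix, [0, 5], 0.10,
                                    seed=7, params=p)
        direct = impute.mask_and_score(structured_matrix, 0.10, seed=7,
                                       params=p)
        row0 = sweep[sweep["window"] == 0].iloc[0]
        assert row0["accuracy_all"] == direct.accuracy_all

    def test_optimum_beats_window0_on_structured_panel(self,
                                                       structured_matrix):
        sweep = impute.window_sweep(structured_matrix,
                                    [0, 2, 5, 10, 20], 0.10, seed=7,
                                    params=impute.ImputeParams())
        best = sweep["accuracy_all"].max()
        at0 = sweep.loc[sweep["window"] == 0, "accuracy_all"].item()
        assert best >= at0
        assert sweep.loc[sweep["accuracy_all"].idxmax(), "window"] > 0


class TestSubsetAnalysis:
    def test_size_one_subset_is_reference_only(self, structured_matrix):
        df = impute.subset_analysis(structured_matrix, 0.10, seed=11,
                                    params=impute.ImputeParams(window=5))
        assert len(df) == 2 ** 8 - 2
        solo = df[df["subset"] == "Sb5"].iloc[0]
        # only donor is the reference: accuracy equals the masked REF
        # fraction for that accession
        rng = np.random.default_rng(11)
        mask = impute._draw_mask(structured_matrix, 0.10, rng)
        cols = mask % structured_matrix.n_accessions
        own = mask[cols == structured_matrix.accessions.index("Sb5")]
        ref_frac = (structured_matrix.codes.ravel()[own] == REF_HOM).mean()
        assert solo["accuracy_all"] == pytest.approx(ref_frac)

    def test_pair_partner_improves_accuracy(self, structured_matrix):
        df = impute.subset_analysis(structured_matrix, 0.10, seed=11,
                                    params=impute.ImputeParams(window=5))
        with_partner = df[df["subset"] == "Sb1,Sb2"].iloc[0]
        without = df[df["subset"] == "Sb1,Sb5"].iloc[0]
        assert with_partner["accuracy_all"] > without["accuracy_all"]
        assert with_partner["mean_similarity"] > without["mean_similarity"]

    def test_accuracy_increases_with_similarity(self, structured_matrix):
        df = impute.subset_analysis(structured_matrix, 0.10, seed=13,
                                    params=impute.ImputeParams(window=5))
        slope = np.polyfit(df["mean_similarity"], df["accuracy_all"], 1)[0]
        assert slope > 0


class TestSnpSubsample:
    def test_full_proportion_equals_direct(self, structured_matrix):
        p = impute.ImputeParams(window=5)
        df = impute.snp_subsample_accuracy(structured_matrix, [1.0], 0.10,
                                           seed=3, params=p)
        direct = impute.mask_and_score(structured_matrix, 0.10, seed=3,
                                       params=p)
        assert df["accuracy_all"].item() == direct.accuracy_all

    def test_sparse_subsample_holds_accuracy(self, structured_matrix):
        p = impute.ImputeParams(window=5)
        df = impute.snp_subsample_accuracy(structured_matrix,
                                           [0.05, 0.5, 1.0], 0.10,
                                           seed=3, params=p)
        assert df["proportion"].tolist() == [0.05, 0.5, 1.0]
        full = df[df["proportion"] == 1.0].iloc[0]
        sparse = df[df["proportion"] == 0.05].iloc[0]
        joint_se = np.hypot(full["se"], sparse["se"])
        assert abs(sparse["accuracy_all"] - full["accuracy_all"]) < 3 * joint_se


class TestReadResample:
    def test_yield_curve_monotone_and_endpoints(self, small_genome,
                                                structured_matrix):
        genome, _ = small_genome
        lib = simulate.LibraryConfig(seed=19, mean_site_depth=6.0,
                                     error_rate=0.0, ncrs_fraction=0.05)
        from radgbs.model import ReadSet
        reads = ReadSet()
        for acc in structured_matrix.accessions[:4]:
            reads.extend(simulate.simulate_reads(genome, structured_matrix,
                                                 lib, acc))
        curve = impute.read_resample_yield(genome, reads,
                                           increment=len(reads) // 4,
                                           seed=1)
        assert curve["n_genotypes"].is_monotonic_increasing
        assert len(curve) >= 4
        assert curve["n_candidates"].is_monotonic_increasing

    def test_all_reads_matches_full_data(self, small_genome,
                                         structured_matrix):
        genome, _ = small_genome
        lib = simulate.LibraryConfig(seed=19, mean_site_depth=5.0,
                                     error_rate=0.0)
        from radgbs.model import ReadSet
        from radgbs import calling
        reads = ReadSet()
        for acc in structured_matrix.accessions[:3]:
            reads.extend(simulate.simulate_reads(genome, structured_matrix,
                                                 lib, acc))
        curve = impute.read_resample_yield(genome, reads,
                                           increment=len(reads),
                                           seed=2)
        clean = calling.preprocess_reads(reads)
        aln = calling.align_unique(genome, clean)
        pile = calling.build_pileup(genome, aln, clean)
        full = calling.call_quality_model(pile).n_genotypes_called()
        assert curve["n_genotypes"].iloc[-1] == full


@settings(max_examples=20, deadline=None, derandomize=True)
@given(arrays(np.int8, (30, 4),
              elements=st.sampled_from([REF_HOM, HET, ALT_HOM, MISSING])),
       st.integers(0, 5))
def test_imputation_only_fills_missing_property(codes, window):
    m = make_matrix(codes)
    res = impute.impute(m, impute.ImputeParams(window=window))
    nonmissing = codes != MISSING
    assert (res.matrix.codes[nonmissing] == codes[nonmissing]).all()
    newly = (codes == MISSING) & (res.matrix.codes != MISSING)
    assert len(res.provenance) == newly.sum()
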