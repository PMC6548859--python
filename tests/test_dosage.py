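"""Dosage calling, the variant-filter cascade, and density binning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spudsel import simulate
from spudsel.dosage import call_dosages, density_bins, filter_variants
from spudsel.layout import GenomeLayout

from .conftest import make_counts, make_dosage, make_loci


class TestCallDosages:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            (10, 0, 1.0),  # AAAA
            (5, 5, 0.5),  # AABB: ref frequency 0.5
            (8, 2, 0.75),  # AAAB
            (2, 8, 0.25),  # ABBB
            (0, 10, 0.0),  # BBBB
            (3, 1, np.nan),  # depth 4 < 5 -> missing
            (4, 1, 1.0),  # one alt read cannot support a heterozygote
            (6, 1, 1.0),  # same rule at higher depth
        ],
    )
    def test_single_cell_calls(self, ref, alt, expected):
        counts = make_counts([[ref]], [[alt]])
        code = call_dosages(counts, min_depth=5, min_het_alt=2).codes[0, 0]
        if np.isnan(expected):
            assert np.isnan(code)
        else:
            assert code == expected

    def test_boundary_fractions_assigned_upward(self):
        # ref fraction exactly 0.375 (3/8) sits on a class edge -> 0.5
        counts = make_counts([[3]], [[5]])
        assert call_dosages(counts).codes[0, 0] == 0.5

    def test_recovery_on_error_free_deep_data(self):
        # nearest-class calling is reliable once binomial noise is small
        truth = simulate.simulate_cohort(40, 120, seed=0)
        counts = simulate.simulate_reads(truth, 200, 0.0, seed=1)
        called = call_dosages(counts)
        obs = ~np.isnan(called.codes)
        concord = (called.codes[obs] == truth.true_dosage.codes[obs]).mean()
        assert concord >= 0.99

    def test_concordance_improves_with_depth(self):
        truth = simulate.simulate_cohort(40, 120, seed=0)
        rates = []
        for depth in (30, 60, 200):
            counts = simulate.simulate_reads(truth, depth, 0.0, seed=1)
            called = call_dosages(counts)
            obs = ~np.isnan(called.codes)
            rates.append((called.codes[obs] == truth.true_dosage.codes[obs]).mean())
        assert rates[0] < rates[1] < rates[2]

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            call_dosages(make_counts([[5]], [[5]]), min_depth=0)


class TestFilterVariants:
    def test_monomorphic_reference_locus_fails_maf(self):
        d = make_dosage(np.ones((4, 1)))
        kept, report = filter_variants(d)
        assert kept.n_loci == 0
        assert report.table.loc[0, "reason"] == "maf_fail"

    def test_half_missing_locus_removed(self):
        codes = np.full((10, 1), 0.5)
        codes[:5, 0] = np.nan
        kept, report = filter_variants(make_dosage(codes))
        assert report.table.loc[0, "missing_fail"]
        assert kept.n_loci == 0

    def test_four_alt_reads_insufficient_support(self):
        # "more than four" alternate reads means >= 5 in at least one sample
        codes = np.array([[0.5], [1.0], [1.0], [0.75]])
        ref = np.array([[4], [20], [20], [12]])
        alt = np.array([[4], [0], [0], [4]])
        kept, report = filter_variants(
            make_dosage(codes), counts=make_counts(ref, alt)
        )
        assert report.table.loc[0, "reason"] == "alt_support_fail"
        assert kept.n_loci == 0

    def test_fraction_threshold_needs_same_sample(self):
        # alt-rich sample has fraction 5/25 = 0.2 < 0.4 -> fraction_fail
        codes = np.array([[0.75], [1.0]])
        kept, report = filter_variants(
            make_dosage(codes), counts=make_counts([[20], [30]], [[5], [0]])
        )
        assert report.table.loc[0, "reason"] == "fraction_fail"

    def test_retained_polymorphic_locus_hand_case(self):
        codes = np.array([[1.0], [0.75], [0.5]])
        kept, report = filter_variants(make_dosage(codes))
        # mean code 0.75 -> MAF 0.25 > 0.05
        assert kept.n_loci == 1
        assert report.n_retained == 1

    def test_report_conservation_and_exclusive_attribution(self):
        truth = simulate.simulate_cohort(30, 80, seed=5)
        counts = simulate.simulate_reads(truth, 15, 0.01, seed=6)
        called = call_dosages(counts)
        masked = simulate.apply_missingness(called, 0.3, seed=7)
        kept, report = filter_variants(masked, counts=counts)
        reasons = report.reason_counts()
        assert report.n_retained == report.n_input - sum(reasons.values())
        assert kept.n_loci == report.n_retained
        # a retained locus has no failure reason
        assert (report.table.loc[report.table["retained"], "reason"] == "").all()

    @settings(max_examples=25, deadline=None)
    @given(
        maf=st.floats(0.0, 0.45),
        miss=st.floats(0.05, 1.0),
        seed=st.integers(0, 50),
    )
    def test_tightening_thresholds_never_retains_more(self, maf, miss, seed):
        truth = simulate.simulate_cohort(15, 40, seed=seed)
        masked = simulate.apply_missingness(truth.true_dosage, 0.2, seed=seed)
        _, base = filter_variants(masked, max_missing=miss, min_maf=maf)
        _, tighter = filter_variants(
            masked, max_missing=max(miss - 0.1, 0.05), min_maf=min(maf + 0.05, 0.45)
        )
        assert tighter.n_retained <= base.n_retained

    def test_empty_matrix_rejected(self):
        d = make_dosage(np.ones((3, 2)))
        with pytest.raises(ValueError):
            filter_variants(d.subset_loci(np.zeros(2, dtype=bool)))


class TestDensityBins:
    layout = GenomeLayout(chromosomes=(("chr01", 250_000), ("chr02", 100_000)))

    def test_no_loci_gives_all_zero_bins(self):
        bins = density_bins(make_loci(0), self.layout, bin_bp=100_000)
        assert (bins["n_snps"] == 0).all()
        assert len(bins) == 3 + 1  # ceil(250k/100k) + ceil(100k/100k)

    def test_position_bin_bp_falls_in_first_bin(self):
        loci = make_loci(2, chrom="chr01", start=1, step=99_999)  # pos 1 and 100000
        bins = density_bins(loci, self.layout, bin_bp=100_000)
        assert bins.loc[0, "n_snps"] == 2

    def test_counts_conserved(self):
        truth = simulate.simulate_cohort(5, 80, seed=9)
        layout = GenomeLayout(
            chromosomes=tuple(
                (c, 90_000_000)
                for c in truth.true_dosage.loci["chrom"].unique()
            )
        )
        bins = density_bins(truth.true_dosage.loci, layout, bin_bp=1_000_000)
        assert bins["n_snps"].sum() == truth.true_dosage.n_loci

    def test_out_of_range_locus_named_in_error(self):
        loci = make_loci(1, chrom="chr02", start=150_000)
        with pytest.raises(ValueError, match="chr02:150000"):
            density_bins(loci, self.layout, bin_bp=10_000)
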