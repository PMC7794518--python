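import itertools
import math
from fractions import Fraction

import pytest
from scipy import stats as sps

from ctdnaflow.concordance import (
    SampleAnalysis,
    build_pair,
    cohort_concordance_report,
    coverage_explained,
    depth_sufficiency,
    fisher_exact_two_sided,
    match_variants,
    serial_concordance,
)
from ctdnaflow.records import SampleRecord
from ctdnaflow.tumor_fraction import estimate_tumor_fraction
from conftest import make_obs


def _key(i):
    return ("chr1", i, "A", "T")


class TestMatchVariants:
    def test_partition_and_fraction(self):
        a = {_key(1), _key(2), _key(3)}
        b = {_key(2), _key(3), _key(4)}
        shared, ea, eb = match_variants(a, b)
        assert shared == {_key(2), _key(3)}
        assert ea == {_key(1)} and eb == {_key(4)}
        assert len(shared) + len(ea) + len(eb) == len(a | b)

    def test_identical_and_disjoint_sets(self):
        a = {_key(1), _key(2)}
        shared, ea, eb = match_variants(a, a)
        assert shared == a and not ea and not eb
        shared, ea, eb = match_variants({_key(1)}, {_key(2)})
        assert not shared

    def test_accepts_observations(self):
        obs = [make_obs(pos=1), make_obs(pos=2)]
        shared, ea, eb = match_variants(obs, [make_obs(pos=2)])
        assert len(shared) == 1 and len(ea) == 1


class TestCoverageExplained:
    @pytest.mark.parametrize("alt,expected", [(3, True), (2, False), (0, False)])
    def test_three_read_threshold(self, alt, expected):
        assert coverage_explained(alt) is expected

    def test_missing_pileup_is_unknown(self):
        assert coverage_explained(None) is None


class TestDepthSufficiency:
    def test_ample_depth(self):
        assert depth_sufficiency(1000, 0.2)  # expected 100 mutant reads

    def test_shallow_low_tf(self):
        assert not depth_sufficiency(100, 0.05)  # expected 2.5 < 8

    def test_zero_tf_insufficient(self):
        assert not depth_sufficiency(10_000, 0.0)


class TestSerialConcordance:
    def test_identical_sets(self):
        s = {_key(1), _key(2)}
        assert serial_concordance([s, s, s]) == 1.0

    def test_half_shared(self):
        assert serial_concordance([{_key(1), _key(2)}, {_key(1)}]) == 0.5

    def test_order_invariant_and_bounded_by_pairwise(self):
        sets = [{_key(1), _key(2), _key(3)}, {_key(1), _key(2)}, {_key(1), _key(4)}]
        base = serial_concordance(sets)
        for perm in itertools.permutations(sets):
            assert serial_concordance(list(perm)) == base
        pairwise = min(
            len(a & b) / len(a | b) for a, b in itertools.combinations(sets, 2)
        )
        assert base <= pairwise

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(ValueError):
            serial_concordance([{_key(1)}])


def fisher_oracle(table):
    """Brute-force enumeration with exact rational arithmetic."""
    (a, b), (c, d) = table
    n, r1, c1 = a + b + c + d, a + b, a + c
    def pmf(k):
        return Fraction(
            math.comb(c1, k) * math.comb(n - c1, r1 - k), math.comb(n, r1)
        )
    obs = pmf(a)
    lo, hi = max(0, r1 - (n - c1)), min(r1, c1)
    return float(sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= obs))


class TestFisherExact:
    def test_printed_clonality_table(self):
        # sharing of subclonal (32/50) vs clonal (189/215) mutations
        result = fisher_exact_two_sided([[32, 18], [189, 26]])
        assert round(result.p_two_sided, 4) == 0.0002

    def test_flat_table_p_is_one(self):
        assert fisher_exact_two_sided([[1, 1], [1, 1]]).p_two_sided == 1.0

    def test_transpose_invariance(self):
        t = [[7, 2], [3, 11]]
        tt = [[7, 3], [2, 11]]
        assert fisher_exact_two_sided(t).p_two_sided == pytest.approx(
            fisher_exact_two_sided(tt).p_two_sided, abs=1e-12
        )

    def test_matches_scipy_on_reference_tables(self):
        for t in ([[32, 18], [189, 26]], [[8, 31], [59, 12]], [[5, 0], [1, 4]]):
            ours = fisher_exact_two_sided(t)
            theirs = sps.fisher_exact(t)
            assert ours.p_two_sided == pytest.approx(theirs.pvalue, rel=1e-9)

    def test_odds_ratio_conventions(self):
        assert fisher_exact_two_sided([[5, 0], [1, 4]]).odds_ratio == math.inf
        assert math.isnan(fisher_exact_two_sided([[0, 5], [0, 4]]).odds_ratio)

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided([[0, 0], [0, 0]])

    def test_agrees_with_enumeration_oracle_on_small_tables(self):
        for a, b, c, d in itertools.product(range(5), repeat=4):
            if a + b + c + d == 0:
                continue
            assert fisher_exact_two_sided([[a, b], [c, d]]).p_two_sided == (
                pytest.approx(fisher_oracle([[a, b], [c, d]]), abs=1e-12)
            )


def _analysis(patient, sample_id, compartment, variants, timepoint=0):
    sample = SampleRecord(patient, sample_id, compartment, timepoint_days=timepoint)
    sample.variants = list(variants)
    tf = estimate_tumor_fraction(list(variants), compartment)
    return SampleAnalysis(sample, list(variants), tf)


class TestCohortReport:
    def test_highest_tf_cfdna_sample_used_for_pairing(self):
        strong = make_obs(pos=1, alt_reads=300, depth=1000)
        weak = make_obs(pos=1, alt_reads=100, depth=1000)
        tissue_obs = make_obs(pos=1, alt_reads=300, depth=1000)
        analyses = [
            _analysis("P1", "P1_cfDNA_a", "cfDNA", [strong]),  # tf ~30%
            _analysis("P1", "P1_cfDNA_b", "cfDNA", [weak]),  # tf ~10%
            _analysis("P1", "P1_tissue_a", "tissue", [tissue_obs]),
        ]
        report = cohort_concordance_report(analyses)
        assert report.pairs[0].sample_a == "P1_cfDNA_a"

    def test_most_recent_tissue_used_for_pairing(self):
        obs = make_obs(pos=1, alt_reads=300, depth=1000)
        analyses = [
            _analysis("P1", "P1_cfDNA_a", "cfDNA", [obs]),
            _analysis("P1", "P1_tissue_old", "tissue", [obs], timepoint=0),
            _analysis("P1", "P1_tissue_new", "tissue", [obs], timepoint=200),
        ]
        report = cohort_concordance_report(analyses)
        assert report.pairs[0].sample_b == "P1_tissue_new"

    def test_fully_shared_cohort_degenerate_contingency(self):
        obs = [make_obs(pos=i, alt_reads=300, depth=1000) for i in (1, 2, 3)]
        analyses = [
            _analysis("P1", "P1_cf", "cfDNA", obs),
            _analysis("P1", "P1_ti", "tissue", obs),
        ]
        report = cohort_concordance_report(analyses)
        assert report.fraction_shared == 1.0
        assert report.contingency is None  # not applicable, reported in notes
        assert any("not applicable" in n for n in report.notes)

    def test_cross_patient_pair_rejected(self):
        a = _analysis("P1", "a", "cfDNA", [make_obs(pos=1, alt_reads=300, depth=1000)])
        b = _analysis("P2", "b", "tissue", [make_obs(pos=1, alt_reads=300, depth=1000)])
        with pytest.raises(ValueError):
            build_pair(a, b)

    def test_no_eligible_pairs_notes_reason(self):
        a = _analysis("P1", "a", "cfDNA", [make_obs(pos=1, alt_reads=300, depth=1000)])
        report = cohort_concordance_report([a])
        assert not report.pairs
        assert any("no eligible" in n for n in report.notes)

    def test_coverage_explained_flags_from_paired_pileup(self):
        shared = make_obs(pos=1, alt_reads=300, depth=1000)
        excl = make_obs(pos=2, alt_reads=100, depth=1000)
        # tissue sample saw 4 alt reads at the exclusive locus: explained
        tissue_pileup = make_obs(pos=2, alt_reads=4, depth=50)
        cf = _analysis("P1", "cf", "cfDNA", [shared, excl])
        ti_sample = SampleRecord("P1", "ti", "tissue")
        ti_sample.variants = [shared, tissue_pileup]
        ti = SampleAnalysis(ti_sample, [shared], estimate_tumor_fraction([shared], "tissue"))
        pair = build_pair(cf, ti)
        assert pair.coverage_explained_flags[excl.key] is True
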