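import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctdnaflow.records import SampleRecord, variant_key_str
from ctdnaflow.synthetic_cohort import SimulationConfig, simulate_patient
from ctdnaflow.variant_filtering import (
    CHIP_GENE_REVIEW,
    END_PROXIMITY,
    GDNA_NO_COVERAGE,
    GDNA_RATIO,
    MAPQ,
    MIN_ALT_READS,
    MIN_VAF,
    WES_MIN_VAF,
    WES_NORMAL_RATIO,
    FilterParams,
    filter_sample,
    passes_somatic_filters,
    passes_wes_silent_filters,
    read_end_proximity,
)
from conftest import make_obs


class TestReadEndProximity:
    def test_arithmetic_mean(self):
        assert read_end_proximity([30, 25, 35]) == 30.0
        assert read_end_proximity([10, 10, 10]) == 10.0

    def test_single_read_at_boundary_fails_gate(self):
        score = read_end_proximity([25])
        assert score == 25.0
        obs = make_obs(end_distance=score)
        decision = passes_somatic_filters(obs, None, "cfDNA")
        assert END_PROXIMITY in decision.reasons

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            read_end_proximity([])


class TestSomaticFilters:
    def test_minimal_passing_cfdna_call(self):
        obs = make_obs(alt_reads=10, depth=1000, mapq=60, end_distance=40)
        gdna = make_obs(alt_reads=0, depth=300)
        decision = passes_somatic_filters(obs, gdna, "cfDNA")
        assert decision.passed and decision.reasons == []

    def test_seven_reads_fail_min_alt(self):
        obs = make_obs(alt_reads=7, depth=100)
        decision = passes_somatic_filters(obs, None, "cfDNA")
        assert MIN_ALT_READS in decision.reasons and not decision.passed

    def test_tissue_fails_both_vaf_floor_and_gdna_ratio(self):
        obs = make_obs(alt_reads=60, depth=1000)  # vaf 6%
        gdna = make_obs(alt_reads=25, depth=1000)  # gdna vaf 2.5%
        decision = passes_somatic_filters(obs, gdna, "tissue")
        assert GDNA_RATIO in decision.reasons
        assert MIN_VAF in decision.reasons

    @pytest.mark.parametrize(
        "mapq,end_distance,expected",
        [
            (30.0, 40.0, [MAPQ]),  # exactly 30 fails (strict >)
            (60.0, 25.0, [END_PROXIMITY]),  # exactly 25 fails (strict >)
            (30.001, 25.001, []),
        ],
    )
    def test_quality_gates_are_strict_inequalities(self, mapq, end_distance, expected):
        obs = make_obs(alt_reads=100, depth=1000, mapq=mapq, end_distance=end_distance)
        decision = passes_somatic_filters(obs, None, "cfDNA")
        assert decision.reasons == expected

    def test_missing_gdna_passes_ratio_with_warning(self):
        obs = make_obs(alt_reads=100, depth=1000)
        decision = passes_somatic_filters(obs, None, "cfDNA")
        assert decision.passed
        assert GDNA_NO_COVERAGE in decision.warnings

    def test_mismatched_locus_rejected(self):
        obs = make_obs(pos=100)
        gdna = make_obs(pos=101)
        with pytest.raises(ValueError):
            passes_somatic_filters(obs, gdna, "cfDNA")

    def test_optional_background_test(self):
        obs = make_obs(alt_reads=8, depth=8000)  # 0.1% vaf, matches background
        params = FilterParams(background_rate=0.001, min_vaf_cfdna=0.0)
        decision = passes_somatic_filters(obs, None, "cfDNA", params)
        assert "BACKGROUND" in decision.reasons


class TestWesSilentFilters:
    def test_passing_call(self):
        obs = make_obs(alt_reads=120, depth=1000, effect="silent")  # 12%
        normal = make_obs(alt_reads=5, depth=1000, effect="silent")  # 0.5%
        decision = passes_wes_silent_filters(obs, 0.001, normal)
        assert decision.passed  # 120x background, 24x normal

    def test_nine_percent_fails_floor(self):
        obs = make_obs(alt_reads=90, depth=1000)
        normal = make_obs(alt_reads=0, depth=1000)
        decision = passes_wes_silent_filters(obs, 0.0, normal)
        assert WES_MIN_VAF in decision.reasons

    def test_normal_ratio_failure(self):
        obs = make_obs(alt_reads=150, depth=1000)  # 15%
        normal = make_obs(alt_reads=20, depth=1000)  # 2% -> 7.5x < 10x
        decision = passes_wes_silent_filters(obs, 0.0, normal)
        assert WES_NORMAL_RATIO in decision.reasons

    def test_background_rate_out_of_range_rejected(self):
        obs = make_obs()
        with pytest.raises(ValueError):
            passes_wes_silent_filters(obs, 1.5, make_obs())


def _sample_pair(variants, gdna_variants, compartment="cfDNA", patient="P1"):
    sample = SampleRecord(patient, f"{patient}_{compartment}_t0", compartment)
    sample.variants = variants
    gdna = SampleRecord(patient, f"{patient}_gDNA", "gDNA")
    gdna.variants = gdna_variants
    return sample, gdna


class TestFilterSample:
    def test_bookkeeping_counts(self):
        passing = [make_obs(pos=i, alt_reads=50, depth=1000) for i in range(1, 6)]
        failing = [make_obs(pos=i, alt_reads=3, depth=1000) for i in range(6, 8)]
        sample, gdna = _sample_pair(passing + failing, [])
        kept, audit = filter_sample(sample, gdna)
        assert len(kept) == 5 and len(audit) == 7

    def test_germline_het_removed_by_gdna_ratio(self):
        het = make_obs(alt_reads=500, depth=1000)
        gdna_het = make_obs(alt_reads=150, depth=300)
        sample, gdna = _sample_pair([het], [gdna_het])
        kept, audit = filter_sample(sample, gdna)
        assert kept == []
        assert GDNA_RATIO in audit[0].reasons

    def test_chip_review_advisory_vs_strict(self):
        chip = make_obs(gene="DNMT3A", chrom="chr2", alt_reads=30, depth=1000)
        gdna_chip = make_obs(gene="DNMT3A", chrom="chr2", alt_reads=2, depth=300)
        sample, gdna = _sample_pair([chip], [gdna_chip])
        kept, audit = filter_sample(sample, gdna, strict_chip=False)
        assert len(kept) == 1 and CHIP_GENE_REVIEW in audit[0].warnings
        kept_strict, audit_strict = filter_sample(sample, gdna, strict_chip=True)
        assert kept_strict == [] and CHIP_GENE_REVIEW in audit_strict[0].reasons

    def test_cross_patient_pairing_rejected(self):
        sample, _ = _sample_pair([], [], patient="P1")
        _, gdna_other = _sample_pair([], [], patient="P2")
        with pytest.raises(ValueError):
            filter_sample(sample, gdna_other)

    def test_idempotence(self, simulated_patient):
        case, _truth = simulated_patient
        gdna = case.gdna
        sample = case.by_compartment("cfDNA")[0]
        kept, _ = filter_sample(sample, gdna)
        refiltered = dataclasses.replace(sample)
        refiltered.variants = kept
        kept2, _ = filter_sample(refiltered, gdna)
        assert kept2 == kept

    def test_synthetic_germline_removal_rate(self):
        """>=99% of germline-labeled variants are removed at depth >= 200."""
        config = SimulationConfig(panel_footprint=5_000, germline_het_count=15, seed=6)
        total = removed = 0
        for seed in range(10):
            case, truth = simulate_patient(config, 500 + seed)
            germline = {
                k for k, lab in truth.labels.items() if lab == "germline"
            }
            gdna = case.gdna
            for sample in case.tumor_samples:
                kept, _ = filter_sample(sample, gdna)
                kept_keys = {variant_key_str(v.key) for v in kept}
                for k in germline:
                    total += 1
                    removed += k not in kept_keys
        assert total >= 500
        assert removed / total >= 0.99


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    alt=st.integers(0, 200),
    depth=st.integers(200, 2000),
    gdna_alt=st.integers(0, 30),
    bump_alt=st.integers(0, 5),
    bump_vaf=st.floats(0.0, 0.05),
)
def test_raising_thresholds_never_admits_a_variant(
    alt, depth, gdna_alt, bump_alt, bump_vaf
):
    """Filter monotonicity: stricter thresholds can only shrink the kept set."""
    obs = make_obs(alt_reads=alt, depth=depth)
    gdna = make_obs(alt_reads=gdna_alt, depth=300)
    base = FilterParams()
    strict = FilterParams(
        min_alt_reads=base.min_alt_reads + bump_alt,
        min_vaf_cfdna=base.min_vaf_cfdna + bump_vaf,
        gdna_ratio=base.gdna_ratio + 1.0,
        min_mapq=base.min_mapq + 5.0,
        min_end_distance=base.min_end_distance + 5.0,
    )
    passed_base = passes_somatic_filters(obs, gdna, "cfDNA", base).passed
    passed_strict = passes_somatic_filters(obs, gdna, "cfDNA", strict).passed
    assert passed_strict <= passed_base
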