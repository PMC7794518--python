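"""Somatic mutation filters for targeted cfDNA/tissue panels and WES.

Targeted-panel calls require at least eight mutant-allele reads, a VAF floor
of 1% in cfDNA and 8% in tissue, a VAF more than 3x that of the matched
germline (gDNA) sample, mean mapping quality of mutation-supporting reads
strictly above 30, and a read-end proximity score strictly above 25.  The
3x-gDNA rule removes germline variants and most clonal-hematopoiesis (CHIP)
somatic variants; variants in known CHIP genes with any residual gDNA read
support are additionally flagged for review (and dropped in strict mode),
since high cfDNA depth can let low-VAF CHIP slip past the ratio rule.

WES silent-mutation calls use stricter thresholds: >=10% VAF, >=50x the
per-site background error rate, and >=10x the matched-normal VAF.

Every input variant gets a :class:`FilterDecision` naming each failed rule,
so cohort-level filtering is fully auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from scipy import stats

from .records import SampleRecord, VariantObservation
from .synthetic_cohort import DEFAULT_CHIP_GENES

# rule codes
MIN_ALT_READS = "MIN_ALT_READS"
MIN_VAF = "MIN_VAF"
GDNA_RATIO = "GDNA_RATIO"
MAPQ = "MAPQ"
END_PROXIMITY = "END_PROXIMITY"
BACKGROUND = "BACKGROUND"
WES_MIN_VAF = "WES_MIN_VAF"
WES_BACKGROUND = "WES_BACKGROUND"
WES_NORMAL_RATIO = "WES_NORMAL_RATIO"
CHIP_GENE_REVIEW = "CHIP_GENE_REVIEW"
# warning (never blocks a call)
GDNA_NO_COVERAGE = "GDNA_NO_COVERAGE"


@dataclass(frozen=True)
class FilterParams:
    """Thresholds for the targeted-panel somatic filters (study defaults)."""

    min_alt_reads: int = 8
    min_vaf_cfdna: float = 0.01
    min_vaf_tissue: float = 0.08
    gdna_ratio: float = 3.0
    min_mapq: float = 30.0  # strict: exactly 30 fails
    min_end_distance: float = 25.0  # strict: exactly 25 fails
    #: optional per-site background-error test (one-sided binomial); the
    #: magnitude of the panel's background error is a free parameter, so the
    #: test is off unless a rate is supplied
    background_rate: Optional[float] = None
    background_alpha: float = 0.01


@dataclass
class FilterDecision:
    """Outcome of the filter stack for one variant."""

    variant_key: tuple
    passed: bool
    reasons: list = field(default_factory=list)
    warnings: list = field(default_factory=list)


def read_end_proximity(end_distances: Sequence[float]) -> float:
    """Mean distance of the mutant allele from the nearest read end.

    Computed over mutation-supporting reads only; low scores indicate
    end-repair/fixation artifacts.
    """
    if len(end_distances) == 0:
        raise ValueError("end_distances must be non-empty")
    if any(d < 0 for d in end_distances):
        raise ValueError("end distances must be >= 0")
    return float(sum(end_distances)) / len(end_distances)


def _quality_failures(obs: VariantObservation, params: FilterParams) -> list[str]:
    reasons = []
    if not (obs.mean_mapq_alt > params.min_mapq):
        reasons.append(MAPQ)
    if not (obs.mean_end_distance_alt > params.min_end_distance):
        reasons.append(END_PROXIMITY)
    return reasons


def passes_somatic_filters(
    obs: VariantObservation,
    gdna_obs: Optional[VariantObservation],
    compartment: str,
    params: FilterParams = FilterParams(),
) -> FilterDecision:
    """Apply the targeted-panel somatic filter stack to one observation."""
    if compartment not in ("cfDNA", "tissue"):
        raise ValueError(f"compartment must be cfDNA or tissue, got {compartment!r}")
    if gdna_obs is not None and gdna_obs.key != obs.key:
        raise ValueError(
            f"gDNA observation is for {gdna_obs.key}, expected {obs.key}"
        )
    reasons: list[str] = []
    warnings: list[str] = []

    if obs.alt_reads < params.min_alt_reads:
        reasons.append(MIN_ALT_READS)
    floor = params.min_vaf_cfdna if compartment == "cfDNA" else params.min_vaf_tissue
    if obs.vaf < floor:
        reasons.append(MIN_VAF)

    if gdna_obs is None or gdna_obs.depth == 0:
        gdna_vaf = 0.0
        warnings.append(GDNA_NO_COVERAGE)
    elif gdna_obs.alt_reads == 0:
        gdna_vaf = 0.0
    else:
        gdna_vaf = gdna_obs.vaf
    if not (obs.vaf > params.gdna_ratio * gdna_vaf):
        reasons.append(GDNA_RATIO)

    reasons.extend(_quality_failures(obs, params))

    if params.background_rate is not None:
        # one-sided: is alt support inconsistent with pure background error?
        p = stats.binom.sf(obs.alt_reads - 1, obs.depth, params.background_rate)
        if p > params.background_alpha:
            reasons.append(BACKGROUND)

    return FilterDecision(obs.key, passed=not reasons, reasons=reasons, warnings=warnings)


def passes_wes_silent_filters(
    obs: VariantObservation,
    site_background_rate: float,
    normal_obs: VariantObservation,
    params: FilterParams = FilterParams(),
) -> FilterDecision:
    """Apply the WES silent-mutation rules to one observation."""
    if not (0.0 <= site_background_rate <= 1.0):
        raise ValueError("site_background_rate must be in [0,1]")
    if normal_obs.key != obs.key:
        raise ValueError(
            f"normal observation is for {normal_obs.key}, expected {obs.key}"
        )
    reasons: list[str] = []
    if obs.vaf < 0.10:
        reasons.append(WES_MIN_VAF)
    if obs.vaf < 50.0 * site_background_rate:
        reasons.append(WES_BACKGROUND)
    if obs.vaf < 10.0 * normal_obs.vaf:
        reasons.append(WES_NORMAL_RATIO)
    reasons.extend(_quality_failures(obs, params))
    return FilterDecision(obs.key, passed=not reasons, reasons=reasons)


def filter_sample(
    sample: SampleRecord,
    gdna: SampleRecord,
    chip_gene_list: Iterable[str] = DEFAULT_CHIP_GENES,
    strict_chip: bool = False,
    params: FilterParams = FilterParams(),
) -> tuple[list[VariantObservation], list[FilterDecision]]:
    """Filter one tumor sample against its matched gDNA.

    Returns the kept observations and one audit entry per input variant.
    CHIP-gene variants with any gDNA alt support carry the advisory
    ``CHIP_GENE_REVIEW`` code; in strict mode they are excluded outright.
    """
    if gdna.compartment != "gDNA":
        raise ValueError(f"matched normal must be gDNA, got {gdna.compartment!r}")
    if gdna.patient_id != sample.patient_id:
        raise ValueError(
            f"cross-patient filtering: {sample.patient_id} vs {gdna.patient_id}"
        )
    chip_genes = set(chip_gene_list)
    gdna_by_key = gdna.variants_by_key()
    kept: list[VariantObservation] = []
    audit: list[FilterDecision] = []
    for obs in sample.variants:
        decision = passes_somatic_filters(
            obs, gdna_by_key.get(obs.key), sample.compartment, params
        )
        gobs = gdna_by_key.get(obs.key)
        if obs.gene in chip_genes and gobs is not None and gobs.alt_reads >= 1:
            if strict_chip:
                decision.reasons.append(CHIP_GENE_REVIEW)
                decision.passed = False
            else:
                decision.warnings.append(CHIP_GENE_REVIEW)
        audit.append(decision)
        if decision.passed:
            kept.append(obs)
    return kept, audit
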