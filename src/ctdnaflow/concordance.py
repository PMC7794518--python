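"""Tissue-ctDNA and serial-sample mutation concordance.

For each eligible patient (at least one evaluable plasma and one evaluable
tissue sample), the highest-tumor-fraction cfDNA sample is paired with the
most recent tissue sample.  Variants are matched exactly on
(chrom, pos, ref, alt); each pair is partitioned into shared and
compartment-exclusive calls.  An exclusive call is "coverage explained"
when the paired sample shows at least three mutant-supporting reads at the
locus — i.e. deeper sequencing could plausibly have called it there too.
Sharing is stratified by clonality (subclonal: VAF < 25% of the tumor
fraction) and tested with a two-sided Fisher exact test computed by exact
hypergeometric enumeration.  Serial concordance within a compartment is the
fraction of mutations called in every sample among those called in any.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Optional, Sequence

from .records import SampleRecord, VariantKey, VariantObservation, variant_key_str
from .tumor_fraction import TumorFractionEstimate, classify_clonality

COVERAGE_EXPLAINED_MIN_READS = 3
TRUNCAL_DETECTION_MIN_READS = 8


def _keys(variants: Iterable) -> set[VariantKey]:
    return {v.key if isinstance(v, VariantObservation) else tuple(v) for v in variants}


def match_variants(
    a: Iterable, b: Iterable
) -> tuple[set[VariantKey], set[VariantKey], set[VariantKey]]:
    """Partition two call sets into (shared, exclusive_a, exclusive_b)."""
    ka, kb = _keys(a), _keys(b)
    return ka & kb, ka - kb, kb - ka


@dataclass
class ConcordancePair:
    sample_a: str
    sample_b: str
    shared: set
    exclusive_a: set
    exclusive_b: set
    #: key -> True/False (paired alt reads >= 3) or None when the locus was
    #: not queried in the paired sample
    coverage_explained_flags: dict = field(default_factory=dict)

    @property
    def total(self) -> int:
        return len(self.shared) + len(self.exclusive_a) + len(self.exclusive_b)

    @property
    def fraction_shared(self) -> float:
        return len(self.shared) / self.total if self.total else 0.0


def coverage_explained(paired_alt_reads: Optional[int]) -> Optional[bool]:
    """Could deeper sequencing have rescued this exclusive call?

    True iff the paired sample shows >= 3 mutant-supporting reads at the
    locus; None (unknown) when the locus has no pileup data there.
    """
    if paired_alt_reads is None:
        return None
    return paired_alt_reads >= COVERAGE_EXPLAINED_MIN_READS


def depth_sufficiency(paired_depth: int, paired_tf: float) -> bool:
    """Was the paired sample deep enough to call a truncal variant?

    A truncal diploid-heterozygous mutation has VAF = tf/2, so the expected
    mutant-read count is depth * tf/2; calling needs >= 8 mutant reads.
    """
    if paired_depth < 0:
        raise ValueError("depth must be >= 0")
    if not (0.0 <= paired_tf <= 1.0):
        raise ValueError("tf must be in [0,1]")
    return paired_depth * paired_tf / 2.0 >= TRUNCAL_DETECTION_MIN_READS


def serial_concordance(call_sets: Sequence[Iterable]) -> float:
    """Fraction of mutations called in every sample among those in any."""
    if len(call_sets) < 2:
        raise ValueError("serial concordance needs >= 2 samples")
    sets = [_keys(s) for s in call_sets]
    union = set().union(*sets)
    if not union:
        raise ValueError("no mutations called in any sample")
    inter = set(sets[0]).intersection(*sets[1:])
    return len(inter) / len(union)


@dataclass(frozen=True)
class ContingencyResult:
    table: tuple  # ((a,b),(c,d))
    odds_ratio: float
    p_two_sided: float


def fisher_exact_two_sided(table: Sequence[Sequence[int]]) -> ContingencyResult:
    """Two-sided Fisher exact test by exact hypergeometric enumeration.

    Sums the probabilities of all tables (with the observed margins) that
    are no more likely than the observed one; probabilities are compared as
    exact rationals, so there is no floating tie ambiguity.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0 or any(
        int(x) != x for x in (a, b, c, d)
    ):
        raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n_total = a + b + c + d
    if n_total == 0:
        raise ValueError("all-zero table")
    row1 = a + b
    col1 = a + c
    denom = math.comb(n_total, row1)

    def weight(k: int) -> int:
        return math.comb(col1, k) * math.comb(n_total - col1, row1 - k)

    k_min = max(0, row1 - (n_total - col1))
    k_max = min(row1, col1)
    w_obs = weight(a)
    num = sum(weight(k) for k in range(k_min, k_max + 1) if weight(k) <= w_obs)
    p = float(Fraction(num, denom))

    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return ContingencyResult(((a, b), (c, d)), odds, p)


# ---------------------------------------------------------------------------
# Cohort-level report
# ---------------------------------------------------------------------------


@dataclass
class SampleAnalysis:
    """One sample after filtering and tumor-fraction estimation."""

    sample: SampleRecord
    kept: list  # kept VariantObservation
    tf: TumorFractionEstimate

    def kept_by_key(self) -> dict:
        return {v.key: v for v in self.kept}


@dataclass
class CohortConcordanceReport:
    pairs: list = field(default_factory=list)  # ConcordancePair per patient
    pair_patients: list = field(default_factory=list)
    n_shared: int = 0
    n_total: int = 0
    clonal_shared: int = 0
    clonal_total: int = 0
    subclonal_shared: int = 0
    subclonal_total: int = 0
    contingency: Optional[ContingencyResult] = None
    coverage_explained_n: int = 0
    exclusive_n: int = 0
    #: (patient_id, compartment) -> serial concordance fraction
    serial: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    @property
    def fraction_shared(self) -> float:
        return self.n_shared / self.n_total if self.n_total else 0.0


def _select_pair(
    analyses: Sequence[SampleAnalysis],
) -> Optional[tuple[SampleAnalysis, SampleAnalysis]]:
    """Highest-TF evaluable cfDNA sample + most recent evaluable tissue."""
    cf = [x for x in analyses if x.sample.compartment == "cfDNA" and x.tf.evaluable]
    ti = [x for x in analyses if x.sample.compartment == "tissue" and x.tf.evaluable]
    if not cf or not ti:
        return None
    best_cf = min(cf, key=lambda x: (-x.tf.tumor_fraction, x.sample.sample_id))
    best_ti = min(ti, key=lambda x: (-x.sample.timepoint_days, x.sample.sample_id))
    return best_cf, best_ti


def _variant_clonality(
    key: VariantKey, holders: Sequence[SampleAnalysis]
) -> Optional[str]:
    """Classify a variant using the detecting sample with the higher TF."""
    holders = [
        h for h in holders if key in h.kept_by_key() and h.tf.tumor_fraction > 0
    ]
    if not holders:
        return None
    h = max(holders, key=lambda x: x.tf.tumor_fraction)
    return classify_clonality(h.kept_by_key()[key].vaf, h.tf.tumor_fraction)


def build_pair(a: SampleAnalysis, b: SampleAnalysis) -> ConcordancePair:
    """Concordance accounting for one tissue-ctDNA pair."""
    if a.sample.patient_id != b.sample.patient_id:
        raise ValueError("cross-patient comparison rejected")
    shared, excl_a, excl_b = match_variants(a.kept, b.kept)
    pair = ConcordancePair(
        a.sample.sample_id, b.sample.sample_id, shared, excl_a, excl_b
    )
    raw_a = a.sample.variants_by_key()
    raw_b = b.sample.variants_by_key()
    for key in excl_a:
        obs = raw_b.get(key)
        pair.coverage_explained_flags[key] = coverage_explained(
            obs.alt_reads if obs is not None else None
        )
    for key in excl_b:
        obs = raw_a.get(key)
        pair.coverage_explained_flags[key] = coverage_explained(
            obs.alt_reads if obs is not None else None
        )
    return pair


def cohort_concordance_report(
    analyses: Sequence[SampleAnalysis],
) -> CohortConcordanceReport:
    """Aggregate pair and serial concordance over a filtered cohort."""
    report = CohortConcordanceReport()
    by_patient: dict[str, list[SampleAnalysis]] = {}
    for x in analyses:
        by_patient.setdefault(x.sample.patient_id, []).append(x)

    for pid in sorted(by_patient):
        patient_analyses = by_patient[pid]
        selected = _select_pair(patient_analyses)
        if selected is not None:
            cf, ti = selected
            pair = build_pair(cf, ti)
            if pair.total and not pair.shared:
                report.notes.append(f"{pid}: pair shares no mutations")
            report.pairs.append(pair)
            report.pair_patients.append(pid)
            report.n_shared += len(pair.shared)
            report.n_total += pair.total
            report.exclusive_n += len(pair.exclusive_a) + len(pair.exclusive_b)
            report.coverage_explained_n += sum(
                1 for v in pair.coverage_explained_flags.values() if v
            )
            for key in pair.shared | pair.exclusive_a | pair.exclusive_b:
                clonality = _variant_clonality(key, (cf, ti))
                if clonality is None:
                    continue
                is_shared = key in pair.shared
                if clonality == "clonal":
                    report.clonal_total += 1
                    report.clonal_shared += is_shared
                else:
                    report.subclonal_total += 1
                    report.subclonal_shared += is_shared

        # serial concordance per compartment
        for comp in ("cfDNA", "tissue"):
            serial = [
                x
                for x in patient_analyses
                if x.sample.compartment == comp and x.tf.evaluable
            ]
            if len(serial) >= 2:
                try:
                    frac = serial_concordance([x.kept for x in serial])
                except ValueError:
                    continue
                report.serial[(pid, comp)] = frac

    # subclonal-vs-clonal sharing contingency: rows (subclonal, clonal) x
    # columns (shared, not shared), same orientation as the 2x2 under test
    table = (
        (report.subclonal_shared, report.subclonal_total - report.subclonal_shared),
        (report.clonal_shared, report.clonal_total - report.clonal_shared),
    )
    row_sums = (table[0][0] + table[0][1], table[1][0] + table[1][1])
    col_sums = (table[0][0] + table[1][0], table[0][1] + table[1][1])
    if min(row_sums) == 0 or min(col_sums) == 0:
        report.contingency = None
        report.notes.append("clonality contingency not applicable (degenerate table)")
    else:
        report.contingency = fisher_exact_two_sided(table)

    if not report.pairs:
        report.notes.append("no eligible tissue-ctDNA pairs")
    return report
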