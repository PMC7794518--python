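"""Conservative tumor-fraction estimation from the highest somatic VAF.

The tumor fraction (TF) of a sample is inferred from the highest-VAF
eligible somatic mutation under a conservative loss-of-heterozygosity
assumption: a truncal mutation on the single remaining allele has
VAF = TF / (2 - TF), inverted as

    TF = 2 / (1/VAF + 1) = 2*VAF / (1 + VAF).

To damp stochastic read sampling, the observed top VAF is first replaced by
the one-sided lower 95% binomial confidence bound (exact Clopper-Pearson
inversion): the VAF the locus would have if the observation were a 95%
quantile outlier.  Mutations on chromosome 9 (frequent copy-neutral LOH),
in the TERT promoter (low depth), in amplified regions, and on sex or
mitochondrial chromosomes are ineligible for TF estimation.

With the calling floors of 1% (cfDNA) and 8% (tissue) VAF, the detection
limits of the estimator are ~2% and ~15% tumor fraction respectively.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from scipy import stats

from .records import VariantObservation

AUTOSOMES = frozenset(
    {str(i) for i in range(1, 23)} | {f"chr{i}" for i in range(1, 23)}
)


def adjusted_vaf(alt_reads: int, depth: int, quantile: float = 0.95) -> float:
    """One-sided lower (quantile)-confidence bound for the true VAF.

    Largest p with P(X >= alt_reads | Binomial(depth, p)) <= 1 - quantile;
    equivalently the Beta(k, n-k+1) lower quantile for k >= 1, and 0 for
    k = 0.  Always <= alt_reads/depth (conservative).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not (0 <= alt_reads <= depth):
        raise ValueError("alt_reads must satisfy 0 <= alt_reads <= depth")
    if not (0.0 < quantile < 1.0):
        raise ValueError("quantile must be in (0,1)")
    if alt_reads == 0:
        return 0.0
    return float(stats.beta.ppf(1.0 - quantile, alt_reads, depth - alt_reads + 1))


def tumor_fraction_from_vaf(vaf: float) -> float:
    """TF = 2*VAF/(1+VAF), the LOH inversion; bijective on [0,1]."""
    if not (0.0 <= vaf <= 1.0):
        raise ValueError("vaf must be in [0,1]")
    return 2.0 * vaf / (1.0 + vaf)


def vaf_from_tumor_fraction(tf: float) -> float:
    """Inverse transform: VAF = TF/(2-TF)."""
    if not (0.0 <= tf <= 1.0):
        raise ValueError("tf must be in [0,1]")
    return tf / (2.0 - tf)


def select_tf_variant(
    kept_variants: Iterable[VariantObservation],
) -> Optional[VariantObservation]:
    """Highest-VAF variant eligible for TF estimation, or None.

    Eligible: autosomal chromosome with region_flag "autosome" (i.e. not
    chr9, not TERT promoter, not in an amplified region).  Ties at the
    maximum VAF break to the lowest (chrom, pos, alt).
    """
    eligible = [
        v
        for v in kept_variants
        if v.region_flag == "autosome" and v.chrom in AUTOSOMES
    ]
    if not eligible:
        return None
    return min(eligible, key=lambda v: (-v.vaf, v.chrom, v.pos, v.alt))


@dataclass(frozen=True)
class TumorFractionEstimate:
    tumor_fraction: float
    adjusted_vaf: float
    raw_max_vaf: float
    source_variant: Optional[tuple]  # variant key, or None
    detected: bool  # TF > 1%
    evaluable: bool  # >=1 protein-altering somatic mutation kept


def estimate_tumor_fraction(
    kept_variants: Sequence[VariantObservation],
    compartment: str = "cfDNA",
    quantile: float = 0.95,
    detection_threshold: float = 0.01,
) -> TumorFractionEstimate:
    """Estimate TF for one sample from its kept (filtered) variants."""
    evaluable = any(v.effect == "protein_altering" for v in kept_variants)
    chosen = select_tf_variant(kept_variants)
    if chosen is None:
        return TumorFractionEstimate(0.0, 0.0, 0.0, None, False, evaluable)
    adj = adjusted_vaf(chosen.alt_reads, chosen.depth, quantile)
    tf = tumor_fraction_from_vaf(adj)
    return TumorFractionEstimate(
        tumor_fraction=tf,
        adjusted_vaf=adj,
        raw_max_vaf=chosen.vaf,
        source_variant=chosen.key,
        detected=tf > detection_threshold,
        evaluable=evaluable,
    )


def normalized_vaf(vaf: float, tf: float) -> float:
    """Purity-normalized VAF ratio vaf/tf (reported x100 as a percent).

    Ratios above 1 (100%) arise on amplified genes and are flagged in
    reports rather than truncated.
    """
    if not (0.0 < tf <= 1.0):
        raise ValueError("tf must be in (0,1]")
    if vaf < 0:
        raise ValueError("vaf must be >= 0")
    return vaf / tf


def classify_clonality(vaf: float, tf: float) -> str:
    """'subclonal' iff VAF < 25% of the tumor fraction (strict), else 'clonal'."""
    if not (0.0 < tf <= 1.0):
        raise ValueError("tf must be in (0,1]")
    return "subclonal" if vaf < 0.25 * tf else "clonal"
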