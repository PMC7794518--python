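"""Purity-corrected per-gene copy number from coverage log-ratios.

The observed normalized coverage of a gene in a sample with tumor fraction
tf and tumor copy number CN follows the mixture

    ratio = (tf * CN + 2 * (1 - tf)) / 2,

so CN = (2 * 2^log_ratio - 2*(1 - tf)) / tf, floored at zero.  This is why
high-level amplifications remain detectable at low tumor fractions: at
tf = 0.05, CN = 50 still shifts coverage by 2.2-fold.

Confidence intervals come from the spread of the same gene's log-ratio in
samples with no evidence of tumor (TF = 0): the 95% interval on the
log-ratio scale (log_ratio +/- z * baseline_sd) is transformed through the
copy-number formula.  Amplification is called at >= 5 copies by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MIN_BASELINE_SAMPLES = 3
DEFAULT_AMP_THRESHOLD = 5.0


@dataclass(frozen=True)
class GeneCopyNumber:
    gene: str
    log_ratio: float
    copy_number: float
    ci_low: float
    ci_high: float
    amplified: bool


def gene_log_ratio(gene_coverage: float, baseline_coverage: float) -> float:
    """log2 of tumor-to-baseline normalized coverage."""
    if gene_coverage <= 0 or baseline_coverage <= 0:
        raise ValueError("coverages must be > 0")
    return math.log2(gene_coverage / baseline_coverage)


def gene_copy_number(log_ratio: float, tumor_fraction: float) -> float:
    """Absolute copy number from a coverage log-ratio at known purity.

    Unidentifiable at tumor_fraction = 0 (rejected); floored at 0 copies.
    """
    if not (0.0 < tumor_fraction <= 1.0):
        raise ValueError("tumor_fraction must be in (0,1]")
    copies = (2.0 * 2.0**log_ratio - 2.0 * (1.0 - tumor_fraction)) / tumor_fraction
    return max(copies, 0.0)


def estimate_baseline_sd(log_ratios: Sequence[float]) -> float:
    """Per-gene sd of the log-ratio among tumor-fraction-zero samples."""
    if len(log_ratios) < MIN_BASELINE_SAMPLES:
        raise ValueError(
            f"need >= {MIN_BASELINE_SAMPLES} zero-TF baseline samples, "
            f"got {len(log_ratios)}"
        )
    return float(np.std(log_ratios, ddof=1))


def copy_number_ci(
    log_ratio: float,
    tumor_fraction: float,
    baseline_sd: float,
    confidence: float = 0.95,
) -> tuple[float, float]:
    """95% CI: log_ratio +/- z*sd transformed through the copy-number model."""
    if baseline_sd < 0:
        raise ValueError("baseline_sd must be >= 0")
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    lo = gene_copy_number(log_ratio - z * baseline_sd, tumor_fraction)
    hi = gene_copy_number(log_ratio + z * baseline_sd, tumor_fraction)
    return lo, hi


def call_amplification(copies: float, threshold: float = DEFAULT_AMP_THRESHOLD) -> bool:
    """Amplified iff copies >= threshold (boundary inclusive)."""
    if copies < 0:
        raise ValueError("copies must be >= 0")
    return copies >= threshold


def gene_copy_numbers(
    gene_coverage: Mapping[str, float],
    tumor_fraction: float,
    baseline_mean: Mapping[str, float],
    baseline_sd: Mapping[str, float],
    amp_threshold: float = DEFAULT_AMP_THRESHOLD,
) -> list[GeneCopyNumber]:
    """Copy-number calls for every gene shared with the baseline tables."""
    out = []
    for gene in sorted(gene_coverage):
        if gene not in baseline_mean:
            continue
        lr = gene_log_ratio(gene_coverage[gene], baseline_mean[gene])
        cn = gene_copy_number(lr, tumor_fraction)
        lo, hi = copy_number_ci(lr, tumor_fraction, baseline_sd.get(gene, 0.0))
        out.append(
            GeneCopyNumber(gene, lr, cn, lo, hi, call_amplification(cn, amp_threshold))
        )
    return out


def baseline_from_samples(
    coverages: Sequence[Mapping[str, float]],
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-gene baseline mean coverage and log-ratio sd from zero-TF samples.

    The baseline mean anchors the log-ratio; the sd of each sample's
    log2(coverage / mean) around it feeds the confidence interval.
    """
    if len(coverages) < MIN_BASELINE_SAMPLES:
        raise ValueError(
            f"need >= {MIN_BASELINE_SAMPLES} zero-TF baseline samples, "
            f"got {len(coverages)}"
        )
    genes = set(coverages[0])
    for c in coverages[1:]:
        genes &= set(c)
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    for gene in sorted(genes):
        vals = np.array([c[gene] for c in coverages], dtype=float)
        if (vals <= 0).any():
            raise ValueError(f"non-positive baseline coverage for {gene}")
        m = float(np.exp2(np.mean(np.log2(vals))))  # geometric mean on log2 scale
        mean[gene] = m
        sd[gene] = estimate_baseline_sd(list(np.log2(vals / m)))
    return mean, sd


def copy_number_table(calls: Sequence[GeneCopyNumber], sample_id: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "gene": [c.gene for c in calls],
            "log_ratio": [c.log_ratio for c in calls],
            "copy_number": [c.copy_number for c in calls],
            "ci_low": [c.ci_low for c in calls],
            "ci_high": [c.ci_high for c in calls],
            "amplified": [c.amplified for c in calls],
        }
    )
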