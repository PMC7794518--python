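"""Core record types shared by all pipeline stages.

A :class:`VariantObservation` is one candidate variant seen in one sequenced
sample, carrying the read-level evidence the somatic filters act on.  A
:class:`SampleRecord` bundles one sample's observations with its depth
profile and per-gene coverage; a :class:`PatientCase` groups a patient's
germline (gDNA) sample with all serial plasma (cfDNA) and tissue samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

COMPARTMENTS = ("cfDNA", "tissue", "gDNA")
EFFECTS = ("protein_altering", "silent")
REGION_FLAGS = ("autosome", "chr9", "TERT_promoter", "amplified")

#: (chrom, pos, ref, alt) — the identity used to match variants across samples
VariantKey = tuple[str, int, str, str]


def variant_key_str(key: VariantKey) -> str:
    """Serialize a variant key as ``chrom:pos:ref:alt`` (used in JSON/TSV)."""
    return f"{key[0]}:{key[1]}:{key[2]}:{key[3]}"


def parse_variant_key(s: str) -> VariantKey:
    chrom, pos, ref, alt = s.split(":")
    return (chrom, int(pos), ref, alt)


@dataclass(frozen=True)
class VariantObservation:
    """One candidate variant in one sample.

    ``mean_mapq_alt`` is the mean mapping quality of the mutation-supporting
    reads; ``mean_end_distance_alt`` is the mean distance (bases) of the
    mutant allele from the nearest read end among those reads — low values
    are characteristic of fixation/end-repair artifacts.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    effect: str
    depth: int
    alt_reads: int
    mean_mapq_alt: float
    mean_end_distance_alt: float
    region_flag: str = "autosome"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.depth < 0:
            raise ValueError(f"depth must be >= 0, got {self.depth}")
        if not (0 <= self.alt_reads <= self.depth):
            raise ValueError(
                f"alt_reads must satisfy 0 <= alt_reads <= depth, "
                f"got alt_reads={self.alt_reads}, depth={self.depth}"
            )
        if self.effect not in EFFECTS:
            raise ValueError(f"effect must be one of {EFFECTS}, got {self.effect!r}")
        if self.region_flag not in REGION_FLAGS:
            raise ValueError(
                f"region_flag must be one of {REGION_FLAGS}, got {self.region_flag!r}"
            )

    @property
    def vaf(self) -> float:
        """Variant allele fraction alt_reads / depth (0 when depth is 0)."""
        return self.alt_reads / self.depth if self.depth > 0 else 0.0

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class DepthProfile:
    """Per-sample sequencing-depth histogram over the panel footprint."""

    depth_bins: tuple[int, ...]
    n_sites: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.depth_bins) != len(self.n_sites):
            raise ValueError("depth_bins and n_sites must have equal length")
        if any(d < 0 for d in self.depth_bins) or any(n < 0 for n in self.n_sites):
            raise ValueError("depth bins and site counts must be non-negative")

    @property
    def footprint(self) -> int:
        """Total number of sites in the profile."""
        return int(sum(self.n_sites))

    @classmethod
    def from_site_depths(cls, depths: np.ndarray) -> "DepthProfile":
        """Build a histogram from a vector of per-site depths."""
        depths = np.asarray(depths, dtype=np.int64)
        if depths.size == 0:
            raise ValueError("empty depth vector")
        if (depths < 0).any():
            raise ValueError("negative depths")
        counts = np.bincount(depths)
        nonzero = np.nonzero(counts)[0]
        return cls(tuple(int(d) for d in nonzero), tuple(int(counts[d]) for d in nonzero))

    def sites_at_least(self, min_depth: int) -> int:
        """Number of sites with depth >= ``min_depth``."""
        return int(
            sum(n for d, n in zip(self.depth_bins, self.n_sites) if d >= min_depth)
        )


@dataclass
class SampleRecord:
    """One sequenced sample with its variant observations and coverage."""

    patient_id: str
    sample_id: str
    compartment: str
    assay: str = "targeted"
    timepoint_days: int = 0
    treatment_context: str = "unknown"
    variants: list[VariantObservation] = field(default_factory=list)
    depth_profile: Optional[DepthProfile] = None
    gene_coverage: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"compartment must be one of {COMPARTMENTS}, got {self.compartment!r}"
            )

    def variants_by_key(self) -> dict[VariantKey, VariantObservation]:
        return {v.key: v for v in self.variants}


@dataclass
class PatientCase:
    """A patient's gDNA truth plus all serial cfDNA/tissue samples."""

    patient_id: str
    samples: list[SampleRecord] = field(default_factory=list)

    def by_compartment(self, compartment: str) -> list[SampleRecord]:
        return [s for s in self.samples if s.compartment == compartment]

    @property
    def gdna(self) -> SampleRecord:
        gdna = self.by_compartment("gDNA")
        if not gdna:
            raise ValueError(f"patient {self.patient_id} has no gDNA sample")
        return gdna[0]

    @property
    def tumor_samples(self) -> list[SampleRecord]:
        return [s for s in self.samples if s.compartment in ("cfDNA", "tissue")]
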