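"""Synthetic paired cfDNA/tissue/germline cohort generator with known truth.

Emulates a targeted-panel liquid-biopsy study of metastatic urothelial
carcinoma: each patient gets a leukocyte gDNA sample, serial plasma cfDNA
samples (~1040x unique depth) and serial tumor tissue samples (~370x), a
truncal/subclonal clone tree with binomially sampled read support, germline
heterozygous variants, clonal-hematopoiesis (CHIP) variants shared between
gDNA and cfDNA, FFPE-like tissue artifacts with short read-end distances,
and amplified oncogenes visible in per-gene coverage.  Ground truth (clone
tree, per-sample tumor fractions, per-variant true VAFs, confounder labels)
is returned alongside, so every downstream stage is testable without
controlled-access patient data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .records import (
    DepthProfile,
    PatientCase,
    SampleRecord,
    VariantKey,
    VariantObservation,
    variant_key_str,
)

# Bladder-cancer targeted panel: gene -> chromosome.  chr9 genes are excluded
# from tumor-fraction estimation downstream (frequent copy-neutral LOH), as is
# the TERT promoter (low depth) — both are present so those rules are exercised.
PANEL_GENES: dict[str, str] = {
    "TP53": "chr17",
    "RB1": "chr13",
    "ARID1A": "chr1",
    "KMT2D": "chr12",
    "KMT2C": "chr7",
    "KDM6A": "chrX",
    "STAG2": "chrX",
    "PIK3CA": "chr3",
    "FGFR3": "chr4",
    "FBXW7": "chr4",
    "ERBB2": "chr17",
    "ERBB3": "chr12",
    "ERCC2": "chr19",
    "ATM": "chr11",
    "BRCA1": "chr17",
    "BRCA2": "chr13",
    "EP300": "chr22",
    "CREBBP": "chr16",
    "ELF3": "chr1",
    "NFE2L2": "chr2",
    "HRAS": "chr11",
    "KRAS": "chr12",
    "NRAS": "chr1",
    "CCND1": "chr11",
    "MDM2": "chr12",
    "E2F3": "chr6",
    "PPARG": "chr3",
    "CDKN2A": "chr9",
    "CDKN2B": "chr9",
    "TSC1": "chr9",
    "TERT": "chr5",
    "DNMT3A": "chr2",
    "TET2": "chr4",
    "ASXL1": "chr20",
}

#: Genes linked to hematopoietic stem-cell clonal expansion (CHIP).
DEFAULT_CHIP_GENES: tuple[str, ...] = ("DNMT3A", "TET2", "ASXL1")

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class Clone:
    clone_id: int
    parent_id: Optional[int]
    #: cancer-cell fraction per tumor sample_id (gDNA carries no clones)
    ccf: dict

    def __post_init__(self) -> None:
        for sid, c in self.ccf.items():
            if not (0.0 <= c <= 1.0):
                raise ValueError(f"CCF for {sid} out of [0,1]: {c}")


@dataclass(frozen=True)
class CloneMutation:
    mutation_id: str
    clone_id: int
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    effect: str
    multiplicity: int  # mutant-allele copies in the tumor genome
    total_copies: int  # total copies at the locus in the tumor genome

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class CloneTree:
    """Truncal/subclonal structure with per-sample cancer-cell fractions."""

    clones: list[Clone]
    mutations: list[CloneMutation]

    def __post_init__(self) -> None:
        by_id = {c.clone_id: c for c in self.clones}
        if len(by_id) != len(self.clones):
            raise ValueError("duplicate clone ids")
        for c in self.clones:
            if c.parent_id is None:
                continue
            parent = by_id[c.parent_id]
            for sid, ccf in c.ccf.items():
                if ccf > parent.ccf.get(sid, 0.0) + 1e-9:
                    raise ValueError(
                        f"clone {c.clone_id} CCF exceeds parent in sample {sid}"
                    )
        clone_ids = set(by_id)
        for m in self.mutations:
            if m.clone_id not in clone_ids:
                raise ValueError(f"mutation {m.mutation_id} has unknown clone")

    def clone(self, clone_id: int) -> Clone:
        return next(c for c in self.clones if c.clone_id == clone_id)


@dataclass
class TruthModel:
    """Ground truth for one synthetic patient.

    ``labels`` classifies every variant key as ``somatic``, ``germline``,
    ``chip`` or ``ffpe_artifact``; ``true_vaf`` maps sample_id -> key -> the
    noiseless allele fraction the binomial read sampler was driven with.
    """

    patient_id: str
    tumor_fraction: dict  # sample_id -> true TF (gDNA: 0.0)
    clone_tree: CloneTree
    true_vaf: dict  # sample_id -> {key_str: vaf}
    labels: dict  # key_str -> label
    copy_states: dict  # gene -> integer copy number (diploid genes omitted)


@dataclass
class SimulationConfig:
    """Study-design knobs for the synthetic cohort.

    Defaults mirror the targeted-panel study the generator emulates: median
    unique depths near 1040x (cfDNA), 370x (tissue) and 300x (gDNA); plasma
    tumor fractions log-uniform over [0.005, 0.6] (median ~5-8%, right-skewed
    as in real cohorts) and tissue purities over [0.05, 0.9]; a handful of
    truncal and subclonal mutations per tumor; ~10 germline heterozygous
    variants and 2 CHIP variants per patient; serial sampling with clonal
    drift confined to tissue (re-biopsies sample different tumor foci, while
    plasma integrates over the whole burden).
    """

    n_patients: int = 20
    tf_range: dict = field(
        default_factory=lambda: {"cfDNA": (0.005, 0.6), "tissue": (0.05, 0.9)}
    )
    tf_sampling: str = "loguniform"  # or "uniform"
    depth_mean: dict = field(
        default_factory=lambda: {"cfDNA": 1040, "tissue": 370, "gDNA": 300}
    )
    depth_nb_size: float = 10.0  # negative-binomial size (inverse dispersion)
    panel_footprint: int = 300_000
    n_truncal: int = 6
    n_subclonal: int = 4
    loh_fraction: float = 0.5  # fraction of truncal mutations on 1-copy LOH loci
    germline_het_count: int = 10
    chip_count: int = 2
    chip_vaf_range: tuple = (0.005, 0.05)
    chip_genes: tuple = DEFAULT_CHIP_GENES
    ffpe_noise_rate: float = 3.0  # mean artifacts per tissue sample
    serial_timepoints: int = 2
    drift_prob: float = 0.5  # P(subclone absent at a later timepoint)
    drift_compartments: tuple = ("tissue",)
    subclone_private_prob: float = 0.35  # P(subclone restricted to one compartment)
    amplified_genes: tuple = (("ERBB2", 20),)
    background_error_rate: float = 5e-4  # per-site sequencing error for absent alleles
    cn_log_noise_sd: float = 0.1  # sd of per-gene coverage log2-ratio noise
    seed: int = 0

    def validate(self) -> list[str]:
        errors = []
        if self.n_patients < 1:
            errors.append("n_patients must be >= 1")
        for comp, (lo, hi) in self.tf_range.items():
            if not (0.0 <= lo <= hi <= 1.0):
                errors.append(f"tf_range[{comp}] must be within [0,1] with lo <= hi")
        if self.tf_sampling not in ("loguniform", "uniform"):
            errors.append("tf_sampling must be 'loguniform' or 'uniform'")
        for comp, d in self.depth_mean.items():
            if d < 0:
                errors.append(f"depth_mean[{comp}] must be >= 0")
        if self.depth_nb_size <= 0:
            errors.append("depth_nb_size must be > 0")
        if self.panel_footprint <= 0:
            errors.append("panel_footprint must be > 0")
        for name in ("n_truncal", "n_subclonal", "germline_het_count", "chip_count"):
            if getattr(self, name) < 0:
                errors.append(f"{name} must be >= 0")
        lo, hi = self.chip_vaf_range
        if not (0.0 <= lo <= hi <= 1.0):
            errors.append("chip_vaf_range must be within [0,1]")
        for name in ("loh_fraction", "drift_prob", "subclone_private_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                errors.append(f"{name} must be in [0,1]")
        if self.ffpe_noise_rate < 0:
            errors.append("ffpe_noise_rate must be >= 0")
        if self.serial_timepoints < 1:
            errors.append("serial_timepoints must be >= 1")
        if not (0.0 <= self.background_error_rate <= 1.0):
            errors.append("background_error_rate must be in [0,1]")
        if self.cn_log_noise_sd < 0:
            errors.append("cn_log_noise_sd must be >= 0")
        for gene, cn in self.amplified_genes:
            if cn < 0:
                errors.append(f"amplified copy number for {gene} must be >= 0")
        return errors


def expected_vaf(
    ccf: float, tumor_fraction: float, total_copies: int, mutant_copies: int
) -> float:
    """Expected allele fraction under the standard purity/copy mixture.

    A mutation carried by a clone at cancer-cell fraction ``ccf`` on
    ``mutant_copies`` of ``total_copies`` tumor alleles, diluted by diploid
    normal DNA at fraction (1 - tumor_fraction):

        vaf = tf * ccf * mutant / (tf * total + (1 - tf) * 2)

    With LOH (total = mutant = 1) and ccf = 1 this reduces to tf / (2 - tf),
    the form the tumor-fraction estimator inverts.
    """
    if ccf < 0 or tumor_fraction < 0 or total_copies < 0 or mutant_copies < 0:
        raise ValueError("negative inputs not allowed")
    if ccf > 1 or tumor_fraction > 1:
        raise ValueError("ccf and tumor_fraction must be <= 1")
    if mutant_copies > total_copies:
        raise ValueError("mutant_copies must be <= total_copies")
    if tumor_fraction == 0.0:
        return 0.0
    denom = tumor_fraction * total_copies + (1.0 - tumor_fraction) * 2.0
    if denom == 0.0:
        return 0.0
    return tumor_fraction * ccf * mutant_copies / denom


def simulate_read_support(
    true_vaf: float, depth: int, rng: np.random.Generator
) -> tuple[int, int]:
    """Binomially sampled mutant-read count at a locus: (alt_reads, depth)."""
    if not (0.0 <= true_vaf <= 1.0):
        raise ValueError("true_vaf must be in [0,1]")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    return int(rng.binomial(depth, true_vaf)), int(depth)


def _draw_tf(config: SimulationConfig, compartment: str, rng: np.random.Generator) -> float:
    lo, hi = config.tf_range[compartment]
    if lo == hi:
        return float(lo)
    if config.tf_sampling == "uniform":
        return float(rng.uniform(lo, hi))
    lo_eff = max(lo, 1e-4)
    return float(np.exp(rng.uniform(np.log(lo_eff), np.log(hi))))


def _draw_depth(config: SimulationConfig, compartment: str, rng: np.random.Generator, size=None):
    mean = config.depth_mean[compartment]
    if mean == 0:
        return np.zeros(size or 1, dtype=np.int64) if size else 0
    r = config.depth_nb_size
    p = r / (r + mean)
    out = rng.negative_binomial(r, p, size=size)
    return out if size else int(out)


def _random_locus(
    gene: str, rng: np.random.Generator, used: set[VariantKey]
) -> VariantKey:
    chrom = PANEL_GENES[gene]
    while True:
        pos = int(rng.integers(1_000_000, 3_000_000))
        ref, alt = rng.choice(len(_BASES), size=2, replace=False)
        key = (chrom, pos, _BASES[ref], _BASES[alt])
        if key not in used:
            used.add(key)
            return key


def _region_flag(gene: str, amplified: dict) -> str:
    if gene in amplified:
        return "amplified"
    if PANEL_GENES[gene] == "chr9":
        return "chr9"
    if gene == "TERT":
        return "TERT_promoter"
    return "autosome"


def simulate_patient(
    config: SimulationConfig, patient_seed: int, patient_id: Optional[str] = None
) -> tuple[PatientCase, TruthModel]:
    """Simulate one patient: gDNA + serial cfDNA and tissue samples.

    Every truth locus of the patient is reported in every sample (with
    binomial read support, possibly zero alt reads), so paired-sample pileup
    queries for concordance are answered from the emitted files alone.
    """
    errors = config.validate()
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    rng = np.random.default_rng(patient_seed)
    pid = patient_id or f"P{patient_seed % 10_000:04d}"
    amplified = {g: int(cn) for g, cn in config.amplified_genes}

    # ---- sample roster -------------------------------------------------
    samples: list[SampleRecord] = []
    gdna_id = f"{pid}_gDNA"
    samples.append(SampleRecord(pid, gdna_id, "gDNA", treatment_context="baseline"))
    tumor_ids: dict[str, list[str]] = {"cfDNA": [], "tissue": []}
    for comp in ("cfDNA", "tissue"):
        for t in range(config.serial_timepoints):
            sid = f"{pid}_{comp}_t{t}"
            tumor_ids[comp].append(sid)
            samples.append(
                SampleRecord(
                    pid,
                    sid,
                    comp,
                    timepoint_days=90 * t,
                    treatment_context="pre_first_line" if t == 0 else "on_treatment",
                )
            )

    # ---- tumor fractions ----------------------------------------------
    tumor_fraction: dict[str, float] = {gdna_id: 0.0}
    for comp in ("cfDNA", "tissue"):
        base = _draw_tf(config, comp, rng)
        lo, hi = config.tf_range[comp]
        for t, sid in enumerate(tumor_ids[comp]):
            if t == 0:
                tf = base
            else:
                # serial TF correlated with baseline (log-normal jitter)
                tf = float(np.clip(base * np.exp(rng.normal(0.0, 0.4)), lo, hi))
            tumor_fraction[sid] = tf

    # ---- clone tree ----------------------------------------------------
    tumor_sids = tumor_ids["cfDNA"] + tumor_ids["tissue"]
    truncal = Clone(0, None, {sid: 1.0 for sid in tumor_sids})
    clones = [truncal]
    n_subclones = min(3, config.n_subclonal) if config.n_subclonal > 0 else 0
    for c in range(1, n_subclones + 1):
        base_ccf = float(rng.uniform(0.15, 0.7))
        private_to = None
        if rng.uniform() < config.subclone_private_prob:
            # subclone restricted to one compartment (absent from the other)
            private_to = "cfDNA" if rng.uniform() < 0.5 else "tissue"
        ccf: dict[str, float] = {}
        for comp in ("cfDNA", "tissue"):
            for t, sid in enumerate(tumor_ids[comp]):
                if private_to is not None and comp != private_to:
                    ccf[sid] = 0.0
                elif (
                    t > 0
                    and comp in config.drift_compartments
                    and rng.uniform() < config.drift_prob
                ):
                    ccf[sid] = 0.0
                else:
                    ccf[sid] = float(base_ccf * rng.uniform(0.6, 1.0))
        clones.append(Clone(c, 0, ccf))

    used_keys: set[VariantKey] = set()
    chip_set = set(config.chip_genes)
    somatic_pool = [
        g for g in PANEL_GENES if g not in chip_set
    ]
    # truncal LOH mutations must be usable for TF estimation: autosomal,
    # outside chr9/TERT/amplified regions
    eligible_pool = [
        g
        for g in somatic_pool
        if _region_flag(g, amplified) == "autosome" and PANEL_GENES[g] not in ("chrX", "chrY")
    ]

    mutations: list[CloneMutation] = []
    n_loh = math.ceil(config.loh_fraction * config.n_truncal)
    for i in range(config.n_truncal):
        loh = i < n_loh
        gene = str(rng.choice(eligible_pool if loh else somatic_pool))
        chrom, pos, ref, alt = _random_locus(gene, rng, used_keys)
        if gene in amplified:
            total = amplified[gene]
            mult = max(1, total - 1)
        elif loh:
            total, mult = 1, 1
        else:
            total, mult = 2, 1
        mutations.append(
            CloneMutation(
                f"{pid}_trunk{i}",
                0,
                chrom,
                pos,
                ref,
                alt,
                gene,
                "protein_altering" if rng.uniform() < 0.8 else "silent",
                mult,
                total,
            )
        )
    for i in range(config.n_subclonal):
        clone_id = 1 + (i % n_subclones) if n_subclones else 0
        gene = str(rng.choice(somatic_pool))
        chrom, pos, ref, alt = _random_locus(gene, rng, used_keys)
        if gene in amplified:
            total = amplified[gene]
            mult = max(1, total - 1)
        else:
            total, mult = 2, 1
        mutations.append(
            CloneMutation(
                f"{pid}_sub{i}",
                clone_id,
                chrom,
                pos,
                ref,
                alt,
                gene,
                "protein_altering" if rng.uniform() < 0.8 else "silent",
                mult,
                total,
            )
        )
    tree = CloneTree(clones, mutations)

    # ---- confounders ---------------------------------------------------
    labels: dict[str, str] = {}
    true_vaf: dict[str, dict[str, float]] = {s.sample_id: {} for s in samples}
    all_sids = [s.sample_id for s in samples]

    for m in mutations:
        labels[variant_key_str(m.key)] = "somatic"
        clone = tree.clone(m.clone_id)
        for sid in all_sids:
            tf = tumor_fraction[sid]
            ccf = clone.ccf.get(sid, 0.0)
            true_vaf[sid][variant_key_str(m.key)] = expected_vaf(
                ccf, tf, m.total_copies, m.multiplicity
            ) if tf > 0 else 0.0

    germline_meta: dict[str, tuple[str, str]] = {}  # key_str -> (gene, effect)
    for i in range(config.germline_het_count):
        gene = str(rng.choice(list(PANEL_GENES)))
        key = _random_locus(gene, rng, used_keys)
        ks = variant_key_str(key)
        labels[ks] = "germline"
        germline_meta[ks] = (gene, "protein_altering" if rng.uniform() < 0.5 else "silent")
        for sid in all_sids:
            true_vaf[sid][ks] = 0.5

    chip_meta: dict[str, tuple[str, str]] = {}
    for i in range(config.chip_count):
        gene = str(rng.choice(list(config.chip_genes)))
        key = _random_locus(gene, rng, used_keys)
        ks = variant_key_str(key)
        labels[ks] = "chip"
        chip_meta[ks] = (gene, "protein_altering")
        lo, hi = config.chip_vaf_range
        v = float(rng.uniform(lo, hi))
        for sid in all_sids:
            comp = next(s.compartment for s in samples if s.sample_id == sid)
            if comp == "tissue":
                true_vaf[sid][ks] = 0.0
            else:
                # correlated between gDNA and each cfDNA draw
                true_vaf[sid][ks] = float(np.clip(v * rng.uniform(0.8, 1.25), 0.0, 1.0))

    ffpe_meta: dict[str, tuple[str, str, str]] = {}  # key -> (gene, effect, sample)
    for sid in tumor_ids["tissue"]:
        n_art = rng.poisson(config.ffpe_noise_rate)
        for _ in range(n_art):
            gene = str(rng.choice(somatic_pool))
            key = _random_locus(gene, rng, used_keys)
            ks = variant_key_str(key)
            labels[ks] = "ffpe_artifact"
            ffpe_meta[ks] = (gene, "protein_altering", sid)
            for s2 in all_sids:
                true_vaf[s2][ks] = (
                    float(rng.uniform(0.005, 0.05)) if s2 == sid else 0.0
                )

    # ---- per-variant metadata (gene/effect/region/end-distance class) --
    meta: dict[str, tuple[str, str, str, bool]] = {}  # key -> (gene, effect, flag, artifact?)
    for m in mutations:
        meta[variant_key_str(m.key)] = (
            m.gene,
            m.effect,
            _region_flag(m.gene, amplified),
            False,
        )
    for ks, (gene, effect) in germline_meta.items():
        meta[ks] = (gene, effect, _region_flag(gene, amplified), False)
    for ks, (gene, effect) in chip_meta.items():
        meta[ks] = (gene, effect, _region_flag(gene, amplified), False)
    for ks, (gene, effect, _sid) in ffpe_meta.items():
        meta[ks] = (gene, effect, _region_flag(gene, amplified), True)

    # ---- observations --------------------------------------------------
    ordered_keys = sorted(meta)  # deterministic emission order
    for s in samples:
        for ks in ordered_keys:
            gene, effect, flag, is_artifact = meta[ks]
            v = true_vaf[s.sample_id].get(ks, 0.0)
            p = v if v > 0 else config.background_error_rate
            depth = _draw_depth(config, s.compartment, rng)
            alt, depth = simulate_read_support(min(p, 1.0), depth, rng)
            chrom, pos, ref, alt_base = ks.split(":")
            mapq = float(np.clip(rng.normal(58.0, 1.5), 35.0, 60.0))
            if is_artifact:
                end_dist = float(rng.uniform(4.0, 15.0))
            else:
                end_dist = float(rng.uniform(32.0, 55.0))
            s.variants.append(
                VariantObservation(
                    chrom=chrom,
                    pos=int(pos),
                    ref=ref,
                    alt=alt_base,
                    gene=gene,
                    effect=effect,
                    depth=depth,
                    alt_reads=alt,
                    mean_mapq_alt=round(mapq, 3),
                    mean_end_distance_alt=round(end_dist, 3),
                    region_flag=flag,
                )
            )

    # ---- depth histograms and gene coverage ----------------------------
    copy_states = dict(amplified)
    for s in samples:
        site_depths = _draw_depth(config, s.compartment, rng, size=config.panel_footprint)
        s.depth_profile = DepthProfile.from_site_depths(site_depths)
        tf = tumor_fraction[s.sample_id]
        for gene in PANEL_GENES:
            cn = copy_states.get(gene, 2)
            ratio = (tf * cn + 2.0 * (1.0 - tf)) / 2.0
            noise = rng.normal(0.0, config.cn_log_noise_sd)
            s.gene_coverage[gene] = round(float(ratio * 2.0 ** noise), 6)

    case = PatientCase(pid, samples)
    truth = TruthModel(
        patient_id=pid,
        tumor_fraction=tumor_fraction,
        clone_tree=tree,
        true_vaf=true_vaf,
        labels=labels,
        copy_states=copy_states,
    )
    return case, truth


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[PatientCase], dict[str, TruthModel]]:
    """Simulate ``config.n_patients`` patients from one global seed.

    Per-patient streams are derived by spawning the root seed sequence, so a
    cohort is reproducible patient-by-patient and order-independent.
    """
    errors = config.validate()
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_patients)
    patients: list[PatientCase] = []
    truths: dict[str, TruthModel] = {}
    for i, child in enumerate(children):
        # derive a bounded integer seed for the per-patient generator
        pseed = int(child.generate_state(1)[0] % (2**31 - 1))
        case, truth = simulate_patient(config, pseed, patient_id=f"P{i:04d}")
        patients.append(case)
        truths[case.patient_id] = truth
    return patients, truths
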