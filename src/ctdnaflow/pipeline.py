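"""End-to-end orchestration: simulate -> filter -> TF -> TMB -> CNV -> concordance.

A :class:`RunConfig` carries every stage's parameters with defaults set to
the study thresholds (8 mutant reads; 1%/8% VAF floors; 3x gDNA ratio;
mapping quality > 30; read-end proximity > 25; 95% binomial quantile;
subclonal below 25% of tumor fraction; 1% ctDNA detection threshold).
``run_pipeline`` executes the enabled stages in dependency order, writes
every intermediate as TSV/JSON under the run directory, embeds the resolved
config, and emits a cohort-level summary JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .concordance import (
    CohortConcordanceReport,
    SampleAnalysis,
    cohort_concordance_report,
)
from .copy_number import baseline_from_samples, copy_number_table, gene_copy_numbers
from .records import PatientCase, variant_key_str
from .synthetic_cohort import (
    DEFAULT_CHIP_GENES,
    SimulationConfig,
    simulate_cohort,
)
from .tmb_estimation import tmb_estimate
from .tumor_fraction import estimate_tumor_fraction
from .variant_filtering import FilterParams, filter_sample

log = logging.getLogger("ctdnaflow")

ALL_STAGES = ("simulate", "filter", "tf", "tmb", "cnv", "concordance")
_STAGE_DEPS = {
    "simulate": (),
    "filter": ("simulate",),
    "tf": ("filter",),
    "tmb": ("filter",),
    "cnv": ("tf",),
    "concordance": ("tf",),
}


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and offending sample."""

    def __init__(self, stage: str, sample_id: Optional[str], message: str):
        self.stage = stage
        self.sample_id = sample_id
        super().__init__(f"[{stage}] sample={sample_id or '-'}: {message}")


@dataclass
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    filters: FilterParams = field(default_factory=FilterParams)
    strict_chip: bool = False
    chip_genes: tuple = DEFAULT_CHIP_GENES
    tf_quantile: float = 0.95
    detection_threshold: float = 0.01
    tmb_include_silent: bool = False
    amp_threshold: float = 5.0
    stages: tuple = ALL_STAGES
    #: read an existing cohort directory instead of simulating
    input_cohort: Optional[str] = None
    schema_version: int = 1

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "simulation" in d and isinstance(d["simulation"], dict):
            sim = dict(d["simulation"])
            sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
            sim_unknown = set(sim) - sim_known
            if sim_unknown:
                raise ValueError(f"unknown simulation keys: {sorted(sim_unknown)}")
            if "tf_range" in sim:
                sim["tf_range"] = {k: tuple(v) for k, v in sim["tf_range"].items()}
            if "amplified_genes" in sim:
                sim["amplified_genes"] = tuple(
                    (g, int(cn)) for g, cn in sim["amplified_genes"]
                )
            for key in ("chip_vaf_range", "chip_genes", "drift_compartments"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            d["simulation"] = SimulationConfig(**sim)
        if "filters" in d and isinstance(d["filters"], dict):
            flt_known = {f.name for f in dataclasses.fields(FilterParams)}
            flt_unknown = set(d["filters"]) - flt_known
            if flt_unknown:
                raise ValueError(f"unknown filter keys: {sorted(flt_unknown)}")
            d["filters"] = FilterParams(**d["filters"])
        for key in ("chip_genes", "stages"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def validate_config(config: RunConfig) -> list[str]:
    """Check every invariant; returns a list of per-field error messages."""
    errors = list(config.simulation.validate())
    f = config.filters
    if f.min_alt_reads < 0:
        errors.append("filters.min_alt_reads must be >= 0")
    for name in ("min_vaf_cfdna", "min_vaf_tissue"):
        v = getattr(f, name)
        if not (0.0 <= v <= 1.0):
            errors.append(f"filters.{name} must be in [0,1]")
    if f.gdna_ratio < 0:
        errors.append("filters.gdna_ratio must be >= 0")
    if f.min_mapq < 0:
        errors.append("filters.min_mapq must be >= 0")
    if f.min_end_distance < 0:
        errors.append("filters.min_end_distance must be >= 0")
    if f.background_rate is not None and not (0.0 <= f.background_rate <= 1.0):
        errors.append("filters.background_rate must be in [0,1]")
    if not (0.0 < f.background_alpha < 1.0):
        errors.append("filters.background_alpha must be in (0,1)")
    if not (0.0 < config.tf_quantile < 1.0):
        errors.append("tf_quantile must be in (0,1); 1.0 is a degenerate bound")
    if not (0.0 <= config.detection_threshold <= 1.0):
        errors.append("detection_threshold must be in [0,1]")
    if config.amp_threshold < 0:
        errors.append("amp_threshold must be >= 0")
    for stage in config.stages:
        if stage not in ALL_STAGES:
            errors.append(f"unknown stage {stage!r}")
            continue
        for dep in _STAGE_DEPS[stage]:
            if dep not in config.stages:
                errors.append(f"stage {stage!r} requires stage {dep!r}")
    return errors


def analyze_cohort(
    patients: list[PatientCase], config: RunConfig
) -> list[SampleAnalysis]:
    """Filter every tumor sample and estimate its tumor fraction."""
    analyses: list[SampleAnalysis] = []
    for patient in patients:
        try:
            gdna = patient.gdna
        except ValueError as exc:
            raise PipelineError("filter", patient.patient_id, str(exc)) from exc
        for sample in patient.tumor_samples:
            kept, _audit = filter_sample(
                sample,
                gdna,
                chip_gene_list=config.chip_genes,
                strict_chip=config.strict_chip,
                params=config.filters,
            )
            tf = estimate_tumor_fraction(
                kept,
                compartment=sample.compartment,
                quantile=config.tf_quantile,
                detection_threshold=config.detection_threshold,
            )
            analyses.append(SampleAnalysis(sample, kept, tf))
    return analyses


def _audit_frame(patients: list[PatientCase], config: RunConfig) -> pd.DataFrame:
    rows = []
    for patient in patients:
        gdna = patient.gdna
        for sample in patient.tumor_samples:
            _kept, audit = filter_sample(
                sample,
                gdna,
                chip_gene_list=config.chip_genes,
                strict_chip=config.strict_chip,
                params=config.filters,
            )
            for decision in audit:
                rows.append(
                    {
                        "sample_id": sample.sample_id,
                        "variant": variant_key_str(decision.variant_key),
                        "passed": decision.passed,
                        "failed_rules": ";".join(decision.reasons),
                        "warnings": ";".join(decision.warnings),
                    }
                )
    return pd.DataFrame(rows)


def _tf_frame(analyses: list[SampleAnalysis]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [x.sample.patient_id for x in analyses],
            "sample_id": [x.sample.sample_id for x in analyses],
            "compartment": [x.sample.compartment for x in analyses],
            "tumor_fraction": [x.tf.tumor_fraction for x in analyses],
            "adjusted_vaf": [x.tf.adjusted_vaf for x in analyses],
            "raw_max_vaf": [x.tf.raw_max_vaf for x in analyses],
            "source_variant": [
                variant_key_str(x.tf.source_variant) if x.tf.source_variant else ""
                for x in analyses
            ],
            "detected": [x.tf.detected for x in analyses],
            "evaluable": [x.tf.evaluable for x in analyses],
        }
    )


def _tmb_frames(
    analyses: list[SampleAnalysis], config: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    summary_rows, contrib_rows = [], []
    for x in analyses:
        if x.sample.depth_profile is None:
            raise PipelineError("tmb", x.sample.sample_id, "missing depth profile")
        est = tmb_estimate(
            x.kept, x.sample.depth_profile, include_silent=config.tmb_include_silent
        )
        summary_rows.append(
            {
                "sample_id": x.sample.sample_id,
                "compartment": x.sample.compartment,
                "tmb_per_mb": est.tmb_per_mb,
                "n_contributing": len(est.contributions),
                "n_excluded": len(est.excluded),
            }
        )
        for c in est.contributions:
            contrib_rows.append(
                {
                    "sample_id": x.sample.sample_id,
                    "variant": variant_key_str(c.variant_key),
                    "vaf": c.vaf,
                    "required_depth": c.required_depth,
                    "detectable_sites": c.detectable_sites,
                    "weight": c.weight,
                }
            )
    return pd.DataFrame(summary_rows), pd.DataFrame(contrib_rows)


def _cnv_frame(
    patients: list[PatientCase], analyses: list[SampleAnalysis], config: RunConfig
) -> pd.DataFrame:
    tf_by_sample = {x.sample.sample_id: x.tf.tumor_fraction for x in analyses}
    # baseline: samples with no evidence of tumor (gDNA has TF 0 by definition;
    # tumor samples estimated at TF 0 join the baseline pool)
    baseline_cov = []
    for p in patients:
        for s in p.samples:
            if not s.gene_coverage:
                continue
            if s.compartment == "gDNA" or tf_by_sample.get(s.sample_id, 1.0) == 0.0:
                baseline_cov.append(s.gene_coverage)
    mean, sd = baseline_from_samples(baseline_cov)
    frames = []
    for p in patients:
        for s in p.tumor_samples:
            tf = tf_by_sample.get(s.sample_id, 0.0)
            if tf <= 0.0 or not s.gene_coverage:
                continue  # copy number unidentifiable without tumor content
            calls = gene_copy_numbers(
                s.gene_coverage, tf, mean, sd, amp_threshold=config.amp_threshold
            )
            frames.append(copy_number_table(calls, s.sample_id))
    if not frames:
        return pd.DataFrame(
            columns=[
                "sample_id",
                "gene",
                "log_ratio",
                "copy_number",
                "ci_low",
                "ci_high",
                "amplified",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def _concordance_json(report: CohortConcordanceReport) -> dict:
    return {
        "n_pairs": len(report.pairs),
        "pair_patients": report.pair_patients,
        "n_shared": report.n_shared,
        "n_total": report.n_total,
        "fraction_shared": report.fraction_shared,
        "clonal_shared": report.clonal_shared,
        "clonal_total": report.clonal_total,
        "subclonal_shared": report.subclonal_shared,
        "subclonal_total": report.subclonal_total,
        "fisher_p": report.contingency.p_two_sided if report.contingency else None,
        "fisher_odds_ratio": (
            report.contingency.odds_ratio
            if report.contingency and np.isfinite(report.contingency.odds_ratio)
            else None
        ),
        "coverage_explained_n": report.coverage_explained_n,
        "exclusive_n": report.exclusive_n,
        "serial": {
            f"{pid}:{comp}": frac for (pid, comp), frac in sorted(report.serial.items())
        },
        "notes": report.notes,
    }


def _pairs_frame(report: CohortConcordanceReport) -> pd.DataFrame:
    rows = []
    for pid, pair in zip(report.pair_patients, report.pairs):
        rows.append(
            {
                "patient_id": pid,
                "sample_cfdna": pair.sample_a,
                "sample_tissue": pair.sample_b,
                "n_shared": len(pair.shared),
                "n_exclusive_cfdna": len(pair.exclusive_a),
                "n_exclusive_tissue": len(pair.exclusive_b),
                "fraction_shared": pair.fraction_shared,
                "n_coverage_explained": sum(
                    1 for v in pair.coverage_explained_flags.values() if v
                ),
            }
        )
    return pd.DataFrame(rows)


def _median(values) -> Optional[float]:
    values = [v for v in values if v is not None and np.isfinite(v)]
    return float(np.median(values)) if values else None


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Run enabled stages; returns the run directory.

    The run directory contains cohort/ (inputs), the per-stage TSV/JSON
    outputs, the resolved config, and summary.json.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    summary: dict = {
        "schema_version": config.schema_version,
        "seed": config.simulation.seed,
        "stages": list(config.stages),
    }

    # ---- simulate (or load) -------------------------------------------
    if config.input_cohort is not None:
        patients, truths = cio.read_cohort(config.input_cohort)
        log.info("loaded cohort from %s", config.input_cohort)
    elif "simulate" in config.stages:
        patients, truths = simulate_cohort(config.simulation)
        cio.write_cohort(patients, truths, out / "cohort")
        log.info("simulated %d patients", len(patients))
    else:
        raise ValueError("no input: enable 'simulate' or set input_cohort")
    summary["n_patients"] = len(patients)
    summary["n_samples"] = sum(len(p.samples) for p in patients)

    analyses: Optional[list[SampleAnalysis]] = None
    if "filter" in config.stages:
        try:
            analyses = analyze_cohort(patients, config)
            _audit_frame(patients, config).to_csv(
                out / "filter_audit.tsv", sep="\t", index=False
            )
        except PipelineError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise PipelineError("filter", None, str(exc)) from exc
        kept_rows = []
        for x in analyses:
            for v in x.kept:
                kept_rows.append(
                    {
                        "sample_id": x.sample.sample_id,
                        "variant": variant_key_str(v.key),
                        "gene": v.gene,
                        "effect": v.effect,
                        "vaf": v.vaf,
                        "depth": v.depth,
                        "alt_reads": v.alt_reads,
                    }
                )
        pd.DataFrame(kept_rows).to_csv(out / "kept_variants.tsv", sep="\t", index=False)
        summary["n_kept_variants"] = len(kept_rows)

    if "tf" in config.stages:
        assert analyses is not None
        tf_frame = _tf_frame(analyses)
        tf_frame.to_csv(out / "tumor_fraction.tsv", sep="\t", index=False)
        cf = tf_frame[tf_frame.compartment == "cfDNA"]
        summary["tf"] = {
            "median_cfdna_tf": _median(cf.tumor_fraction),
            "cfdna_detection_rate": (
                float(cf.detected.mean()) if len(cf) else None
            ),
            "n_cfdna_samples": int(len(cf)),
        }

    if "tmb" in config.stages:
        assert analyses is not None
        tmb_frame, contrib_frame = _tmb_frames(analyses, config)
        tmb_frame.to_csv(out / "tmb.tsv", sep="\t", index=False)
        contrib_frame.to_csv(out / "tmb_contributions.tsv", sep="\t", index=False)
        summary["tmb"] = {
            comp: _median(tmb_frame[tmb_frame.compartment == comp].tmb_per_mb)
            for comp in ("cfDNA", "tissue")
        }

    if "cnv" in config.stages:
        assert analyses is not None
        try:
            cnv_frame = _cnv_frame(patients, analyses, config)
        except ValueError as exc:
            raise PipelineError("cnv", None, str(exc)) from exc
        cnv_frame.to_csv(out / "copy_number.tsv", sep="\t", index=False)
        summary["cnv"] = {
            "n_amplified_calls": int(cnv_frame.amplified.sum()) if len(cnv_frame) else 0
        }

    if "concordance" in config.stages:
        assert analyses is not None
        report = cohort_concordance_report(analyses)
        payload = _concordance_json(report)
        with open(out / "concordance.json", "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
        _pairs_frame(report).to_csv(out / "concordance_pairs.tsv", sep="\t", index=False)
        serial_cf = [v for (p, c), v in report.serial.items() if c == "cfDNA"]
        serial_ti = [v for (p, c), v in report.serial.items() if c == "tissue"]
        summary["concordance"] = {
            "fraction_shared": report.fraction_shared,
            "n_pairs": len(report.pairs),
            "fisher_p": payload["fisher_p"],
            "serial_median_cfdna": _median(serial_cf),
            "serial_median_tissue": _median(serial_ti),
        }

    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    log.info("run complete: %s", out)
    return out
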