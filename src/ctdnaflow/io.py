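"""Readers and writers for the cohort's on-disk formats.

Primary dialect is plain TSV (UTF-8, 1-based positions): one variant table
and one depth histogram per sample, one per-gene coverage table per sample,
a cohort manifest, and a truth JSON.  An optional VCF 4.2 writer mirrors the
variant table (FORMAT DP/AD, INFO MQ/REP/GENE/EFF/REGFLAG) for
interoperability with standard toolchains.

Float columns are written with ``repr`` so files round-trip losslessly.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import pandas as pd

from .records import DepthProfile, PatientCase, SampleRecord, VariantObservation
from .synthetic_cohort import Clone, CloneMutation, CloneTree, TruthModel

VARIANT_COLUMNS = [
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "effect",
    "depth",
    "alt_reads",
    "mean_mapq_alt",
    "mean_end_distance_alt",
    "region_flag",
]

MANIFEST_COLUMNS = [
    "patient_id",
    "sample_id",
    "compartment",
    "assay",
    "timepoint_days",
    "treatment_context",
]


def write_variants_tsv(sample: SampleRecord, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(VARIANT_COLUMNS)
        for v in sample.variants:
            w.writerow(
                [
                    sample.sample_id,
                    v.chrom,
                    v.pos,
                    v.ref,
                    v.alt,
                    v.gene,
                    v.effect,
                    v.depth,
                    v.alt_reads,
                    repr(v.mean_mapq_alt),
                    repr(v.mean_end_distance_alt),
                    v.region_flag,
                ]
            )


def read_variants_tsv(path) -> tuple[Optional[str], list[VariantObservation]]:
    """Read a variant TSV; returns (sample_id, observations)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"variant TSV missing columns: {sorted(missing)}")
    obs = [
        VariantObservation(
            chrom=row.chrom,
            pos=int(row.pos),
            ref=row.ref,
            alt=row.alt,
            gene=row.gene,
            effect=row.effect,
            depth=int(row.depth),
            alt_reads=int(row.alt_reads),
            mean_mapq_alt=float(row.mean_mapq_alt),
            mean_end_distance_alt=float(row.mean_end_distance_alt),
            region_flag=row.region_flag,
        )
        for row in df.itertuples(index=False)
    ]
    sample_id = str(df["sample_id"].iloc[0]) if len(df) else None
    return sample_id, obs


def write_depth_tsv(profile: DepthProfile, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["depth_bin", "n_sites"])
        for d, n in zip(profile.depth_bins, profile.n_sites):
            w.writerow([d, n])


def read_depth_tsv(path) -> DepthProfile:
    df = pd.read_csv(path, sep="\t")
    return DepthProfile(
        tuple(int(d) for d in df["depth_bin"]), tuple(int(n) for n in df["n_sites"])
    )


def write_coverage_tsv(sample: SampleRecord, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", "gene", "coverage"])
        for gene in sorted(sample.gene_coverage):
            w.writerow([sample.sample_id, gene, repr(sample.gene_coverage[gene])])


def read_coverage_tsv(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    return {str(r.gene): float(r.coverage) for r in df.itertuples(index=False)}


def write_manifest(patients: list[PatientCase], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(MANIFEST_COLUMNS)
        for p in patients:
            for s in p.samples:
                w.writerow(
                    [
                        p.patient_id,
                        s.sample_id,
                        s.compartment,
                        s.assay,
                        s.timepoint_days,
                        s.treatment_context,
                    ]
                )


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _truth_to_dict(truth: TruthModel) -> dict:
    return {
        "patient_id": truth.patient_id,
        "tumor_fraction": truth.tumor_fraction,
        "clone_tree": {
            "clones": [
                {"clone_id": c.clone_id, "parent_id": c.parent_id, "ccf": c.ccf}
                for c in truth.clone_tree.clones
            ],
            "mutations": [asdict(m) for m in truth.clone_tree.mutations],
        },
        "true_vaf": truth.true_vaf,
        "labels": truth.labels,
        "copy_states": truth.copy_states,
    }


def _truth_from_dict(d: dict) -> TruthModel:
    tree = CloneTree(
        clones=[
            Clone(c["clone_id"], c["parent_id"], dict(c["ccf"]))
            for c in d["clone_tree"]["clones"]
        ],
        mutations=[CloneMutation(**m) for m in d["clone_tree"]["mutations"]],
    )
    return TruthModel(
        patient_id=d["patient_id"],
        tumor_fraction=dict(d["tumor_fraction"]),
        clone_tree=tree,
        true_vaf={k: dict(v) for k, v in d["true_vaf"].items()},
        labels=dict(d["labels"]),
        copy_states={k: int(v) for k, v in d["copy_states"].items()},
    )


def write_truth_json(truths: dict[str, TruthModel], path) -> None:
    payload = {pid: _truth_to_dict(t) for pid, t in sorted(truths.items())}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth_json(path) -> dict[str, TruthModel]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return {pid: _truth_from_dict(d) for pid, d in payload.items()}


def write_cohort(
    patients: list[PatientCase],
    truths: Optional[dict[str, TruthModel]],
    out_dir,
    vcf: bool = False,
) -> Path:
    """Write a cohort directory; returns the manifest path.

    Layout: ``<sample_id>.variants.tsv``, ``<sample_id>.depth.tsv`` and
    ``<sample_id>.coverage.tsv`` per sample, plus ``manifest.tsv`` and
    (when truth is given) ``truth.json``.
    """
    if not patients:
        raise ValueError("empty cohort")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for p in patients:
        for s in p.samples:
            write_variants_tsv(s, out / f"{s.sample_id}.variants.tsv")
            if s.depth_profile is not None:
                write_depth_tsv(s.depth_profile, out / f"{s.sample_id}.depth.tsv")
            if s.gene_coverage:
                write_coverage_tsv(s, out / f"{s.sample_id}.coverage.tsv")
            if vcf:
                write_vcf(s, out / f"{s.sample_id}.vcf")
    manifest_path = out / "manifest.tsv"
    write_manifest(patients, manifest_path)
    if truths is not None:
        write_truth_json(truths, out / "truth.json")
    return manifest_path


def read_cohort(cohort_dir) -> tuple[list[PatientCase], Optional[dict[str, TruthModel]]]:
    """Re-assemble PatientCase objects from a cohort directory."""
    cohort_dir = Path(cohort_dir)
    manifest = read_manifest(cohort_dir / "manifest.tsv")
    patients: dict[str, PatientCase] = {}
    for row in manifest.itertuples(index=False):
        case = patients.setdefault(str(row.patient_id), PatientCase(str(row.patient_id)))
        sample = SampleRecord(
            patient_id=str(row.patient_id),
            sample_id=str(row.sample_id),
            compartment=str(row.compartment),
            assay=str(row.assay),
            timepoint_days=int(row.timepoint_days),
            treatment_context=str(row.treatment_context),
        )
        _, sample.variants = read_variants_tsv(cohort_dir / f"{row.sample_id}.variants.tsv")
        depth_path = cohort_dir / f"{row.sample_id}.depth.tsv"
        if depth_path.exists():
            sample.depth_profile = read_depth_tsv(depth_path)
        cov_path = cohort_dir / f"{row.sample_id}.coverage.tsv"
        if cov_path.exists():
            sample.gene_coverage = read_coverage_tsv(cov_path)
        case.samples.append(sample)
    truth_path = cohort_dir / "truth.json"
    truths = read_truth_json(truth_path) if truth_path.exists() else None
    return list(patients.values()), truths


# ---------------------------------------------------------------------------
# VCF 4.2 output (optional mirror of the TSV dialect)
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=ctdnaflow
##INFO=<ID=MQ,Number=1,Type=Float,Description="Mean mapping quality of mutation-supporting reads">
##INFO=<ID=REP,Number=1,Type=Float,Description="Read-end proximity: mean distance of the mutant allele from the nearest read end">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=EFF,Number=1,Type=String,Description="Coding effect class">
##INFO=<ID=REGFLAG,Number=1,Type=String,Description="Region flag for tumor-fraction eligibility">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
"""


def write_vcf(sample: SampleRecord, path) -> None:
    contigs = sorted({v.chrom for v in sample.variants})
    rows = sorted(sample.variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_VCF_HEADER)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + sample.sample_id
            + "\n"
        )
        for v in rows:
            info = (
                f"MQ={v.mean_mapq_alt};REP={v.mean_end_distance_alt};"
                f"GENE={v.gene};EFF={v.effect};REGFLAG={v.region_flag}"
            )
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t{info}\t"
                f"DP:AD\t{v.depth}:{v.depth - v.alt_reads},{v.alt_reads}\n"
            )
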