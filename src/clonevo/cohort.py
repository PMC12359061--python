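"""Containers for a paired baseline/recurrence cohort and its on-disk layout.

A cohort is four long tables:

``variants``
    MAF-style calls: patient, sample, timepoint, chrom, pos, ref, alt,
    t_ref_count, t_alt_count, vaf, variant_classification, gene_symbol.
    Coordinates are 1-based inclusive.
``segments``
    Allele-specific copy number per sample: sample, chrom, start, end,
    major_cn, minor_cn, normal_cn.
``meta``
    One row per sample: sample, patient, timepoint, purity, ploidy,
    immune_group.
``truth``
    Present only for simulated cohorts: per-mutation generative truth
    (clone membership, per-timepoint CCF, artefact/neoantigen/evasion
    labels, fabricated binding affinity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

VARIANT_COLUMNS = [
    "patient",
    "sample",
    "timepoint",
    "chrom",
    "pos",
    "ref",
    "alt",
    "t_ref_count",
    "t_alt_count",
    "vaf",
    "variant_classification",
    "gene_symbol",
]

SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "major_cn", "minor_cn", "normal_cn"]

META_COLUMNS = ["sample", "patient", "timepoint", "purity", "ploidy", "immune_group"]

TRUTH_COLUMNS = [
    "patient",
    "mutation_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene_symbol",
    "variant_classification",
    "clone_id",
    "ccf_baseline",
    "ccf_recurrence",
    "is_artifact",
    "artifact_sample",
    "is_neoantigen",
    "is_evasion_lof",
    "affinity_nm",
    "stringent_pass",
]


@dataclass
class PatientPair:
    """Baseline and recurrence call tables for one patient."""

    patient: str
    baseline: pd.DataFrame
    recurrence: pd.DataFrame
    segments: pd.DataFrame
    meta: pd.DataFrame
    truth: pd.DataFrame | None = None

    def sample_id(self, timepoint: str) -> str:
        rows = self.meta.loc[self.meta["timepoint"] == timepoint, "sample"]
        if rows.empty:
            raise KeyError(f"patient {self.patient} has no {timepoint} sample")
        return rows.iloc[0]


@dataclass
class Cohort:
    """A set of paired tumour profiles, optionally with simulation truth."""

    variants: pd.DataFrame
    segments: pd.DataFrame
    meta: pd.DataFrame
    truth: pd.DataFrame | None = None
    methylation: pd.DataFrame | None = None  # probes x samples beta matrix
    probe_annotation: pd.DataFrame | None = None

    def __post_init__(self):
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variants table missing columns: {missing}")

    @property
    def patients(self) -> list[str]:
        return sorted(self.meta["patient"].unique())

    @property
    def samples(self) -> list[str]:
        return sorted(self.meta["sample"].unique())

    def patient_pair(self, patient: str) -> PatientPair:
        meta = self.meta[self.meta["patient"] == patient]
        if meta.empty:
            raise KeyError(f"unknown patient {patient!r}")
        v = self.variants[self.variants["patient"] == patient]
        seg = self.segments[self.segments["sample"].isin(meta["sample"])]
        truth = None
        if self.truth is not None:
            truth = self.truth[self.truth["patient"] == patient]
        return PatientPair(
            patient=patient,
            baseline=v[v["timepoint"] == "baseline"].reset_index(drop=True),
            recurrence=v[v["timepoint"] == "recurrence"].reset_index(drop=True),
            segments=seg.reset_index(drop=True),
            meta=meta.reset_index(drop=True),
            truth=truth.reset_index(drop=True) if truth is not None else None,
        )

    def iter_pairs(self):
        for p in self.patients:
            yield self.patient_pair(p)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.variants.to_csv(outdir / "variants.maf.tsv", sep="\t", index=False)
        self.segments.to_csv(outdir / "segments.tsv", sep="\t", index=False)
        self.meta.to_csv(outdir / "sample_meta.tsv", sep="\t", index=False)
        if self.truth is not None:
            self.truth.to_csv(outdir / "truth_labels.tsv", sep="\t", index=False)
        if self.methylation is not None:
            self.methylation.to_csv(outdir / "beta_matrix.tsv", sep="\t")
        if self.probe_annotation is not None:
            self.probe_annotation.to_csv(outdir / "probe_annotation.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, indir: str | Path) -> "Cohort":
        indir = Path(indir)
        kwargs = {}
        truth_path = indir / "truth_labels.tsv"
        if truth_path.exists():
            kwargs["truth"] = pd.read_csv(truth_path, sep="\t", dtype={"chrom": str})
        beta_path = indir / "beta_matrix.tsv"
        if beta_path.exists():
            kwargs["methylation"] = pd.read_csv(beta_path, sep="\t", index_col=0)
        ann_path = indir / "probe_annotation.tsv"
        if ann_path.exists():
            kwargs["probe_annotation"] = pd.read_csv(ann_path, sep="\t")
        return cls(
            variants=pd.read_csv(indir / "variants.maf.tsv", sep="\t", dtype={"chrom": str}),
            segments=pd.read_csv(indir / "segments.tsv", sep="\t", dtype={"chrom": str}),
            meta=pd.read_csv(indir / "sample_meta.tsv", sep="\t"),
            **kwargs,
        )
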