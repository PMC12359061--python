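"""Readers for the tabular inputs: MAF-style TSV, VCF, segments and metadata.

The MAF-style layout is a plain TSV with 1-based inclusive coordinates and
the columns listed in :data:`clonevo.cohort.VARIANT_COLUMNS`; VAF is always
recomputed from the read counts when both are present. VCF input (4.2, via
cyvcf2) is split into per-allele calls with VAF taken from the tumour
sample's AD field.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "read_variant_table",
    "read_segments",
    "read_sample_meta",
    "read_covariates",
    "read_neoantigen_annotations",
]

_REQUIRED_MAF_COLUMNS = [
    "patient",
    "sample",
    "timepoint",
    "chrom",
    "pos",
    "ref",
    "alt",
    "t_ref_count",
    "t_alt_count",
]


def read_variant_table(path: str | Path, format: str = "maf_tsv") -> pd.DataFrame:
    """Read somatic calls from a MAF-style TSV or a VCF.

    Malformed rows (non-numeric counts, non-positive positions) are dropped
    and reported with their 1-based file line numbers. Missing required
    columns raise a :class:`ValueError` naming the column.
    """
    if format == "maf_tsv":
        return _read_maf_tsv(Path(path))
    if format == "vcf":
        return _read_vcf(Path(path))
    raise ValueError(f"unknown variant table format {format!r}")


def _read_maf_tsv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if df.empty:
        logger.warning("variant table %s is empty", path)
        cols = _REQUIRED_MAF_COLUMNS + ["vaf", "variant_classification", "gene_symbol"]
        return pd.DataFrame(columns=cols)
    for col in _REQUIRED_MAF_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"variant table {path} is missing required column {col!r}")

    pos = pd.to_numeric(df["pos"], errors="coerce")
    ref_n = pd.to_numeric(df["t_ref_count"], errors="coerce")
    alt_n = pd.to_numeric(df["t_alt_count"], errors="coerce")
    bad = pos.isna() | (pos < 1) | ref_n.isna() | alt_n.isna() | (ref_n < 0) | (alt_n < 0)
    if bad.any():
        # +2: 1-based line numbers counting the header line
        lines = (df.index[bad] + 2).tolist()
        logger.warning("dropping %d malformed rows in %s (lines %s)", bad.sum(), path, lines)
        df = df.loc[~bad].copy()
        pos, ref_n, alt_n = pos[~bad], ref_n[~bad], alt_n[~bad]
    df["pos"] = pos.astype(int)
    df["t_ref_count"] = ref_n.astype(int)
    df["t_alt_count"] = alt_n.astype(int)
    depth = df["t_ref_count"] + df["t_alt_count"]
    with np.errstate(invalid="ignore"):
        df["vaf"] = np.where(depth > 0, df["t_alt_count"] / depth, np.nan)
    if "variant_classification" not in df.columns:
        df["variant_classification"] = "other"
    if "gene_symbol" not in df.columns:
        df["gene_symbol"] = ""
    return df.reset_index(drop=True)


def _read_vcf(path: Path) -> pd.DataFrame:
    """VCF reader: one output row per alt allele, VAF from the AD field."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    tumour_idx = 0 if vcf.samples else None
    sample_name = vcf.samples[0] if vcf.samples else str(path)
    rows = []
    for rec in vcf:
        ad = rec.format("AD")
        depth_alleles = ad[tumour_idx] if ad is not None else None
        for ai, alt in enumerate(rec.ALT):
            if depth_alleles is not None and len(depth_alleles) > ai + 1:
                ref_count = int(depth_alleles[0])
                alt_count = int(depth_alleles[ai + 1])
            else:
                ref_count, alt_count = 0, 0
            rows.append(
                {
                    "patient": sample_name,
                    "sample": sample_name,
                    "timepoint": "baseline",
                    "chrom": rec.CHROM,
                    "pos": rec.POS,
                    "ref": rec.REF,
                    "alt": alt,
                    "t_ref_count": ref_count,
                    "t_alt_count": alt_count,
                    "vaf": alt_count / (ref_count + alt_count)
                    if ref_count + alt_count > 0
                    else np.nan,
                    "variant_classification": "other",
                    "gene_symbol": "",
                }
            )
    if not rows:
        logger.warning("VCF %s contains no records", path)
    return pd.DataFrame(
        rows,
        columns=_REQUIRED_MAF_COLUMNS + ["vaf", "variant_classification", "gene_symbol"],
    )


def read_segments(path: str | Path) -> pd.DataFrame:
    """Read a Sequenza-style allele-specific copy number segment table.

    Accepts either the package's column names (chrom/start/end/major_cn/
    minor_cn) or Sequenza's (chromosome/start.pos/end.pos/A/B).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "chromosome": str})
    rename = {
        "chromosome": "chrom",
        "start.pos": "start",
        "end.pos": "end",
        "A": "major_cn",
        "B": "minor_cn",
    }
    df = df.rename(columns={k: v for k, v in rename.items() if k in df.columns})
    for col in ("chrom", "start", "end", "major_cn", "minor_cn"):
        if col not in df.columns:
            raise ValueError(f"segment table {path} is missing column {col!r}")
    if "normal_cn" not in df.columns:
        df["normal_cn"] = 2
    return df


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("sample", "patient", "timepoint", "purity"):
        if col not in df.columns:
            raise ValueError(f"sample meta table {path} is missing column {col!r}")
    bad = df.loc[(df["purity"] <= 0) | (df["purity"] > 1)]
    if len(bad):
        raise ValueError(f"purity must lie in (0, 1]; offending samples: {bad['sample'].tolist()}")
    return df


def read_neoantigen_annotations(path: str | Path) -> pd.DataFrame:
    """Per-mutation neoantigen annotations: key columns plus ``affinity_nm``
    (nM, optional per row) and/or a boolean ``stringent_pass`` call."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("chrom", "pos", "ref", "alt"):
        if col not in df.columns:
            raise ValueError(f"annotation table {path} is missing column {col!r}")
    if "affinity_nm" not in df.columns and "stringent_pass" not in df.columns:
        raise ValueError(
            f"annotation table {path} needs 'affinity_nm' and/or 'stringent_pass'"
        )
    if "stringent_pass" in df.columns:
        df["stringent_pass"] = df["stringent_pass"].astype(bool)
    return df


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Sample-by-column covariate table (mutational burden, CD8, CD8/Treg...)."""
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns:
        raise ValueError(f"covariate table {path} is missing column 'sample'")
    return df
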