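"""Promoter methylation summaries and neoantigen-stratified shift tests.

Illumina EPIC probes annotated to the upstream regulatory region of a gene
(region classes TSS200, TSS1500 and 1stExon) are summarised per gene per
sample by both the mean and the median beta value; probes in any other
region class never enter the summary. Per-gene shifts between timepoints
are then compared between neoantigen-bearing genes and the rest with a
rank-sum test, stratified by immune group.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .stats import rank_sum_test

logger = logging.getLogger(__name__)

__all__ = ["PROMOTER_CLASSES", "summarise_promoters", "compare_shifts"]

PROMOTER_CLASSES = ("TSS200", "TSS1500", "1stExon")


def summarise_promoters(beta_matrix: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Per-gene promoter beta summaries (mean and median) per sample.

    *beta_matrix* is probes x samples with values in [0, 1]; *annotation*
    links ``probe_id`` to ``gene_symbol`` with a ``region_class``. Probes
    absent from the annotation are ignored (count reported); genes with no
    qualifying promoter probe are omitted with a log entry. A probe
    annotated to several genes contributes to each.
    """
    vals = beta_matrix.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size and ((finite < 0).any() or (finite > 1).any()):
        raise ValueError("beta values must lie in [0, 1]")
    n_unannotated = (~beta_matrix.index.isin(annotation["probe_id"])).sum()
    if n_unannotated:
        logger.info("%d probes in the matrix have no annotation and are ignored", n_unannotated)

    promoter = annotation[annotation["region_class"].isin(PROMOTER_CLASSES)]
    skipped = set(annotation["gene_symbol"]) - set(promoter["gene_symbol"])
    if skipped:
        logger.info("%d genes have no promoter-class probes and are omitted", len(skipped))

    long = (
        beta_matrix.reset_index()
        .melt(id_vars=beta_matrix.index.name or "index", var_name="sample", value_name="beta")
        .rename(columns={beta_matrix.index.name or "index": "probe_id"})
    )
    merged = promoter.merge(long, on="probe_id", how="inner")
    if merged.empty:
        return pd.DataFrame(
            columns=["sample", "gene_symbol", "mean_beta", "median_beta", "n_probes"]
        )
    out = (
        merged.groupby(["sample", "gene_symbol"])["beta"]
        .agg(mean_beta="mean", median_beta="median", n_probes="size")
        .reset_index()
    )
    return out


def compare_shifts(
    summaries: pd.DataFrame,
    meta: pd.DataFrame,
    neoantigen_genes: set | dict,
    statistic: str = "mean_beta",
) -> dict:
    """Compare promoter methylation shifts of neoantigen genes vs the rest.

    *summaries* comes from :func:`summarise_promoters`; *meta* maps samples
    to ``patient``, ``timepoint`` and ``immune_group``. *neoantigen_genes*
    is either a set (cohort-wide) or a dict patient -> set (a gene counts
    as neoantigen-bearing for a patient if it carries any stringent-pass
    neoantigen there). The per-gene shift is recurrence minus baseline of
    the chosen summary statistic; unpaired gene/patient combinations are
    skipped with a count. Rank-sum results are reported per immune group
    and overall.
    """
    m = meta.set_index("sample")
    df = summaries.copy()
    df["patient"] = df["sample"].map(m["patient"])
    df["timepoint"] = df["sample"].map(m["timepoint"])
    df["immune_group"] = df["sample"].map(m["immune_group"])

    wide = df.pivot_table(
        index=["patient", "gene_symbol", "immune_group"],
        columns="timepoint",
        values=statistic,
        aggfunc="first",
    ).reset_index()
    n_unpaired = int(wide["baseline"].isna().sum() + wide["recurrence"].isna().sum()) \
        if {"baseline", "recurrence"} <= set(wide.columns) else len(wide)
    for tp in ("baseline", "recurrence"):
        if tp not in wide.columns:
            raise ValueError(f"no {tp} samples present; paired timepoints required")
    wide = wide.dropna(subset=["baseline", "recurrence"])
    if n_unpaired:
        logger.info("skipped %d unpaired gene/patient combinations", n_unpaired)
    wide["shift"] = wide["recurrence"] - wide["baseline"]

    if isinstance(neoantigen_genes, dict):
        wide["is_neo_gene"] = [
            g in neoantigen_genes.get(p, set())
            for p, g in zip(wide["patient"], wide["gene_symbol"])
        ]
    else:
        wide["is_neo_gene"] = wide["gene_symbol"].isin(neoantigen_genes)

    def _test(sub):
        neo = sub.loc[sub["is_neo_gene"], "shift"]
        other = sub.loc[~sub["is_neo_gene"], "shift"]
        if neo.empty or other.empty:
            return None
        res = rank_sum_test(neo, other)
        res["n_neo_genes"] = int(len(neo))
        res["n_other_genes"] = int(len(other))
        return res

    results = {"overall": _test(wide), "by_group": {}, "shifts": wide}
    for group, sub in wide.groupby("immune_group"):
        results["by_group"][group] = _test(sub)
    return results
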