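"""Immune-evasion loss-of-function flags and their group/covariate tests.

A tumour is flagged as carrying an immune-evasion LoF if any of its calls
is a loss-of-function class (nonsense, frameshift, other indel, nonstop) in
a catalogue gene. The packaged catalogue combines antigen-presentation
machinery (HLA class II genes, CIITA, B2M, TAP1) with genes whose
loss-of-function confers resistance to CD8 T-cell killing in CRISPR
screens (IRF2, IRF8, JAK2, PRKCD); it is a small editable seed list, not a
frozen copy of any pathway database release.

Flag proportions between patient groups are compared with Fisher's exact
test; continuous immune covariates (mutational burden, CD8 level, CD8/Treg
ratio) between flagged and unflagged tumours with Wilcoxon's rank-sum.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import pandas as pd

from .stats import fisher_exact_2x2, rank_sum_test
from .types import EvasionCatalog, LOF_CLASSES

logger = logging.getLogger(__name__)

__all__ = [
    "load_catalog",
    "is_lof",
    "flag_samples",
    "fisher_group_comparison",
    "covariate_association",
]

_KNOWN_CLASSES = {
    "missense", "nonsense", "frameshift_ins", "frameshift_del",
    "in_frame_indel", "nonstop", "silent", "splice", "other",
}


def load_catalog(path: str | Path | None = None) -> EvasionCatalog:
    """Load the evasion-gene catalogue (packaged seed list by default)."""
    if path is None:
        source = resources.files("clonevo.data") / "evasion_catalog.tsv"
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    for col in ("gene_symbol", "provenance"):
        if col not in df.columns:
            raise ValueError(f"catalogue is missing column {col!r}")
    return EvasionCatalog(provenance=dict(zip(df["gene_symbol"], df["provenance"])))


def is_lof(variant) -> bool:
    """True for loss-of-function classes; unknown classes are False with a warning."""
    cls = variant if isinstance(variant, str) else variant.variant_classification
    if cls not in _KNOWN_CLASSES:
        logger.warning("unknown variant classification %r treated as non-LoF", cls)
        return False
    return cls in LOF_CLASSES


def flag_samples(
    variants: pd.DataFrame,
    catalog: EvasionCatalog,
    by: str = "sample",
) -> pd.DataFrame:
    """Flag each sample (or patient, ``by='patient'``) with any catalogue LoF call.

    Returns one row per unit with ``has_evasion_lof`` and the supporting
    variants as a list of ``chrom:pos:ref>alt gene`` strings.
    """
    if by not in ("sample", "patient"):
        raise ValueError("by must be 'sample' or 'patient'")
    lof = variants["variant_classification"].isin(LOF_CLASSES)
    in_catalog = variants["gene_symbol"].astype(str).str.upper().isin(catalog.gene_symbols)
    support = variants.loc[lof & in_catalog]
    rows = []
    for unit in sorted(variants[by].unique()):
        sub = support[support[by] == unit]
        rows.append(
            {
                by: unit,
                "has_evasion_lof": bool(len(sub)),
                "supporting_variants": [
                    f"{r.chrom}:{r.pos}:{r.ref}>{r.alt} {r.gene_symbol}"
                    for r in sub.itertuples()
                ],
            }
        )
    return pd.DataFrame(rows)


def fisher_group_comparison(flags: pd.DataFrame, groups: pd.Series | dict) -> dict:
    """Fisher's exact test of evasion-LoF proportions between two groups.

    *flags* is the output of :func:`flag_samples`; *groups* maps each unit
    to one of exactly two group labels.
    """
    unit_col = flags.columns[0]
    g = flags[unit_col].map(dict(groups) if not isinstance(groups, pd.Series) else groups)
    levels = sorted(g.dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    table = []
    for level in levels:
        sub = flags.loc[g == level, "has_evasion_lof"]
        if sub.empty:
            raise ValueError(f"group {level!r} is empty")
        table.append([int(sub.sum()), int((~sub).sum())])
    res = fisher_exact_2x2(table)
    res["table"] = table
    res["groups"] = [str(l) for l in levels]
    return res


def covariate_association(flags: pd.DataFrame, covariate_values: pd.Series | dict) -> dict:
    """Rank-sum comparison of a covariate between flagged and unflagged units."""
    unit_col = flags.columns[0]
    cov = flags[unit_col].map(
        dict(covariate_values) if not isinstance(covariate_values, pd.Series) else covariate_values
    )
    flagged = cov[flags["has_evasion_lof"] & cov.notna()]
    unflagged = cov[~flags["has_evasion_lof"] & cov.notna()]
    if flagged.empty or unflagged.empty:
        raise ValueError("covariate must be observed in both flagged and unflagged units")
    res = rank_sum_test(flagged, unflagged)
    res["n_flagged"] = int(len(flagged))
    res["n_unflagged"] = int(len(unflagged))
    return res
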