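"""Neoantigen binding tiers and delta-CCF immunoediting statistics.

Candidate neoantigens are tiered by predicted MHC class I binding affinity
(nM; lower binds tighter): affinity <= 100 nM is a strong binder, <= 500 nM
weak, > 500 nM a non-binder; records without an affinity are unknown. A
stringent consortium-style boolean call can be supplied alongside.

The immunoediting statistic compares, between neoantigens and control
mutations, the per-mutation change in cancer cell fraction between the
recurrence and baseline samples (delta-CCF = CCF_recurrence -
CCF_baseline, with mutations absent at a timepoint contributing CCF 0
there). Under immune selection against neoantigens the neoantigen
delta-CCF distribution shifts downwards.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cohort import PatientPair
from .stats import fisher_combined_p, rank_sum_test

logger = logging.getLogger(__name__)

__all__ = [
    "classify_binders",
    "compute_delta_ccf",
    "compare_dynamics",
    "immunoediting_detection",
]

STRONG_BINDER_NM = 100.0
WEAK_BINDER_NM = 500.0


def classify_binders(
    annotations: pd.DataFrame,
    strong_nm: float = STRONG_BINDER_NM,
    weak_nm: float = WEAK_BINDER_NM,
) -> pd.DataFrame:
    """Add a ``tier`` column from binding affinity (inclusive thresholds).

    affinity <= strong_nm -> ``strong``; <= weak_nm -> ``weak``; above ->
    ``non_binder``; missing affinity -> ``unknown``. Records with
    non-positive affinity are rejected (dropped with a logged message).
    """
    out = annotations.copy()
    aff = pd.to_numeric(out["affinity_nm"], errors="coerce")
    nonpos = aff.notna() & (aff <= 0)
    if nonpos.any():
        logger.error(
            "rejecting %d records with non-positive binding affinity", int(nonpos.sum())
        )
        out = out.loc[~nonpos].copy()
        aff = aff[~nonpos]
    tier = np.select(
        [aff.isna(), aff <= strong_nm, aff <= weak_nm],
        ["unknown", "strong", "weak"],
        default="non_binder",
    )
    out["tier"] = tier
    return out


def compute_delta_ccf(
    pair: PatientPair,
    ccf_baseline: pd.DataFrame,
    ccf_recurrence: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
    mode: str = "union",
) -> pd.DataFrame:
    """Per-mutation delta-CCF between recurrence and baseline.

    *ccf_baseline* / *ccf_recurrence* are CCF-assigned call tables (with
    ``chrom, pos, ref, alt, ccf``) for the two timepoints. In ``union``
    mode (default — private mutations dominate paired FFPE cohorts) a
    mutation absent at a timepoint contributes CCF 0 there; ``intersection``
    mode keeps only mutations observed at both.

    Neoantigen status comes from *annotations* (keyed on chrom/pos/ref/alt
    with ``stringent_pass`` and optionally ``affinity_nm``) or, for
    simulated pairs, from the pair's truth labels.
    """
    if mode not in ("union", "intersection"):
        raise ValueError(f"mode must be 'union' or 'intersection', got {mode!r}")
    key_cols = ["chrom", "pos", "ref", "alt"]

    def _keyed(df):
        k = df[key_cols + ["ccf"]].copy()
        k["chrom"] = k["chrom"].astype(str)
        return k.drop_duplicates(key_cols)

    merged = _keyed(ccf_baseline).merge(
        _keyed(ccf_recurrence), on=key_cols, how="outer" if mode == "union" else "inner",
        suffixes=("_baseline", "_recurrence"),
    )
    for col in ("ccf_baseline", "ccf_recurrence"):
        merged[col] = pd.to_numeric(merged[col], errors="coerce").fillna(0.0)
    merged["delta"] = merged["ccf_recurrence"] - merged["ccf_baseline"]

    if annotations is None and pair.truth is not None:
        annotations = pair.truth.loc[
            ~pair.truth["is_artifact"],
            key_cols + ["stringent_pass", "affinity_nm"],
        ]
    if annotations is not None:
        ann = annotations.copy()
        ann["chrom"] = ann["chrom"].astype(str)
        merged = merged.merge(ann.drop_duplicates(key_cols), on=key_cols, how="left")
        neo = merged.get("stringent_pass")
        merged["is_neoantigen"] = (
            neo.astype("boolean").fillna(False).astype(bool) if neo is not None else False
        )
    else:
        merged["is_neoantigen"] = False
    merged["patient"] = pair.patient
    return merged


def compare_dynamics(
    records: pd.DataFrame,
    grouping: str = "stringent_pass",
    pooling: str = "centred",
) -> dict:
    """Test whether neoantigen delta-CCFs differ from control mutations.

    *records* is a concatenation of :func:`compute_delta_ccf` outputs with
    ``patient``, ``delta`` and a boolean group column (*grouping*, default
    ``stringent_pass``; ``tier`` groups strong+weak binders against
    non-binders). Per-patient two-sided rank-sum tests are reported, plus a
    pooled test: by default patient-centred deltas pooled into one rank-sum
    comparison (``pooling='centred'``); ``pooling='fisher'`` combines the
    per-patient p-values instead.

    The pooled result carries both the two-sided p and the one-sided
    depletion p (neoantigen deltas below control).
    """
    if grouping == "tier":
        if "tier" not in records.columns:
            raise ValueError("grouping='tier' requires a tier column (run classify_binders)")
        is_neo = records["tier"].isin(["strong", "weak"])
    else:
        is_neo = records[grouping].astype(bool)
    records = records.assign(_neo=is_neo.to_numpy())

    per_patient = []
    for patient, sub in records.groupby("patient"):
        neo = sub.loc[sub["_neo"], "delta"]
        ctrl = sub.loc[~sub["_neo"], "delta"]
        if neo.empty or ctrl.empty:
            logger.warning(
                "patient %s skipped: empty %s group",
                patient, "neoantigen" if neo.empty else "control",
            )
            continue
        res = rank_sum_test(neo, ctrl)
        res["patient"] = patient
        res["n_neoantigen"] = int(len(neo))
        res["n_control"] = int(len(ctrl))
        per_patient.append(res)
    if not per_patient:
        raise ValueError("no patient had both neoantigen and control mutations")

    if pooling == "centred":
        centred = records.copy()
        centred["delta"] = centred["delta"] - centred.groupby("patient")["delta"].transform("mean")
        neo = centred.loc[centred["_neo"], "delta"]
        ctrl = centred.loc[~centred["_neo"], "delta"]
        pooled = rank_sum_test(neo, ctrl)
        pooled["p_depletion"] = rank_sum_test(neo, ctrl, alternative="less")["p_value"]
    elif pooling == "fisher":
        pooled = {"p_value": fisher_combined_p([r["p_value"] for r in per_patient])}
        pooled["p_depletion"] = fisher_combined_p(
            [
                rank_sum_test(
                    records.loc[(records["patient"] == r["patient"]) & records["_neo"], "delta"],
                    records.loc[(records["patient"] == r["patient"]) & ~records["_neo"], "delta"],
                    alternative="less",
                )["p_value"]
                for r in per_patient
            ]
        )
    else:
        raise ValueError(f"pooling must be 'centred' or 'fisher', got {pooling!r}")
    pooled["median_difference"] = float(
        records.loc[records["_neo"], "delta"].median()
        - records.loc[~records["_neo"], "delta"].median()
    )
    return {"per_patient": per_patient, "pooled": pooled}


def immunoediting_detection(cohort, vaf_threshold: float = 0.10,
                            mode: str = "union", pooling: str = "centred") -> dict:
    """Filter, assign CCFs and test a whole cohort for neoantigen depletion.

    Convenience wrapper running the FFPE filter, the CCF assignment and the
    pooled delta-CCF comparison in one call; returns the
    :func:`compare_dynamics` result dict. Neoantigen labels come from the
    cohort truth table (simulated cohorts) — for real cohorts, call the
    stages individually with external annotations.
    """
    from .ccf import assign_ccfs
    from .filtering import apply_artifact_filters

    if cohort.truth is None:
        raise ValueError("immunoediting_detection needs truth labels; see compute_delta_ccf")
    filtered, _ = apply_artifact_filters(cohort.variants, vaf_threshold=vaf_threshold)
    assigned = assign_ccfs(filtered, cohort.meta, cohort.segments)
    records = []
    for pair in cohort.iter_pairs():
        sub = assigned[assigned["patient"] == pair.patient]
        records.append(
            compute_delta_ccf(
                pair,
                sub[sub["timepoint"] == "baseline"],
                sub[sub["timepoint"] == "recurrence"],
                mode=mode,
            )
        )
    return compare_dynamics(pd.concat(records, ignore_index=True), pooling=pooling)
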