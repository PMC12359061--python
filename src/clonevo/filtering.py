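"""FFPE-aware variant filtering.

Formalin fixation deaminates cytosine, producing spurious C>T (G>A on the
opposite strand) calls that concentrate at low variant allele frequencies.
The dual filter applied here removes, in a fixed order:

1. signature filter — C>T/G>A substitutions that either carry an explicit
   artefact flag or (for flag-less inputs) fall below a signature
   sub-threshold VAF;
2. VAF filter — any remaining call with VAF strictly below the threshold
   (default 10%).

The boundary is strict: a call at exactly the threshold VAF is retained.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import FilterReport

logger = logging.getLogger(__name__)

__all__ = ["apply_artifact_filters", "retention_rate", "is_signature_substitution"]

DEFAULT_VAF_THRESHOLD = 0.10
DEFAULT_SIGNATURE_SUBTHRESHOLD = 0.05


def is_signature_substitution(ref, alt) -> np.ndarray:
    """C>T or G>A single-base substitutions (formalin deamination classes)."""
    ref = np.asarray(ref, dtype=object)
    alt = np.asarray(alt, dtype=object)
    return ((ref == "C") & (alt == "T")) | ((ref == "G") & (alt == "A"))


def apply_artifact_filters(
    variants: pd.DataFrame,
    vaf_threshold: float = DEFAULT_VAF_THRESHOLD,
    signature_filter: bool = True,
    signature_subthreshold: float = DEFAULT_SIGNATURE_SUBTHRESHOLD,
    artifact_flag_column: str | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the signature filter then the strict-below VAF filter.

    Parameters
    ----------
    variants
        Call table with at least ``ref``, ``alt`` and ``vaf`` columns.
    vaf_threshold
        Calls with ``vaf < vaf_threshold`` are removed (strictly below).
    signature_filter
        When on, C>T/G>A calls flagged as artefacts — or, if
        *artifact_flag_column* is None, with ``vaf < signature_subthreshold``
        — are removed first and counted separately.
    artifact_flag_column
        Optional boolean column marking caller-flagged artefacts.

    Returns
    -------
    (retained, report)
        The retained calls (original row order) and a :class:`FilterReport`
        reconciling the counts.
    """
    if not 0.0 <= vaf_threshold <= 1.0:
        raise ValueError(f"vaf_threshold must lie in [0, 1], got {vaf_threshold}")
    n_input = len(variants)
    if n_input == 0:
        return variants.copy(), FilterReport(0, 0, 0, 0)

    vaf = variants["vaf"].to_numpy(dtype=float)
    removed_sig = np.zeros(n_input, dtype=bool)
    if signature_filter:
        sig = is_signature_substitution(variants["ref"], variants["alt"])
        if artifact_flag_column is not None:
            flagged = variants[artifact_flag_column].astype(bool).to_numpy()
        else:
            flagged = vaf < signature_subthreshold
        removed_sig = sig & flagged
    removed_vaf = ~removed_sig & (vaf < vaf_threshold)
    keep = ~(removed_sig | removed_vaf)

    report = FilterReport(
        n_input=n_input,
        n_removed_signature=int(removed_sig.sum()),
        n_removed_vaf=int(removed_vaf.sum()),
        n_retained=int(keep.sum()),
    )
    logger.info(
        "artifact filter: %d in, %d removed by signature, %d by VAF<%.3g, %d retained",
        report.n_input, report.n_removed_signature, report.n_removed_vaf,
        vaf_threshold, report.n_retained,
    )
    return variants.loc[keep].reset_index(drop=True), report


def retention_rate(report: FilterReport) -> float:
    """Fraction of input calls surviving both filters; undefined for empty input."""
    return report.retention_rate
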