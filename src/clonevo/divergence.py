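"""Private/public mutation classification and the unmatched-pair overlap null.

A mutation is identified by (chrom, pos, ref, alt) — gene annotation is
ignored. For a matched baseline/recurrence pair, a mutation is *public* if
it appears at both timepoints and *private* otherwise; percent public is
the Jaccard-style 100*|A∩B|/|A∪B|.

The unmatched null asks how much overlap unrelated tumours show by chance:
overlap_percent(A, B) = 100*|A∩B|/|A| (asymmetric, first-profile
denominator) is evaluated over all ordered pairs of cohort profiles —
N^2 pairs when self-pairs are included (360 profiles give 129,600 values),
N*(N-1) without. Matched overlaps are then compared against this null with
a two-sided rank-sum test.
"""

from __future__ import annotations

import logging
from typing import Iterable

import pandas as pd

from .cohort import PatientPair
from .stats import rank_sum_test
from .types import OverlapNull

logger = logging.getLogger(__name__)

__all__ = [
    "mutation_keys",
    "classify_private_public",
    "overlap_percent",
    "build_unmatched_null",
    "compare_matched_vs_null",
]


def mutation_keys(profile) -> set:
    """The set of (chrom, pos, ref, alt) keys for a call table (or pass a set through)."""
    if isinstance(profile, (set, frozenset)):
        return set(profile)
    return set(
        zip(
            profile["chrom"].astype(str),
            profile["pos"].astype(int),
            profile["ref"],
            profile["alt"],
        )
    )


def classify_private_public(pair: PatientPair):
    """Label each of a patient's mutations private or public across timepoints.

    Returns ``(labels, percent_public)`` where *labels* has one row per
    mutation in the union with columns ``chrom, pos, ref, alt, in_baseline,
    in_recurrence, label`` and percent public is 100*|A∩B|/|A∪B|.
    """
    a = mutation_keys(pair.baseline)
    b = mutation_keys(pair.recurrence)
    union = a | b
    if not union:
        raise ValueError(f"patient {pair.patient}: no mutations at either timepoint")
    rows = []
    for key in sorted(union):
        in_a, in_b = key in a, key in b
        rows.append(
            {
                "chrom": key[0],
                "pos": key[1],
                "ref": key[2],
                "alt": key[3],
                "in_baseline": in_a,
                "in_recurrence": in_b,
                "label": "public" if (in_a and in_b) else "private",
            }
        )
    labels = pd.DataFrame(rows)
    percent_public = 100.0 * len(a & b) / len(union)
    return labels, percent_public


def overlap_percent(profile_a, profile_b) -> float:
    """Asymmetric overlap: percent of the first profile's mutations found in the second."""
    a = mutation_keys(profile_a)
    b = mutation_keys(profile_b)
    if not a:
        raise ValueError("overlap percent undefined for an empty first profile")
    return 100.0 * len(a & b) / len(a)


def build_unmatched_null(profiles: Iterable, include_self_pairs: bool = True) -> OverlapNull:
    """Overlap distribution over all ordered pairs of unmatched profiles.

    With self-pairs included, N profiles give exactly N^2 values (each
    self-pair contributing 100); excluding them gives N*(N-1).
    """
    key_sets = [mutation_keys(p) for p in profiles]
    n = len(key_sets)
    if n == 0 or (n == 1 and not include_self_pairs):
        raise ValueError("need at least two profiles (or one with self-pairs) for a null")
    values = []
    for i, a in enumerate(key_sets):
        if not a:
            raise ValueError(f"profile {i} is empty; overlap undefined")
        na = len(a)
        for j, b in enumerate(key_sets):
            if i == j and not include_self_pairs:
                continue
            values.append(100.0 * len(a & b) / na)
    return OverlapNull(values=values, n_profiles=n, includes_self_pairs=include_self_pairs)


def build_cross_timepoint_null(baseline_profiles, recurrence_profiles) -> OverlapNull:
    """Unmatched null from cross-patient baseline-vs-recurrence pairs.

    For N patients, overlap_percent(baseline_i, recurrence_j) over all
    i != j gives N*(N-1) values — the natural unmatched control when both
    timepoints come from the same cohort.
    """
    base = [mutation_keys(p) for p in baseline_profiles]
    rec = [mutation_keys(p) for p in recurrence_profiles]
    if len(base) != len(rec):
        raise ValueError("need matched-length baseline and recurrence profile lists")
    values = []
    for i, a in enumerate(base):
        if not a:
            raise ValueError(f"baseline profile {i} is empty; overlap undefined")
        for j, b in enumerate(rec):
            if i == j:
                continue
            values.append(100.0 * len(a & b) / len(a))
    return OverlapNull(values=values, n_profiles=len(base), includes_self_pairs=False)


def compare_matched_vs_null(matched_overlaps, null: OverlapNull) -> dict:
    """Two-sided rank-sum test of matched overlaps against the unmatched null.

    The reported direction says whether the matched distribution sits above
    the null (the signature of genuinely related pairs).
    """
    res = rank_sum_test(matched_overlaps, null.values)
    res["matched_greater"] = res["direction"] == "greater"
    res["n_matched"] = len(list(matched_overlaps))
    res["n_null_pairs"] = null.n_pairs
    return res
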