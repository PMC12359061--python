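"""Cancer cell fraction estimation, clone clustering, and clonality scores.

The CCF of a mutation is the fraction of tumour cells carrying it. With
tumour purity ``p``, tumour total copy number ``CNt``, normal copy number
``CNn`` and mutation multiplicity ``m`` (mutant copies per carrying cell),
the expected VAF of a mutation at cancer cell fraction ``CCF`` is

    E[VAF] = m * p * CCF / (p * CNt + (1 - p) * CNn)

Multiplicity is chosen from {1..major_cn} as the value whose clonal
(CCF = 1) expected VAF is closest to the observed VAF, breaking ties toward
the smaller (more conservative) m; the CCF estimate then inverts the
formula and is capped at 1, with the uncapped value kept as a
purity/copy-number consistency diagnostic.

Clone clustering is a seeded EM binomial mixture over alt read counts with
component success probabilities induced by candidate clone CCFs, the
component count selected by BIC up to a hard cap (default 15 subclones).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .stats import rank_sum_test
from .types import CCFAssignment, CloneSet, CopyNumberSegment, SampleMeta, VariantCall

logger = logging.getLogger(__name__)

__all__ = [
    "expected_vaf",
    "compute_ccf",
    "assign_ccfs",
    "cluster_ccfs",
    "clonality_score",
    "clonality_score_by_clone",
    "delta_clonality",
]

MAX_CLONES = 15


def expected_vaf(ccf, purity, multiplicity, total_cn, normal_cn=2):
    """Expected VAF under the purity/copy-number read model."""
    denom = purity * np.asarray(total_cn, dtype=float) + (1.0 - purity) * np.asarray(
        normal_cn, dtype=float
    )
    return np.asarray(multiplicity, dtype=float) * purity * np.asarray(ccf, dtype=float) / denom


def compute_ccf(
    variant: VariantCall,
    meta: SampleMeta,
    segment: CopyNumberSegment | None,
) -> CCFAssignment:
    """Estimate multiplicity and CCF for a single mutation.

    A variant with no covering segment is treated as diploid
    (``CNt = normal_cn``, ``m = 1``); a homozygous-deletion segment
    (``major_cn = 0``) marks the call purity/CN-inconsistent and excludes it
    from clustering.
    """
    if segment is not None and not segment.contains(variant.chrom, variant.pos):
        raise ValueError(
            f"variant {variant.chrom}:{variant.pos} lies outside segment "
            f"{segment.chrom}:{segment.start}-{segment.end}"
        )
    if segment is None:
        cnn = 2
        cnt, major = cnn, 1
    else:
        cnn = segment.normal_cn
        cnt, major = segment.total_cn, segment.major_cn
    if major == 0:
        return CCFAssignment(
            key=variant.key, multiplicity=0, ccf=float("nan"),
            ccf_uncapped=float("nan"), inconsistent=True,
        )
    p = meta.purity
    denom = p * cnt + (1.0 - p) * cnn
    # choose m minimising |clonal expected VAF - observed VAF|; ties -> smaller m
    candidates = np.arange(1, major + 1)
    err = np.abs(candidates * p / denom - variant.vaf)
    m = int(candidates[np.argmin(err)])
    ccf_uncapped = variant.vaf * denom / (p * m)
    return CCFAssignment(
        key=variant.key,
        multiplicity=m,
        ccf=min(ccf_uncapped, 1.0),
        ccf_uncapped=ccf_uncapped,
    )


def _join_segments(variants: pd.DataFrame, segments: pd.DataFrame) -> pd.DataFrame:
    """Attach major/minor/normal CN by 1-based inclusive containment.

    Variants with no covering segment default to diploid (CNt = CNn, m = 1).
    """
    n = len(variants)
    major = np.full(n, -1, dtype=np.int64)
    minor = np.zeros(n, dtype=np.int64)
    normal = np.full(n, 2, dtype=np.int64)
    v_chrom = variants["chrom"].to_numpy(dtype="U32")
    v_pos = variants["pos"].to_numpy()
    s_chrom = segments["chrom"].to_numpy(dtype="U32")
    s_order = np.lexsort((segments["start"].to_numpy(), s_chrom))
    s_chrom = s_chrom[s_order]
    s_start = segments["start"].to_numpy()[s_order]
    s_end = segments["end"].to_numpy()[s_order]
    s_major = segments["major_cn"].to_numpy()[s_order]
    s_minor = segments["minor_cn"].to_numpy()[s_order]
    s_normal = segments["normal_cn"].to_numpy()[s_order]
    for chrom in np.unique(v_chrom):
        mask = np.flatnonzero(v_chrom == chrom)
        lo = np.searchsorted(s_chrom, chrom, side="left")
        hi = np.searchsorted(s_chrom, chrom, side="right")
        if lo == hi:
            continue
        pos = v_pos[mask]
        idx = lo + np.searchsorted(s_start[lo:hi], pos, side="right") - 1
        valid = (idx >= lo) & (pos <= s_end[np.clip(idx, lo, None)])
        hit = mask[valid]
        major[hit] = s_major[idx[valid]]
        minor[hit] = s_minor[idx[valid]]
        normal[hit] = s_normal[idx[valid]]
    unmatched = major < 0
    if unmatched.any():
        logger.info("%d variants had no covering segment; assuming diploid", unmatched.sum())
        major[unmatched] = 1
        minor[unmatched] = 1
    return variants.assign(major_cn=major, minor_cn=minor, normal_cn=normal)


def assign_ccfs(variants: pd.DataFrame, meta: pd.DataFrame | SampleMeta,
                segments: pd.DataFrame) -> pd.DataFrame:
    """Vectorised per-sample CCF assignment for a call table.

    Adds columns ``major_cn``, ``minor_cn``, ``normal_cn``, ``multiplicity``,
    ``ccf``, ``ccf_uncapped`` and ``inconsistent`` (homozygous-deletion
    segments). Equivalent to :func:`compute_ccf` applied row-wise.
    """
    if isinstance(meta, SampleMeta):
        meta = pd.DataFrame([{"sample": meta.sample, "purity": meta.purity}])
    purity_by_sample = meta.set_index("sample")["purity"]
    frames = []
    for sample, sub in variants.groupby("sample", sort=False):
        p = float(purity_by_sample[sample])
        seg = segments[segments["sample"] == sample] if "sample" in segments.columns else segments
        sub = _join_segments(sub, seg)
        cnt = (sub["major_cn"] + sub["minor_cn"]).to_numpy(dtype=float)
        cnn = sub["normal_cn"].to_numpy(dtype=float)
        major = sub["major_cn"].to_numpy()
        vaf = sub["vaf"].to_numpy(dtype=float)
        denom = p * cnt + (1.0 - p) * cnn
        max_major = int(major.max()) if len(major) else 1
        best_m = np.ones(len(sub), dtype=int)
        best_err = np.full(len(sub), np.inf)
        for m in range(1, max(max_major, 1) + 1):
            allowed = major >= m
            err = np.abs(m * p / denom - vaf)
            better = allowed & (err < best_err - 1e-15)  # strict: ties keep smaller m
            best_m[better] = m
            best_err[better] = err[better]
        inconsistent = major == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            ccf_uncapped = vaf * denom / (p * best_m)
        ccf_uncapped[inconsistent] = np.nan
        sub = sub.assign(
            purity=p,
            multiplicity=np.where(inconsistent, 0, best_m),
            ccf=np.minimum(ccf_uncapped, 1.0),
            ccf_uncapped=ccf_uncapped,
            inconsistent=inconsistent,
        )
        n_over = int((ccf_uncapped > 1.0).sum())
        if n_over:
            logger.info(
                "sample %s: %d/%d CCFs exceeded 1 before capping "
                "(purity/copy-number inconsistency diagnostics)",
                sample, n_over, len(sub),
            )
        frames.append(sub)
    return pd.concat(frames, ignore_index=True) if frames else variants.copy()


def _em_binomial_mixture(alt, depth, vaf_factor, k, init_phi, max_iter=500, tol=1e-8):
    """EM fit of a k-component binomial mixture with success prob phi_c * r_i."""
    n = len(alt)
    eps = 1e-6
    log_binom = gammaln(depth + 1) - gammaln(alt + 1) - gammaln(depth - alt + 1)
    phi = np.clip(np.asarray(init_phi, dtype=float), eps, 1.0)
    w = np.full(k, 1.0 / k)
    prev_ll = -np.inf
    for _ in range(max_iter):
        p = np.clip(phi[None, :] * vaf_factor[:, None], eps, 1 - eps)  # (n, k)
        logp = (
            log_binom[:, None]
            + alt[:, None] * np.log(p)
            + (depth - alt)[:, None] * np.log1p(-p)
            + np.log(np.clip(w, 1e-300, None))[None, :]
        )
        ll_i = logsumexp(logp, axis=1)
        ll = float(ll_i.sum())
        gamma = np.exp(logp - ll_i[:, None])
        w = gamma.mean(axis=0)
        denom = gamma.T @ (depth * vaf_factor)
        num = gamma.T @ alt
        phi = np.clip(np.where(denom > 0, num / np.maximum(denom, 1e-300), phi), eps, 1.0)
        if abs(ll - prev_ll) < tol * max(1.0, abs(ll)):
            prev_ll = ll
            break
        prev_ll = ll
    labels = np.argmax(gamma, axis=1)
    return phi, w, labels, prev_ll


def cluster_ccfs(assigned: pd.DataFrame, max_clones: int = MAX_CLONES,
                 seed: int = 0) -> CloneSet:
    """Cluster mutations into CCF clones by a BIC-selected binomial mixture.

    Expects the output of :func:`assign_ccfs` (needs ``t_alt_count``,
    ``t_ref_count``, ``multiplicity``, copy-number columns and a per-sample
    purity already folded into ``ccf``); rows flagged inconsistent are
    excluded. Component count runs over 1..max_clones (default cap 15) and
    the best model by BIC is returned with hard maximum-responsibility
    labels (-1 for excluded rows).
    """
    usable = ~assigned["inconsistent"].to_numpy(dtype=bool)
    sub = assigned.loc[usable]
    if len(sub) == 0:
        raise ValueError("no assignable variants to cluster")
    alt = sub["t_alt_count"].to_numpy(dtype=float)
    depth = alt + sub["t_ref_count"].to_numpy(dtype=float)
    # vaf_factor r_i maps a clone CCF to that mutation's expected VAF
    p = sub["purity"].to_numpy(dtype=float)
    cnt = (sub["major_cn"] + sub["minor_cn"]).to_numpy(dtype=float)
    cnn = sub["normal_cn"].to_numpy(dtype=float)
    m = sub["multiplicity"].to_numpy(dtype=float)
    vaf_factor = m * p / (p * cnt + (1.0 - p) * cnn)
    ccf_hat = np.clip(alt / np.maximum(depth * vaf_factor, 1e-12), 0.0, 1.0)
    n = len(sub)
    rng = np.random.default_rng(seed)

    best = None
    worse_streak = 0
    for k in range(1, min(max_clones, n) + 1):
        q = (np.arange(k) + 0.5) / k
        init = np.quantile(ccf_hat, q) + rng.normal(0.0, 1e-4, k)
        phi, w, labels, ll = _em_binomial_mixture(alt, depth, vaf_factor, k, init)
        bic = (2 * k - 1) * np.log(n) - 2.0 * ll
        if best is None or bic < best[0] - 1e-9:
            best = (bic, phi, w, labels)
            worse_streak = 0
        else:
            # BIC worsening twice in a row: larger models won't recover
            worse_streak += 1
            if worse_streak >= 2:
                break
    bic, phi, w, labels = best

    # keep only clusters that own at least one mutation; renumber by CCF
    owned = np.unique(labels)
    order = owned[np.argsort(phi[owned])]
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[l] for l in labels])
    clusters = []
    for new, old in enumerate(order):
        members = labels == new
        clusters.append((new, float(phi[old]), float(members.sum() / n)))

    full_labels = np.full(len(assigned), -1, dtype=int)
    full_labels[np.flatnonzero(usable)] = labels
    return CloneSet(clusters=clusters, labels=full_labels.tolist(), bic=float(bic))


def clonality_score(ccf_values) -> float:
    """Frequency-weighted CCF score: 1 = entirely clonal, -> 0 = subclonal.

    The sum of each clone's CCF weighted by the fraction of mutations it
    contains reduces to the mutation-level mean CCF, which is what is
    computed here.
    """
    ccf = np.asarray(ccf_values, dtype=float)
    ccf = ccf[np.isfinite(ccf)]
    if ccf.size == 0:
        raise ValueError("clonality score undefined for empty input")
    if (ccf < 0).any() or (ccf > 1).any():
        raise ValueError("CCFs must lie in [0, 1] (cap before scoring)")
    return float(ccf.mean())


def clonality_score_by_clone(ccf_values, clone_labels) -> float:
    """Clone-decomposed form: sum over clones of mutation_fraction x mean CCF."""
    df = pd.DataFrame({"ccf": np.asarray(ccf_values, dtype=float), "clone": clone_labels})
    df = df[np.isfinite(df["ccf"])]
    if df.empty:
        raise ValueError("clonality score undefined for empty input")
    n = len(df)
    per_clone = df.groupby("clone")["ccf"].agg(["mean", "size"])
    return float((per_clone["mean"] * per_clone["size"] / n).sum())


def delta_clonality(scores: pd.DataFrame, group_column: str | None = "immune_group"):
    """Per-patient change in clonality (recurrence - baseline) and group test.

    *scores* needs columns ``patient``, ``timepoint``, ``score`` and, for
    the group comparison, *group_column*. Patients missing either timepoint
    are excluded with a warning. Returns ``(deltas, test)`` where *test* is
    a two-sided rank-sum comparison of deltas between groups (None if no
    grouping or fewer than two groups).
    """
    wide = scores.pivot_table(index="patient", columns="timepoint", values="score", aggfunc="first")
    for tp in ("baseline", "recurrence"):
        if tp not in wide.columns:
            wide[tp] = np.nan
    incomplete = wide["baseline"].isna() | wide["recurrence"].isna()
    if incomplete.any():
        logger.warning(
            "excluding %d patients missing a timepoint: %s",
            incomplete.sum(), list(wide.index[incomplete]),
        )
    wide = wide[~incomplete]
    deltas = (wide["recurrence"] - wide["baseline"]).rename("delta_clonality").reset_index()
    test = None
    if group_column is not None and group_column in scores.columns:
        groups = scores.drop_duplicates("patient").set_index("patient")[group_column]
        deltas[group_column] = deltas["patient"].map(groups)
        levels = deltas[group_column].dropna().unique()
        if len(levels) == 2:
            g0 = deltas.loc[deltas[group_column] == levels[0], "delta_clonality"]
            g1 = deltas.loc[deltas[group_column] == levels[1], "delta_clonality"]
            test = rank_sum_test(g0, g1)
            test["groups"] = (str(levels[0]), str(levels[1]))
    return deltas, test
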