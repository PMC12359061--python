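"""Synthetic paired-tumour cohort generator with known clonal truth.

Emulates a cohort of patients profiled by whole-exome sequencing at an
initial resection (baseline) and at recurrence, with:

* a flat clone model — each sample is a mixture of CCF clusters, with a
  configurable fraction of mutations shared (truncal) between timepoints
  and the remainder private to one timepoint (truly absent, CCF 0, at the
  other);
* binomial read sampling — the observed VAF of a mutation is drawn as
  ``alt ~ Binomial(depth, CCF * purity * m / (purity * CNt + (1 - purity) * CNn))``
  with per-chromosome allele-specific copy number and per-mutation
  multiplicity, and depth Poisson-distributed around the configured mean
  (floored at 10 reads);
* formalin-fixation artefacts — spurious low-VAF C>T / G>A calls injected
  per sample at a Poisson rate;
* fabricated neoantigen labels with consistent MHC-binding affinities, and
  a tunable immunoediting selection coefficient that depletes neoantigen
  CCFs at recurrence;
* loss-of-function mutations planted in immune-evasion catalogue genes;
* an optional promoter-methylation beta matrix.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, PatientPair, TRUTH_COLUMNS
from .types import VARIANT_CLASSES, LOF_CLASSES

__all__ = [
    "SimulationConfig",
    "simulate_cohort",
    "inject_ffpe_artifacts",
    "apply_immunoediting",
    "simulate_promoter_methylation",
]

_GENOME_SPAN = 200_000_000  # per-chromosome coordinate space
_CHROMS = [str(c) for c in range(1, 23)]
_BASES = np.array(list("ACGT"))

# (major, minor) states and their sampling weights
_CN_STATES = [(1, 1), (2, 1), (2, 2), (1, 0), (2, 0), (3, 1)]
_CN_WEIGHTS = [0.55, 0.15, 0.10, 0.10, 0.05, 0.05]

# functional classes for background (non-planted) mutations
_CLASS_PROBS = {
    "missense": 0.58,
    "silent": 0.20,
    "nonsense": 0.04,
    "splice": 0.05,
    "frameshift_ins": 0.02,
    "frameshift_del": 0.03,
    "in_frame_indel": 0.02,
    "nonstop": 0.01,
    "other": 0.05,
}


@dataclass
class SimulationConfig:
    """Study conditions for a simulated paired-recurrence cohort.

    Defaults mirror a small FFPE exome cohort: 15 patients sequenced at
    100X (tumour) against 50X normals, most mutations private to one
    timepoint, and a handful of low-VAF fixation artefacts per sample.
    """

    n_patients: int = 15
    clones_per_sample_range: tuple[int, int] = (3, 6)
    #: fraction of each sample's mutations shared (truncal) across timepoints
    trunk_shared_fraction: float = 0.2
    mutations_per_sample_range: tuple[int, int] = (100, 300)
    purity_range: tuple[float, float] = (0.3, 0.9)
    tumour_depth_mean: float = 100.0
    normal_depth_mean: float = 50.0  # recorded study condition; germline reads are not simulated
    #: expected number of injected FFPE artefacts per sample
    ffpe_artifact_rate: float = 20.0
    #: Beta shape parameters for the true artefact VAF (low-VAF by default)
    artifact_vaf_beta_params: tuple[float, float] = (1.5, 30.0)
    neoantigen_fraction: float = 0.15
    #: immunoediting strength: recurrence CCF of neoantigens scaled by (1 - s)
    selection_coefficient_s: float = 0.0
    #: expected number of planted immune-evasion LoF mutations per sample
    evasion_lof_rate: float = 1.0
    #: fraction of patients in the immunocompromised (transplant) group
    fraction_immunocompromised: float = 2 / 3
    #: force shared clones to keep identical CCFs at both timepoints
    shared_ccf_identical: bool = False
    #: optional detection-limit censoring of observed calls (off by default)
    detection_limit_vaf: float | None = None
    n_gene_pool: int = 400
    seed: int = 0

    def __post_init__(self):
        for name in ("trunk_shared_fraction", "neoantigen_fraction", "fraction_immunocompromised"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.selection_coefficient_s <= 1.0:
            raise ValueError("selection_coefficient_s must lie in [0, 1]")
        if self.tumour_depth_mean <= 0 or self.normal_depth_mean <= 0:
            raise ValueError("depth means must be positive")
        if self.ffpe_artifact_rate < 0:
            raise ValueError("ffpe_artifact_rate must be non-negative")
        for name in ("clones_per_sample_range", "mutations_per_sample_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValueError(f"{name} must be a non-empty positive interval")
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("purity_range must lie within (0, 1]")


def _draw_bases(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    ref = _BASES[rng.integers(0, 4, n)]
    shift = rng.integers(1, 4, n)
    alt = _BASES[(np.searchsorted(_BASES, ref) + shift) % 4]
    return ref, alt


def _draw_positions(rng: np.random.Generator, n: int, used: set[tuple[str, int]]):
    """Unique (chrom, pos) pairs per patient."""
    chroms = np.empty(n, dtype=object)
    poss = np.empty(n, dtype=np.int64)
    for i in range(n):
        while True:
            c = _CHROMS[rng.integers(0, len(_CHROMS))]
            p = int(rng.integers(1, _GENOME_SPAN))
            if (c, p) not in used:
                used.add((c, p))
                break
        chroms[i], poss[i] = c, p
    return chroms, poss


def _simulate_segments(rng: np.random.Generator, sample: str) -> pd.DataFrame:
    idx = rng.choice(len(_CN_STATES), size=len(_CHROMS), p=_CN_WEIGHTS)
    major = np.array([_CN_STATES[i][0] for i in idx])
    minor = np.array([_CN_STATES[i][1] for i in idx])
    return pd.DataFrame(
        {
            "sample": sample,
            "chrom": _CHROMS,
            "start": 1,
            "end": _GENOME_SPAN,
            "major_cn": major,
            "minor_cn": minor,
            "normal_cn": 2,
        }
    )


def _patient_truth(cfg: SimulationConfig, rng: np.random.Generator, patient: str,
                   gene_pool: np.ndarray) -> pd.DataFrame:
    """Generative truth for one patient: clones, CCFs, labels (no reads yet)."""
    n_per_sample = int(rng.integers(cfg.mutations_per_sample_range[0],
                                    cfg.mutations_per_sample_range[1] + 1))
    n_shared = int(round(cfg.trunk_shared_fraction * n_per_sample))
    n_priv = n_per_sample - n_shared
    k_clones = int(rng.integers(cfg.clones_per_sample_range[0],
                                cfg.clones_per_sample_range[1] + 1))

    clone_ids, ccf_b, ccf_r, counts = [], [], [], []
    next_clone = 0

    def _alloc(n_mut, k):
        w = rng.dirichlet(np.ones(k))
        return rng.multinomial(n_mut, w)

    if n_shared > 0:
        k_shared = max(1, int(round(k_clones * cfg.trunk_shared_fraction)))
        k_shared = min(k_shared, n_shared)
        cb = rng.uniform(0.1, 0.95, k_shared)
        cr = cb.copy() if cfg.shared_ccf_identical else rng.uniform(0.1, 0.95, k_shared)
        cb[0] = cr[0] = 1.0  # truncal clone is fully clonal at both timepoints
        alloc = _alloc(n_shared, k_shared)
        for j in range(k_shared):
            clone_ids.append(next_clone)
            ccf_b.append(cb[j])
            ccf_r.append(cr[j])
            counts.append(alloc[j])
            next_clone += 1
    else:
        k_shared = 0

    k_priv = max(1, k_clones - k_shared) if n_priv > 0 else 0
    for tp in ("baseline", "recurrence"):
        if k_priv == 0:
            continue
        k = min(k_priv, n_priv) if n_priv else 0
        if k == 0:
            continue
        cc = rng.uniform(0.1, 0.95, k)
        if n_shared == 0:
            cc[0] = 1.0  # keep a clonal peak even with no shared trunk
        alloc = _alloc(n_priv, k)
        for j in range(k):
            clone_ids.append(next_clone)
            ccf_b.append(cc[j] if tp == "baseline" else 0.0)
            ccf_r.append(cc[j] if tp == "recurrence" else 0.0)
            counts.append(alloc[j])
            next_clone += 1

    clone_of_mut = np.repeat(clone_ids, counts)
    ccf_b_mut = np.repeat(ccf_b, counts)
    ccf_r_mut = np.repeat(ccf_r, counts)
    n_total = len(clone_of_mut)

    used: set[tuple[str, int]] = set()
    chroms, poss = _draw_positions(rng, n_total, used)
    ref, alt = _draw_bases(rng, n_total)
    classes = rng.choice(list(_CLASS_PROBS), size=n_total, p=list(_CLASS_PROBS.values()))
    genes = gene_pool[rng.integers(0, len(gene_pool), n_total)]

    is_neo = rng.random(n_total) < cfg.neoantigen_fraction
    affinity = np.where(
        is_neo,
        10 ** rng.uniform(0.7, np.log10(500.0), n_total),   # binders: ~5-500 nM
        10 ** rng.uniform(np.log10(520.0), 4.3, n_total),   # non-binders: >500 nM
    )

    truth = pd.DataFrame(
        {
            "patient": patient,
            "mutation_id": [f"{patient}_M{i:05d}" for i in range(n_total)],
            "chrom": chroms,
            "pos": poss,
            "ref": ref,
            "alt": alt,
            "gene_symbol": genes,
            "variant_classification": classes,
            "clone_id": clone_of_mut,
            "ccf_baseline": ccf_b_mut,
            "ccf_recurrence": ccf_r_mut,
            "is_artifact": False,
            "artifact_sample": "",
            "is_neoantigen": is_neo,
            "is_evasion_lof": False,
            "affinity_nm": affinity,
            "stringent_pass": is_neo,
        }
    )
    return truth


def _plant_evasion_lof(truth: pd.DataFrame, cfg: SimulationConfig,
                       rng: np.random.Generator, catalog_genes: list[str]) -> pd.DataFrame:
    """Relabel a Poisson number of present mutations per sample as catalogue LoF."""
    lof_classes = sorted(LOF_CLASSES)
    for col in ("ccf_baseline", "ccf_recurrence"):
        n_plant = rng.poisson(cfg.evasion_lof_rate)
        present = truth.index[(truth[col] > 0) & ~truth["is_evasion_lof"]].to_numpy()
        if n_plant == 0 or len(present) == 0:
            continue
        pick = rng.choice(present, size=min(n_plant, len(present)), replace=False)
        truth.loc[pick, "gene_symbol"] = rng.choice(catalog_genes, size=len(pick))
        truth.loc[pick, "variant_classification"] = rng.choice(lof_classes, size=len(pick))
        truth.loc[pick, "is_evasion_lof"] = True
    return truth


def draw_sample_calls(truth: pd.DataFrame, segments: pd.DataFrame, *, patient: str,
                      sample: str, timepoint: str, purity: float,
                      cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw an observed MAF-style call table for one sample from its truth CCFs.

    A mutation is "called" only if at least one alt read is drawn; private
    mutations (CCF 0 here) never appear.
    """
    ccf_col = "ccf_baseline" if timepoint == "baseline" else "ccf_recurrence"
    present = truth[(truth[ccf_col] > 0) & ~truth["is_artifact"]]
    n = len(present)
    seg = segments.set_index("chrom")
    cnt = (seg["major_cn"] + seg["minor_cn"]).reindex(present["chrom"]).to_numpy()
    major = seg["major_cn"].reindex(present["chrom"]).to_numpy()
    cnn = seg["normal_cn"].reindex(present["chrom"]).to_numpy()
    # per-mutation multiplicity: uniform over 1..major_cn of the host segment
    m = rng.integers(1, np.maximum(major, 1) + 1)
    exp_vaf = present[ccf_col].to_numpy() * purity * m / (purity * cnt + (1 - purity) * cnn)
    exp_vaf = np.clip(exp_vaf, 0.0, 1.0)
    depth = np.maximum(rng.poisson(cfg.tumour_depth_mean, n), 10)
    alt_count = rng.binomial(depth, exp_vaf)
    called = alt_count >= 1
    if cfg.detection_limit_vaf is not None:
        called &= alt_count / depth >= cfg.detection_limit_vaf
    out = pd.DataFrame(
        {
            "patient": patient,
            "sample": sample,
            "timepoint": timepoint,
            "chrom": present["chrom"].to_numpy()[called],
            "pos": present["pos"].to_numpy()[called],
            "ref": present["ref"].to_numpy()[called],
            "alt": present["alt"].to_numpy()[called],
            "t_ref_count": (depth - alt_count)[called],
            "t_alt_count": alt_count[called],
            "vaf": (alt_count / depth)[called],
            "variant_classification": present["variant_classification"].to_numpy()[called],
            "gene_symbol": present["gene_symbol"].to_numpy()[called],
        }
    )
    return out


def inject_ffpe_artifacts(calls: pd.DataFrame, rate: float,
                          vaf_params: tuple[float, float],
                          rng: np.random.Generator | int, *,
                          depth_mean: float = 100.0,
                          used_positions: set[tuple[str, int]] | None = None,
                          gene_pool: np.ndarray | None = None):
    """Add Poisson(rate) spurious formalin-deamination calls to one sample.

    Artefacts are C>T or G>A substitutions with true VAF drawn from a
    Beta(*vaf_params*) distribution (low-VAF by default) and at least one
    supporting read (otherwise the caller would not have emitted them).

    Returns ``(calls_with_artifacts, artifact_rows)``; the second frame holds
    the injected rows so truth labels can be maintained by the caller.
    """
    if rate < 0:
        raise ValueError("artefact rate must be non-negative")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    n_art = int(rng.poisson(rate))
    if n_art == 0:
        return calls, calls.iloc[0:0].copy()
    used = used_positions if used_positions is not None else set(
        zip(calls["chrom"], calls["pos"])
    )
    chroms, poss = _draw_positions(rng, n_art, used)
    is_ct = rng.random(n_art) < 0.5
    ref = np.where(is_ct, "C", "G")
    alt = np.where(is_ct, "T", "A")
    true_vaf = rng.beta(vaf_params[0], vaf_params[1], n_art)
    depth = np.maximum(rng.poisson(depth_mean, n_art), 10)
    alt_count = np.maximum(rng.binomial(depth, true_vaf), 1)
    if gene_pool is None:
        gene_pool = np.array([f"GENE{i:04d}" for i in range(400)])
    template = calls.iloc[0] if len(calls) else None
    art = pd.DataFrame(
        {
            "patient": template["patient"] if template is not None else "",
            "sample": template["sample"] if template is not None else "",
            "timepoint": template["timepoint"] if template is not None else "",
            "chrom": chroms,
            "pos": poss,
            "ref": ref,
            "alt": alt,
            "t_ref_count": depth - alt_count,
            "t_alt_count": alt_count,
            "vaf": alt_count / depth,
            "variant_classification": rng.choice(
                ["missense", "silent"], size=n_art, p=[0.7, 0.3]
            ),
            "gene_symbol": gene_pool[rng.integers(0, len(gene_pool), n_art)],
        }
    )
    return pd.concat([calls, art], ignore_index=True), art


def apply_immunoediting(pair: PatientPair, s: float,
                        cfg: SimulationConfig | None = None,
                        rng: np.random.Generator | int = 0) -> PatientPair:
    """Deplete neoantigen CCFs at recurrence by selection strength ``s``.

    Each neoantigen mutation's true recurrence CCF is multiplied by
    ``(1 - s)`` and the recurrence call table is re-drawn from the edited
    truth. ``s = 0`` is the immune-escape null (truth unchanged); ``s = 1``
    eliminates every neoantigen from the recurrence.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"selection coefficient must lie in [0, 1], got {s}")
    if pair.truth is None:
        raise ValueError("immunoediting requires simulation truth")
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    truth = pair.truth.copy()
    neo = truth["is_neoantigen"] & ~truth["is_artifact"]
    truth.loc[neo, "ccf_recurrence"] *= 1.0 - s
    rec_sample = pair.sample_id("recurrence")
    rec_meta = pair.meta[pair.meta["sample"] == rec_sample].iloc[0]
    rec_segments = pair.segments[pair.segments["sample"] == rec_sample]
    recurrence = draw_sample_calls(
        truth, rec_segments, patient=pair.patient, sample=rec_sample,
        timepoint="recurrence", purity=float(rec_meta["purity"]), cfg=cfg, rng=rng,
    )
    return PatientPair(
        patient=pair.patient, baseline=pair.baseline, recurrence=recurrence,
        segments=pair.segments, meta=pair.meta, truth=truth,
    )


def simulate_cohort(config: SimulationConfig | None = None, *,
                    catalog_genes: list[str] | None = None) -> Cohort:
    """Generate a full paired cohort with truth labels.

    Per patient: a clone structure and mutation pool, immunoediting of the
    recurrence when ``selection_coefficient_s > 0``, binomial read draws for
    both timepoints, and FFPE artefact injection per sample.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    if catalog_genes is None:
        from .evasion import load_catalog

        catalog_genes = sorted(load_catalog().gene_symbols)
    gene_pool = np.array([f"GENE{i:04d}" for i in range(cfg.n_gene_pool)])

    n_compromised = int(round(cfg.fraction_immunocompromised * cfg.n_patients))
    variants, segments, metas, truths = [], [], [], []
    for i in range(cfg.n_patients):
        patient = f"P{i + 1:02d}"
        group = "immunocompromised" if i < n_compromised else "immunocompetent"
        truth = _patient_truth(cfg, rng, patient, gene_pool)
        truth = _plant_evasion_lof(truth, cfg, rng, catalog_genes)
        if cfg.selection_coefficient_s > 0:
            neo = truth["is_neoantigen"] & ~truth["is_artifact"]
            truth.loc[neo, "ccf_recurrence"] *= 1.0 - cfg.selection_coefficient_s
        used = set(zip(truth["chrom"], truth["pos"]))
        for tp in ("baseline", "recurrence"):
            sample = f"{patient}_{'B' if tp == 'baseline' else 'R'}"
            purity = rng.uniform(*cfg.purity_range)
            seg = _simulate_segments(rng, sample)
            calls = draw_sample_calls(
                truth, seg, patient=patient, sample=sample, timepoint=tp,
                purity=purity, cfg=cfg, rng=rng,
            )
            calls, art = inject_ffpe_artifacts(
                calls, cfg.ffpe_artifact_rate, cfg.artifact_vaf_beta_params, rng,
                depth_mean=cfg.tumour_depth_mean, used_positions=used,
                gene_pool=gene_pool,
            )
            if len(art):
                art_truth = pd.DataFrame(
                    {
                        "patient": patient,
                        "mutation_id": [
                            f"{patient}_A{tp[0].upper()}{j:04d}" for j in range(len(art))
                        ],
                        "chrom": art["chrom"],
                        "pos": art["pos"],
                        "ref": art["ref"],
                        "alt": art["alt"],
                        "gene_symbol": art["gene_symbol"],
                        "variant_classification": art["variant_classification"],
                        "clone_id": np.nan,  # artefacts carry no clone membership
                        "ccf_baseline": 0.0,
                        "ccf_recurrence": 0.0,
                        "is_artifact": True,
                        "artifact_sample": sample,
                        "is_neoantigen": False,
                        "is_evasion_lof": False,
                        "affinity_nm": np.nan,
                        "stringent_pass": False,
                    }
                )
                truth = pd.concat([truth, art_truth], ignore_index=True)
            if len(calls):
                calls["patient"] = patient
                calls["sample"] = sample
                calls["timepoint"] = tp
            variants.append(calls)
            segments.append(seg)
            metas.append(
                {
                    "sample": sample,
                    "patient": patient,
                    "timepoint": tp,
                    "purity": purity,
                    "ploidy": 2.0,
                    "immune_group": group,
                }
            )
        truths.append(truth[TRUTH_COLUMNS])

    return Cohort(
        variants=pd.concat(variants, ignore_index=True),
        segments=pd.concat(segments, ignore_index=True),
        meta=pd.DataFrame(metas),
        truth=pd.concat(truths, ignore_index=True),
    )


def simulate_promoter_methylation(cohort: Cohort, *,
                                  probes_per_gene_range: tuple[int, int] = (3, 8),
                                  neoantigen_shift: float = 0.0,
                                  noise_sd: float = 0.05,
                                  seed: int | np.random.Generator = 0):
    """Fabricate an EPIC-style promoter beta matrix for a simulated cohort.

    Probes are annotated to genes with region classes TSS200 / TSS1500 /
    1stExon / other. ``neoantigen_shift`` adds a methylation offset at
    recurrence to promoters of genes carrying a stringent-pass neoantigen in
    that patient — the alternative for power testing; at 0 the neoantigen
    and control promoter distributions coincide by construction.

    Returns ``(beta_matrix, probe_annotation)`` where the matrix is probes x
    samples with values clipped to [0, 1].
    """
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    if cohort.truth is None:
        raise ValueError("methylation simulation requires truth labels")
    genes = np.sort(cohort.truth.loc[~cohort.truth["is_artifact"], "gene_symbol"].unique())
    classes = np.array(["TSS200", "TSS1500", "1stExon", "other"])
    class_p = [0.3, 0.3, 0.2, 0.2]
    n_probes = rng.integers(probes_per_gene_range[0], probes_per_gene_range[1] + 1, len(genes))
    ann = pd.DataFrame(
        {
            "probe_id": [f"cg{k:07d}" for k in range(int(n_probes.sum()))],
            "gene_symbol": np.repeat(genes, n_probes),
            "region_class": rng.choice(classes, size=int(n_probes.sum()), p=class_p),
        }
    )
    gene_level = pd.Series(rng.uniform(0.15, 0.85, len(genes)), index=genes)
    probe_offset = rng.normal(0.0, 0.03, len(ann))
    base = gene_level.reindex(ann["gene_symbol"]).to_numpy() + probe_offset

    # per-patient neoantigen-bearing gene sets (any stringent-pass mutation)
    neo_by_patient = {
        p: set(g["gene_symbol"][g["stringent_pass"] & ~g["is_artifact"]])
        for p, g in cohort.truth.groupby("patient")
    }
    meta = cohort.meta.set_index("sample")
    betas = {}
    for sample in cohort.meta["sample"]:
        b = base + rng.normal(0.0, noise_sd, len(ann))
        if neoantigen_shift != 0.0 and meta.loc[sample, "timepoint"] != "baseline":
            neo_genes = neo_by_patient.get(meta.loc[sample, "patient"], set())
            b = b + neoantigen_shift * ann["gene_symbol"].isin(neo_genes).to_numpy()
        betas[sample] = np.clip(b, 0.0, 1.0)
    beta = pd.DataFrame(betas, index=ann["probe_id"]).rename_axis("probe_id")
    return beta, ann
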