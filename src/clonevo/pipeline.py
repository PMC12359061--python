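"""Orchestration: simulate -> filter -> CCF/clonality -> divergence ->
neoantigen -> evasion -> methylation, from one config.

Each run writes into a fresh versioned subdirectory (``run_0001``,
``run_0002``, ...) of the output directory — re-running never overwrites a
previous run — containing per-stage TSV/JSON artefacts, a manifest
(package version, seed, config hash) and a human-readable summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ccf import assign_ccfs, cluster_ccfs, clonality_score, delta_clonality
from .cohort import Cohort
from .divergence import (
    build_cross_timepoint_null,
    classify_private_public,
    compare_matched_vs_null,
    mutation_keys,
    overlap_percent,
)
from .evasion import covariate_association, fisher_group_comparison, flag_samples, load_catalog
from .filtering import apply_artifact_filters
from .neoantigen import compare_dynamics, compute_delta_ccf
from .methylation import compare_shifts, summarise_promoters
from .simulate import SimulationConfig, simulate_cohort, simulate_promoter_methylation

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

ALL_STAGES = ("filter", "ccf", "divergence", "neoantigen", "evasion", "methylation")


@dataclass
class RunConfig:
    """Pipeline settings: stage toggles, inputs (or simulation), thresholds."""

    outdir: str = "results/pipeline"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    #: directory with variants.maf.tsv / segments.tsv / sample_meta.tsv; None -> simulate
    input_dir: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    vaf_threshold: float = 0.10
    signature_filter: bool = True
    strong_binder_nm: float = 100.0
    weak_binder_nm: float = 500.0
    alpha: float = 0.05
    max_clones: int = 15
    catalog_path: str | None = None
    methylation_shift: float = 0.0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        sim = raw.pop("simulation", {})
        cfg = cls(**raw)
        if sim:
            cfg.simulation = SimulationConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _next_run_dir(outdir: Path) -> Path:
    outdir.mkdir(parents=True, exist_ok=True)
    existing = [int(p.name[4:]) for p in outdir.glob("run_[0-9]*") if p.name[4:].isdigit()]
    run = outdir / f"run_{max(existing, default=0) + 1:04d}"
    run.mkdir()
    return run


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages and return a report dict (also written to disk)."""
    run_dir = _next_run_dir(Path(config.outdir))
    cfg_blob = json.dumps(config.to_dict(), sort_keys=True, default=_json_default)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(cfg_blob.encode()).hexdigest(),
        "stages_run": [],
        "run_dir": str(run_dir),
    }
    summary_lines = [f"clonevo {__version__} run in {run_dir}"]
    report: dict = {"run_dir": str(run_dir)}

    if config.input_dir is not None:
        cohort = Cohort.read(config.input_dir)
        summary_lines.append(f"loaded cohort from {config.input_dir}")
    else:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        cohort = simulate_cohort(sim)
        cohort.write(run_dir / "simulated")
        summary_lines.append(
            f"simulated {sim.n_patients} patients "
            f"({len(cohort.variants)} calls, seed {config.seed})"
        )
    manifest["stages_run"].append("simulate" if config.input_dir is None else "load")

    filtered = cohort.variants
    if "filter" in config.stages:
        frames, reports = [], {}
        for sample, sub in cohort.variants.groupby("sample", sort=True):
            kept, rep = apply_artifact_filters(
                sub, vaf_threshold=config.vaf_threshold,
                signature_filter=config.signature_filter,
            )
            frames.append(kept)
            reports[sample] = rep.to_dict()
        filtered = pd.concat(frames, ignore_index=True)
        filtered.to_csv(run_dir / "variants_filtered.tsv", sep="\t", index=False)
        _write_json(run_dir / "filter_report.json", reports)
        pd.DataFrame(reports).T.rename_axis("sample").reset_index().to_csv(
            run_dir / "filter_report.tsv", sep="\t", index=False
        )
        manifest["stages_run"].append("filter")
        rates = [r["retention_rate"] for r in reports.values()]
        summary_lines.append(
            f"filter: retention rate {np.mean(rates):.3f} "
            f"(range {np.min(rates):.3f}-{np.max(rates):.3f}) across {len(rates)} samples"
        )
        report["filter"] = reports

    fcohort = Cohort(
        variants=filtered, segments=cohort.segments, meta=cohort.meta,
        truth=cohort.truth,
    )

    assigned = None
    if "ccf" in config.stages or "neoantigen" in config.stages:
        assigned = assign_ccfs(filtered, cohort.meta, cohort.segments)
        assigned.to_csv(run_dir / "ccf_assignments.tsv", sep="\t", index=False)

    if "ccf" in config.stages:
        scores, clone_rows = [], []
        for sample, sub in assigned.groupby("sample", sort=True):
            meta_row = cohort.meta.loc[cohort.meta["sample"] == sample].iloc[0]
            usable = sub.loc[~sub["inconsistent"], "ccf"]
            if usable.empty:
                continue
            scores.append(
                {
                    "sample": sample,
                    "patient": meta_row["patient"],
                    "timepoint": meta_row["timepoint"],
                    "immune_group": meta_row["immune_group"],
                    "score": clonality_score(usable),
                }
            )
            clones = cluster_ccfs(sub, max_clones=config.max_clones, seed=config.seed)
            for cid, centre, frac in clones.clusters:
                clone_rows.append(
                    {"sample": sample, "clone_id": cid, "ccf_centre": centre,
                     "mutation_fraction": frac}
                )
        scores_df = pd.DataFrame(scores)
        scores_df.to_csv(run_dir / "clonality_scores.tsv", sep="\t", index=False)
        pd.DataFrame(clone_rows).to_csv(run_dir / "clones.tsv", sep="\t", index=False)
        deltas, group_test = delta_clonality(scores_df)
        deltas.to_csv(run_dir / "delta_clonality.tsv", sep="\t", index=False)
        _write_json(run_dir / "delta_clonality_test.json", group_test or {})
        manifest["stages_run"].append("ccf")
        line = f"ccf: mean clonality {scores_df['score'].mean():.3f}"
        if group_test:
            line += f"; delta-clonality group test p = {group_test['p_value']:.3g}"
        summary_lines.append(line)
        report["ccf"] = {
            "mean_clonality": float(scores_df["score"].mean()),
            "delta_test": group_test,
        }

    if "divergence" in config.stages:
        rows, matched, base_profiles, rec_profiles = [], [], [], []
        for pair in fcohort.iter_pairs():
            labels, pct_public = classify_private_public(pair)
            base, rec = mutation_keys(pair.baseline), mutation_keys(pair.recurrence)
            rows.append(
                {"patient": pair.patient, "percent_public": pct_public,
                 "n_baseline": len(base), "n_recurrence": len(rec)}
            )
            matched.append(overlap_percent(base, rec))
            base_profiles.append(base)
            rec_profiles.append(rec)
        null = build_cross_timepoint_null(base_profiles, rec_profiles)
        test = compare_matched_vs_null(matched, null)
        pd.DataFrame(rows).to_csv(run_dir / "private_public.tsv", sep="\t", index=False)
        pd.DataFrame({"overlap_percent": null.values}).to_csv(
            run_dir / "unmatched_null.tsv", sep="\t", index=False
        )
        _write_json(run_dir / "divergence_test.json", test)
        manifest["stages_run"].append("divergence")
        summary_lines.append(
            f"divergence: median percent public "
            f"{np.median([r['percent_public'] for r in rows]):.1f}%; "
            f"matched vs unmatched p = {test['p_value']:.3g} "
            f"({'matched higher' if test['matched_greater'] else 'no elevation'})"
        )
        report["divergence"] = test

    if "neoantigen" in config.stages:
        records = []
        for pair in fcohort.iter_pairs():
            sub = assigned[assigned["patient"] == pair.patient]
            rec = compute_delta_ccf(
                pair,
                sub[sub["timepoint"] == "baseline"],
                sub[sub["timepoint"] == "recurrence"],
            )
            records.append(rec)
        records = pd.concat(records, ignore_index=True)
        records.to_csv(run_dir / "delta_ccf.tsv", sep="\t", index=False)
        dyn = compare_dynamics(records)
        _write_json(run_dir / "neoantigen_dynamics.json", dyn)
        manifest["stages_run"].append("neoantigen")
        summary_lines.append(
            f"neoantigen: pooled delta-CCF test p = {dyn['pooled']['p_value']:.3g}, "
            f"median difference {dyn['pooled']['median_difference']:+.4f}"
        )
        report["neoantigen"] = dyn["pooled"]

    if "evasion" in config.stages:
        catalog = load_catalog(config.catalog_path)
        flags = flag_samples(filtered, catalog, by="sample")
        groups = cohort.meta.set_index("sample")["immune_group"]
        fisher = fisher_group_comparison(flags, groups)
        tmb = filtered.groupby("sample").size()
        assoc = covariate_association(flags, tmb)
        out = flags.copy()
        out["supporting_variants"] = out["supporting_variants"].map(";".join)
        out.to_csv(run_dir / "evasion_flags.tsv", sep="\t", index=False)
        _write_json(run_dir / "evasion_tests.json", {"fisher": fisher, "tmb_association": assoc})
        manifest["stages_run"].append("evasion")
        summary_lines.append(
            f"evasion: {int(flags['has_evasion_lof'].sum())}/{len(flags)} samples flagged; "
            f"Fisher p = {fisher['p_value']:.3g}, OR = {fisher['odds_ratio']:.2f}"
        )
        report["evasion"] = fisher

    if "methylation" in config.stages:
        if cohort.methylation is None:
            if cohort.truth is None:
                logger.warning("methylation stage skipped: no beta matrix and no truth")
                beta = None
            else:
                beta, ann = simulate_promoter_methylation(
                    cohort, neoantigen_shift=config.methylation_shift, seed=config.seed,
                )
        else:
            beta, ann = cohort.methylation, cohort.probe_annotation
        if beta is not None:
            summaries = summarise_promoters(beta, ann)
            summaries.to_csv(run_dir / "promoter_summaries.tsv", sep="\t", index=False)
            neo_genes = {}
            if cohort.truth is not None:
                neo_genes = {
                    p: set(g.loc[g["stringent_pass"] & ~g["is_artifact"], "gene_symbol"])
                    for p, g in cohort.truth.groupby("patient")
                }
            shifts = compare_shifts(summaries, cohort.meta, neo_genes)
            shifts["shifts"].to_csv(run_dir / "promoter_shifts.tsv", sep="\t", index=False)
            _write_json(
                run_dir / "methylation_tests.json",
                {"overall": shifts["overall"], "by_group": shifts["by_group"]},
            )
            manifest["stages_run"].append("methylation")
            ov = shifts["overall"]
            summary_lines.append(
                "methylation: neoantigen-gene shift test "
                + (f"p = {ov['p_value']:.3g}" if ov else "not testable")
            )
            report["methylation"] = shifts["overall"]

    _write_json(run_dir / "manifest.json", manifest)
    (run_dir / "summary.txt").write_text("\n".join(summary_lines) + "\n")
    logger.info("pipeline finished: %s", run_dir)
    report["manifest"] = manifest
    report["summary"] = summary_lines
    return report
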