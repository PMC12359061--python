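"""Generator behaviour: read model, determinism, artefacts, immunoediting."""

import numpy as np
import pandas as pd
import pytest

from clonevo.divergence import mutation_keys, overlap_percent
from clonevo.simulate import (
    SimulationConfig,
    apply_immunoediting,
    inject_ffpe_artifacts,
    simulate_cohort,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"trunk_shared_fraction": 1.5},
            {"trunk_shared_fraction": -0.1},
            {"selection_coefficient_s": 2.0},
            {"tumour_depth_mean": 0},
            {"normal_depth_mean": -5},
            {"ffpe_artifact_rate": -1},
            {"mutations_per_sample_range": (50, 10)},
            {"purity_range": (0.0, 0.5)},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_default_coverage_is_exome_study_design(self):
        cfg = SimulationConfig()
        assert cfg.tumour_depth_mean == 100
        assert cfg.normal_depth_mean == 50


class TestReadModel:
    def test_observed_vaf_matches_purity_ccf_expectation(self):
        """Clonal diploid het mutation at purity 0.5: mean VAF ~ 0.25 over 1e4 draws."""
        from clonevo.simulate import draw_sample_calls

        n = 10_000
        truth = pd.DataFrame(
            {
                "chrom": "1",
                "pos": np.arange(1, n + 1),
                "ref": "A",
                "alt": "T",
                "gene_symbol": "G",
                "variant_classification": "missense",
                "ccf_baseline": 1.0,
                "ccf_recurrence": 1.0,
                "is_artifact": False,
            }
        )
        segments = pd.DataFrame(
            {"chrom": ["1"], "start": [1], "end": [n + 1],
             "major_cn": [1], "minor_cn": [1], "normal_cn": [2]}
        )
        cfg = SimulationConfig()
        calls = draw_sample_calls(
            truth, segments, patient="P", sample="S", timepoint="baseline",
            purity=0.5, cfg=cfg, rng=np.random.default_rng(3),
        )
        expected = 0.25
        se = np.sqrt(expected * (1 - expected) / cfg.tumour_depth_mean / len(calls))
        assert abs(calls["vaf"].mean() - expected) < 3 * se

    def test_identical_seed_gives_byte_identical_tables(self):
        cfg = SimulationConfig(n_patients=3, seed=7)
        a = simulate_cohort(cfg)
        b = simulate_cohort(SimulationConfig(n_patients=3, seed=7))
        assert a.variants.to_csv() == b.variants.to_csv()
        assert a.truth.to_csv() == b.truth.to_csv()
        assert a.segments.to_csv() == b.segments.to_csv()
        assert a.meta.to_csv() == b.meta.to_csv()

    def test_full_trunk_sharing_gives_complete_overlap(self):
        """trunk=1 with identical clone CCFs: every truth mutation is public."""
        cfg = SimulationConfig(
            n_patients=4, trunk_shared_fraction=1.0, shared_ccf_identical=True,
            ffpe_artifact_rate=0.0, seed=5,
        )
        cohort = simulate_cohort(cfg)
        for pair in cohort.iter_pairs():
            t = pair.truth[~pair.truth["is_artifact"]]
            base = mutation_keys(t[t["ccf_baseline"] > 0])
            rec = mutation_keys(t[t["ccf_recurrence"] > 0])
            assert overlap_percent(base, rec) == 100.0
            assert overlap_percent(rec, base) == 100.0


class TestFfpeArtifacts:
    def _calls(self):
        return pd.DataFrame(
            {
                "patient": ["P1"], "sample": ["S1"], "timepoint": ["baseline"],
                "chrom": ["1"], "pos": [100], "ref": ["A"], "alt": ["T"],
                "t_ref_count": [80], "t_alt_count": [20], "vaf": [0.2],
                "variant_classification": ["missense"], "gene_symbol": ["G1"],
            }
        )

    def test_zero_rate_is_identity(self):
        calls = self._calls()
        out, art = inject_ffpe_artifacts(calls, 0.0, (1.5, 30.0), 1)
        pd.testing.assert_frame_equal(out, calls)
        assert art.empty

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            inject_ffpe_artifacts(self._calls(), -1.0, (1.5, 30.0), 1)

    def test_artifact_count_is_poisson_with_configured_mean(self):
        """Empirical mean over 200 samples within 3 SE of rate 20."""
        rng = np.random.default_rng(0)
        counts = [
            len(inject_ffpe_artifacts(self._calls(), 20.0, (1.5, 30.0), rng)[1])
            for _ in range(200)
        ]
        se = np.sqrt(20.0 / 200)
        assert abs(np.mean(counts) - 20.0) < 3 * se

    def test_artifacts_are_deamination_substitutions(self):
        _, art = inject_ffpe_artifacts(self._calls(), 50.0, (1.5, 30.0), 2)
        pairs = set(zip(art["ref"], art["alt"]))
        assert pairs <= {("C", "T"), ("G", "A")}

    def test_truth_flags_partition_artifacts_exactly(self, small_cohort):
        truth = small_cohort.truth
        art = truth[truth["is_artifact"]]
        real = truth[~truth["is_artifact"]]
        assert (art["clone_id"].isna()).all()
        assert (art["ccf_baseline"] == 0).all() and (art["ccf_recurrence"] == 0).all()
        assert real["clone_id"].notna().all()
        # artefact keys never collide with real mutation keys
        art_keys = set(zip(art["chrom"], art["pos"]))
        real_keys = set(zip(real["chrom"], real["pos"]))
        assert not art_keys & real_keys


class TestImmunoediting:
    def test_invalid_selection_rejected(self, small_cohort):
        pair = small_cohort.patient_pair("P01")
        with pytest.raises(ValueError):
            apply_immunoediting(pair, 1.5)

    def test_null_selection_leaves_truth_unchanged(self, small_cohort):
        pair = small_cohort.patient_pair("P01")
        edited = apply_immunoediting(pair, 0.0, rng=3)
        pd.testing.assert_frame_equal(edited.truth, pair.truth)

    def test_complete_selection_eliminates_neoantigens(self, small_cohort):
        pair = small_cohort.patient_pair("P02")
        edited = apply_immunoediting(pair, 1.0, rng=3)
        neo = edited.truth["is_neoantigen"] & ~edited.truth["is_artifact"]
        assert (edited.truth.loc[neo, "ccf_recurrence"] == 0).all()
        # edited neoantigens never appear in the re-drawn recurrence calls
        rec_keys = mutation_keys(edited.recurrence)
        neo_keys = mutation_keys(edited.truth.loc[neo])
        assert not rec_keys & neo_keys

    def test_half_selection_matches_analytic_truth_delta(self):
        """s=0.5: E[delta_neo] - E[delta_other] ~ -0.5 * mean baseline neo CCF."""
        cfg = SimulationConfig(
            n_patients=40, selection_coefficient_s=0.5, seed=9,
            mutations_per_sample_range=(200, 300),
        )
        truth = simulate_cohort(cfg).truth
        t = truth[~truth["is_artifact"]]
        delta = t["ccf_recurrence"] - t["ccf_baseline"]
        observed = delta[t["is_neoantigen"]].mean() - delta[~t["is_neoantigen"]].mean()
        # pre-edit recurrence CCFs are distributed like baseline CCFs, so the
        # expected group difference is -s * E[baseline neoantigen CCF]
        expected = -0.5 * t.loc[t["is_neoantigen"], "ccf_baseline"].mean()
        assert observed == pytest.approx(expected, abs=0.03)
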