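"""CCF estimation against a brute-force oracle, clustering recovery, clonality."""

import numpy as np
import pandas as pd
import pytest

from clonevo.ccf import (
    assign_ccfs,
    clonality_score,
    clonality_score_by_clone,
    cluster_ccfs,
    compute_ccf,
    delta_clonality,
    expected_vaf,
)
from clonevo.types import CopyNumberSegment, SampleMeta, VariantCall

from .conftest import make_assigned_frame
from .oracles import brute_force_ccf, exact_rank_sum_p


def variant(vaf, chrom="1", pos=500):
    alt = int(round(vaf * 100))
    return VariantCall(
        patient="P1", sample="S1", timepoint="baseline", chrom=chrom, pos=pos,
        ref="A", alt="T", t_ref_count=100 - alt, t_alt_count=alt, vaf=vaf,
    )


def meta(purity):
    return SampleMeta(sample="S1", patient="P1", timepoint="baseline", purity=purity)


class TestComputeCcf:
    def test_pure_diploid_het_clonal(self):
        seg = CopyNumberSegment("1", 1, 1000, 1, 1)
        a = compute_ccf(variant(0.5), meta(1.0), seg)
        assert a.ccf == pytest.approx(1.0)
        assert a.multiplicity == 1

    def test_half_purity_diploid(self):
        seg = CopyNumberSegment("1", 1, 1000, 1, 1)
        a = compute_ccf(variant(0.25), meta(0.5), seg)
        assert a.ccf == pytest.approx(1.0)

    def test_triploid_case_matches_oracle(self):
        seg = CopyNumberSegment("1", 1, 1000, 2, 1)
        a = compute_ccf(variant(0.55), meta(0.8), seg)
        m, ccf = brute_force_ccf(0.55, 0.8, 2, 1)
        assert a.multiplicity == m
        assert a.ccf == pytest.approx(ccf)

    def test_random_instances_match_brute_force_oracle(self):
        rng = np.random.default_rng(100)
        for _ in range(1000):
            purity = rng.uniform(0.1, 1.0)
            major = int(rng.integers(1, 5))
            minor = int(rng.integers(0, major + 1))
            vaf = rng.uniform(0.0, 1.0)
            seg = CopyNumberSegment("1", 1, 1000, major, minor)
            a = compute_ccf(variant(vaf), meta(purity), seg)
            m, ccf = brute_force_ccf(vaf, purity, major, minor)
            assert a.multiplicity == m
            assert a.ccf == pytest.approx(ccf)

    def test_homozygous_deletion_flagged_inconsistent(self):
        seg = CopyNumberSegment("1", 1, 1000, 0, 0)
        a = compute_ccf(variant(0.2), meta(0.7), seg)
        assert a.inconsistent and np.isnan(a.ccf)

    def test_position_outside_segment_rejected(self):
        seg = CopyNumberSegment("2", 1, 100, 1, 1)
        with pytest.raises(ValueError):
            compute_ccf(variant(0.2), meta(0.7), seg)

    def test_no_covering_segment_defaults_to_diploid(self):
        a = compute_ccf(variant(0.5), meta(1.0), None)
        assert a.ccf == pytest.approx(1.0) and a.multiplicity == 1

    def test_capping_retains_uncapped_diagnostic(self):
        seg = CopyNumberSegment("1", 1, 1000, 1, 1)
        a = compute_ccf(variant(0.9), meta(0.5), seg)
        assert a.ccf == 1.0
        assert a.ccf_uncapped == pytest.approx(0.9 * 2 / 0.5)


class TestAssignCcfs:
    def test_vectorised_matches_scalar_path(self, small_cohort):
        sample = small_cohort.meta["sample"].iloc[0]
        sub = small_cohort.variants[small_cohort.variants["sample"] == sample].head(50)
        assigned = assign_ccfs(sub, small_cohort.meta, small_cohort.segments)
        purity = float(
            small_cohort.meta.set_index("sample").loc[sample, "purity"]
        )
        segs = small_cohort.segments[small_cohort.segments["sample"] == sample]
        for row, (_, arow) in zip(sub.itertuples(), assigned.iterrows()):
            seg_row = segs[segs["chrom"] == row.chrom].iloc[0]
            seg = CopyNumberSegment(
                seg_row["chrom"], int(seg_row["start"]), int(seg_row["end"]),
                int(seg_row["major_cn"]), int(seg_row["minor_cn"]),
            )
            v = VariantCall(
                patient=row.patient, sample=row.sample, timepoint=row.timepoint,
                chrom=row.chrom, pos=row.pos, ref=row.ref, alt=row.alt,
                t_ref_count=row.t_ref_count, t_alt_count=row.t_alt_count, vaf=row.vaf,
            )
            scalar = compute_ccf(v, meta(purity), seg)
            if scalar.inconsistent:
                assert arow["inconsistent"]
            else:
                assert arow["multiplicity"] == scalar.multiplicity
                assert arow["ccf"] == pytest.approx(scalar.ccf)

    def test_no_output_ccf_exceeds_one(self, small_cohort):
        assigned = assign_ccfs(
            small_cohort.variants, small_cohort.meta, small_cohort.segments
        )
        ok = assigned.loc[~assigned["inconsistent"], "ccf"]
        assert (ok <= 1.0).all() and (ok >= 0.0).all()


class TestClusterCcfs:
    def test_single_tight_cluster_recovered(self):
        rng = np.random.default_rng(1)
        df = make_assigned_frame(np.ones(100), depth=500, purity=1.0, rng=rng)
        clones = cluster_ccfs(df, seed=0)
        assert clones.n_clusters == 1
        assert clones.clusters[0][1] == pytest.approx(1.0, abs=0.02)

    def test_three_well_separated_clones_recovered(self):
        rng = np.random.default_rng(2)
        ccfs = np.repeat([0.2, 0.5, 1.0], 100)
        df = make_assigned_frame(ccfs, depth=500, purity=0.8, rng=rng)
        clones = cluster_ccfs(df, seed=0)
        assert clones.n_clusters == 3
        centres = sorted(c for _, c, _ in clones.clusters)
        for got, want in zip(centres, [0.2, 0.5, 1.0]):
            assert got == pytest.approx(want, abs=0.05)

    def test_component_cap_honoured(self):
        rng = np.random.default_rng(3)
        # 30 distinct CCF levels cannot yield more clusters than the cap
        ccfs = np.repeat(np.linspace(0.05, 1.0, 30), 20)
        df = make_assigned_frame(ccfs, depth=2000, purity=1.0, rng=rng)
        clones = cluster_ccfs(df, max_clones=15, seed=0)
        assert clones.n_clusters <= 15

    def test_identical_ccfs_collapse_to_single_cluster(self):
        df = make_assigned_frame(np.full(50, 0.6), depth=10**6, purity=1.0,
                                 rng=np.random.default_rng(4))
        df["t_alt_count"] = 300  # exactly identical counts
        df["t_ref_count"] = 700
        df["vaf"] = 0.3
        clones = cluster_ccfs(df, seed=0)
        assert clones.n_clusters == 1

    def test_mutation_fractions_sum_to_one(self):
        rng = np.random.default_rng(5)
        df = make_assigned_frame(rng.uniform(0.1, 1.0, 150), depth=100, purity=0.6, rng=rng)
        clones = cluster_ccfs(df, seed=0)
        assert sum(f for _, _, f in clones.clusters) == pytest.approx(1.0)


class TestClonalityScore:
    def test_fully_clonal_scores_one(self):
        assert clonality_score(np.ones(40)) == 1.0

    def test_two_equal_clones(self):
        assert clonality_score([0.2] * 10 + [0.8] * 10) == pytest.approx(0.5)

    def test_clone_weighted_sum_equals_mean_ccf(self):
        rng = np.random.default_rng(7)
        ccf = rng.uniform(0, 1, 500)
        labels = rng.integers(0, 6, 500)
        assert clonality_score_by_clone(ccf, labels) == pytest.approx(
            clonality_score(ccf), abs=1e-12
        )

    def test_invariant_to_order_and_relabelling(self):
        rng = np.random.default_rng(8)
        ccf = rng.uniform(0, 1, 100)
        labels = rng.integers(0, 4, 100)
        perm = rng.permutation(100)
        relabel = {0: 9, 1: 3, 2: 7, 3: 1}
        assert clonality_score(ccf[perm]) == pytest.approx(clonality_score(ccf))
        assert clonality_score_by_clone(
            ccf[perm], [relabel[l] for l in labels[perm]]
        ) == pytest.approx(clonality_score_by_clone(ccf, labels))

    def test_empty_input_signalled(self):
        with pytest.raises(ValueError):
            clonality_score([])


class TestDeltaClonality:
    def _scores(self, rows):
        return pd.DataFrame(rows, columns=["patient", "timepoint", "score", "immune_group"])

    def test_identical_scores_give_zero_delta(self):
        scores = self._scores([("P1", "baseline", 0.5, "a"), ("P1", "recurrence", 0.5, "a")])
        deltas, _ = delta_clonality(scores)
        assert deltas["delta_clonality"].iloc[0] == 0.0

    def test_signed_difference(self):
        scores = self._scores([("P1", "baseline", 0.4, "a"), ("P1", "recurrence", 0.7, "a")])
        deltas, _ = delta_clonality(scores)
        assert deltas["delta_clonality"].iloc[0] == pytest.approx(0.3)

    def test_missing_timepoint_excluded_with_warning(self, caplog):
        scores = self._scores(
            [("P1", "baseline", 0.4, "a"), ("P1", "recurrence", 0.7, "a"),
             ("P2", "baseline", 0.2, "b")]
        )
        with caplog.at_level("WARNING", logger="clonevo.ccf"):
            deltas, _ = delta_clonality(scores)
        assert list(deltas["patient"]) == ["P1"]
        assert any("P2" in r.message for r in caplog.records)

    def test_group_test_matches_exact_enumeration_oracle(self):
        g1 = [0.31, 0.12, -0.05, 0.27, 0.08]
        g2 = [-0.21, -0.33, 0.02, -0.14, -0.40]
        rows = []
        for i, d in enumerate(g1):
            rows += [(f"A{i}", "baseline", 0.0, "grp1"), (f"A{i}", "recurrence", d, "grp1")]
        for i, d in enumerate(g2):
            rows += [(f"B{i}", "baseline", 0.0, "grp2"), (f"B{i}", "recurrence", d, "grp2")]
        _, test = delta_clonality(self._scores(rows))
        assert test["p_value"] == pytest.approx(exact_rank_sum_p(g1, g2), rel=1e-9)


class TestExpectedVaf:
    def test_closed_form(self):
        assert expected_vaf(1.0, 0.5, 1, 2, 2) == pytest.approx(0.25)
        assert expected_vaf(0.5, 1.0, 2, 4, 2) == pytest.approx(0.25)
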