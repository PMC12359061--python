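"""LoF classification, catalogue flags, Fisher and covariate tests."""

import numpy as np
import pandas as pd
import pytest

from clonevo.evasion import (
    covariate_association,
    fisher_group_comparison,
    flag_samples,
    is_lof,
    load_catalog,
)
from clonevo.stats import fisher_exact_2x2, rank_sum_test
from clonevo.types import EvasionCatalog

from .oracles import exact_fisher_p, exact_rank_sum_p


def calls(rows):
    return pd.DataFrame(
        rows, columns=["patient", "sample", "chrom", "pos", "ref", "alt",
                       "variant_classification", "gene_symbol"],
    )


class TestIsLof:
    @pytest.mark.parametrize(
        "cls,expected",
        [
            ("nonsense", True),
            ("frameshift_ins", True),
            ("frameshift_del", True),
            ("in_frame_indel", True),
            ("nonstop", True),
            ("missense", False),
            ("silent", False),
            ("splice", False),
        ],
    )
    def test_lof_classes(self, cls, expected):
        assert is_lof(cls) is expected

    def test_unknown_class_false_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert is_lof("weird_annotation") is False
        assert any("unknown" in r.message for r in caplog.records)


class TestFlagSamples:
    def test_packaged_catalog_contents(self):
        cat = load_catalog()
        assert "B2M" in cat and "TAP1" in cat
        assert cat.provenance["IRF2"] == "crispr_screen_hit"
        assert len(cat.gene_symbols) == 10

    def test_nonsense_in_catalog_gene_flags_sample(self):
        cat = load_catalog()
        flags = flag_samples(
            calls([("P1", "S1", "1", 10, "C", "T", "nonsense", "B2M")]), cat
        )
        assert flags["has_evasion_lof"].iloc[0]
        assert "B2M" in flags["supporting_variants"].iloc[0][0]

    def test_missense_in_catalog_gene_does_not_flag(self):
        cat = load_catalog()
        flags = flag_samples(
            calls([("P1", "S1", "1", 10, "C", "T", "missense", "TAP1")]), cat
        )
        assert not flags["has_evasion_lof"].iloc[0]

    def test_non_catalog_lof_never_changes_flags(self):
        cat = load_catalog()
        base = calls([("P1", "S1", "1", 10, "C", "T", "nonsense", "B2M"),
                      ("P1", "S2", "2", 20, "G", "A", "missense", "GENE1")])
        with_extra = pd.concat(
            [base, calls([("P1", "S2", "3", 30, "A", "G", "nonsense", "NOT_IN_CATALOG")])],
            ignore_index=True,
        )
        a = flag_samples(base, cat).set_index("sample")["has_evasion_lof"]
        b = flag_samples(with_extra, cat).set_index("sample")["has_evasion_lof"]
        assert a.equals(b)

    def test_patient_level_aggregation(self):
        cat = load_catalog()
        df = calls([("P1", "S1", "1", 10, "C", "T", "nonsense", "B2M"),
                    ("P1", "S2", "2", 20, "G", "A", "missense", "GENE1")])
        flags = flag_samples(df, cat, by="patient")
        assert list(flags.columns[:2]) == ["patient", "has_evasion_lof"]
        assert flags["has_evasion_lof"].iloc[0]

    def test_flags_match_simulation_truth_exactly(self, small_cohort):
        cat = load_catalog()
        flags = flag_samples(small_cohort.variants, cat).set_index("sample")
        truth, variants = small_cohort.truth, small_cohort.variants
        lof_keys = set(
            zip(truth.loc[truth["is_evasion_lof"], "chrom"],
                truth.loc[truth["is_evasion_lof"], "pos"])
        )
        for sample, sub in variants.groupby("sample"):
            observed_lof = any(
                (c, p) in lof_keys for c, p in zip(sub["chrom"], sub["pos"])
            )
            assert flags.loc[sample, "has_evasion_lof"] == observed_lof


class TestFisherComparison:
    def test_printed_cohort_table_matches_enumeration_oracle(self):
        """19/22 flagged vs 2/10: exact p and a finite OR."""
        table = [[19, 3], [2, 10]]
        res = fisher_exact_2x2(table)
        assert res["p_value"] == pytest.approx(exact_fisher_p(table), rel=1e-9)
        assert res["p_value"] < 0.001
        assert res["odds_ratio"] > 1

    def test_identical_proportions_give_or_one(self):
        res = fisher_exact_2x2([[5, 5], [5, 5]])
        assert res["odds_ratio"] == pytest.approx(1.0)
        assert res["p_value"] == pytest.approx(1.0)

    def test_extreme_table_matches_oracle_with_finite_or(self):
        table = [[10, 0], [0, 10]]
        res = fisher_exact_2x2(table)
        assert res["p_value"] == pytest.approx(exact_fisher_p(table), rel=1e-9)
        assert np.isfinite(res["odds_ratio"])

    def test_all_small_tables_match_enumeration_oracle(self):
        """Every 2x2 table with total n <= 12 and both rows non-empty."""
        for n in range(2, 13):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        if a + b == 0 or c + d == 0:
                            continue
                        table = [[a, b], [c, d]]
                        assert fisher_exact_2x2(table)["p_value"] == pytest.approx(
                            exact_fisher_p(table), rel=1e-8
                        ), table

    def test_group_comparison_from_flags(self):
        flags = pd.DataFrame(
            {"sample": [f"S{i}" for i in range(6)],
             "has_evasion_lof": [True, True, True, False, False, False]}
        )
        groups = {f"S{i}": ("g1" if i < 3 else "g2") for i in range(6)}
        res = fisher_group_comparison(flags, groups)
        assert res["table"] == [[3, 0], [0, 3]]

    def test_empty_group_named_in_error(self):
        flags = pd.DataFrame({"sample": ["S1"], "has_evasion_lof": [True]})
        with pytest.raises(ValueError):
            fisher_group_comparison(flags, {"S1": "only_group"})


class TestCovariateAssociation:
    def test_identical_distributions_not_significant(self):
        flags = pd.DataFrame(
            {"sample": list("abcdef"), "has_evasion_lof": [True] * 3 + [False] * 3}
        )
        cov = dict(zip("abcdef", [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]))
        res = covariate_association(flags, cov)
        assert res["p_value"] == pytest.approx(1.0)

    def test_toy_vectors_match_exact_enumeration_oracle(self):
        res = rank_sum_test([5, 6, 7], [1, 2, 3])
        assert res["p_value"] == pytest.approx(exact_rank_sum_p([5, 6, 7], [1, 2, 3]), rel=1e-9)

    def test_rejection_rate_rises_with_shift(self):
        """Power grows monotonically as the flagged group's covariate shifts."""
        rng = np.random.default_rng(5)
        n = 12
        flags = pd.DataFrame(
            {"sample": [f"S{i}" for i in range(2 * n)],
             "has_evasion_lof": [True] * n + [False] * n}
        )
        rates = []
        for shift in (0.0, 1.0, 2.5):
            rej = 0
            for _ in range(100):
                cov = {
                    f"S{i}": rng.normal(shift if i < n else 0.0, 1.0)
                    for i in range(2 * n)
                }
                rej += covariate_association(flags, cov)["p_value"] < 0.05
            rates.append(rej / 100)
        assert rates[0] < rates[1] < rates[2]
        assert rates[2] > 0.9
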