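#!/usr/bin/env python
"""Flag tumours carrying loss-of-function mutations in immune-evasion
catalogue genes, compare flag proportions between immune groups (Fisher),
and test association with mutational burden (rank-sum)."""

import json

import pandas as pd

from clonevo.cohort import Cohort
from clonevo.evasion import (
    covariate_association,
    fisher_group_comparison,
    flag_samples,
    load_catalog,
)

cohort = Cohort.read("results/cohort")
filtered = pd.read_csv("results/variants_filtered.tsv", sep="\t", dtype={"chrom": str})

catalog = load_catalog()
flags = flag_samples(filtered, catalog, by="sample")
groups = cohort.meta.set_index("sample")["immune_group"]
fisher = fisher_group_comparison(flags, groups)
tmb = filtered.groupby("sample").size()
assoc = covariate_association(flags, tmb)

out = flags.copy()
out["supporting_variants"] = out["supporting_variants"].map(";".join)
out.to_csv("results/evasion_flags.tsv", sep="\t", index=False)
with open("results/evasion_tests.json", "w") as fh:
    json.dump({"fisher": fisher, "tmb_association": assoc}, fh, indent=2)

n_flagged = int(flags["has_evasion_lof"].sum())
print(f"catalogue: {len(catalog.gene_symbols)} genes "
      f"(antigen presentation + CD8-killing-resistance screen hits)")
print(f"{n_flagged}/{len(flags)} samples carry an evasion LoF mutation")
(g1, g2), ((a, b), (c, d)) = fisher["groups"], fisher["table"]
print(f"{g1}: {a}/{a + b} flagged vs {g2}: {c}/{c + d}; "
      f"Fisher p = {fisher['p_value']:.3g}, OR = {fisher['odds_ratio']:.2f}")
print(f"mutational burden, flagged vs not: rank-sum p = {assoc['p_value']:.3g}")
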