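#!/usr/bin/env python
"""Simulate the study cohort: 15 patients, paired baseline/recurrence FFPE
exomes at 100X with known clonal truth, and write its tables under
results/cohort/."""

from pathlib import Path

from clonevo.simulate import SimulationConfig, simulate_cohort

OUT = Path("results/cohort")

cfg = SimulationConfig(seed=1)
cohort = simulate_cohort(cfg)
cohort.write(OUT)

truth = cohort.truth
print(f"simulated {cfg.n_patients} patients, {len(cohort.meta)} samples")
print(f"observed calls: {len(cohort.variants)}")
print(f"truth mutations: {len(truth)} "
      f"({int(truth['is_artifact'].sum())} FFPE artefacts, "
      f"{int(truth['is_neoantigen'].sum())} neoantigens, "
      f"{int(truth['is_evasion_lof'].sum())} evasion LoF)")
print(f"immune groups: {cohort.meta.groupby('immune_group')['patient'].nunique().to_dict()}")
print(f"tables written to {OUT}/")
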