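# clonevo

Clonal evolution analysis for paired baseline/recurrence tumour exomes,
built around the question of whether immune pressure (e.g. transplant
immunosuppression vs an intact immune system) reshapes how hepatocellular
carcinomas evolve to recurrence. Because cohorts of this kind are small,
FFPE-archived and access-restricted, the package ships a synthetic cohort
generator with known clonal truth so every stage is testable end to end.

## What it computes

- **FFPE-aware filtering.** Formalin fixation produces spurious low-VAF
  C>T/G>A calls. The dual filter removes signature-class calls first, then
  every call with VAF strictly below 10% (configurable), and reports
  per-sample retention.
- **CCF estimation.** With purity *p*, tumour total copy number *CN_t*,
  normal copy number *CN_n* and multiplicity *m*, a mutation at cancer cell
  fraction CCF has expected VAF
  `E[VAF] = m·p·CCF / (p·CN_t + (1−p)·CN_n)`.
  *m* is chosen from {1..major_cn} by closeness of the clonal (CCF = 1)
  expectation to the observed VAF; the CCF estimate inverts the formula and
  is capped at 1 (uncapped value kept as a purity/CN diagnostic).
- **Clone clustering.** A seeded EM binomial mixture over alt read counts
  with BIC model selection, capped at 15 subclones.
- **Clonality score.** The sum over clones of (fraction of mutations in the
  clone) × (clone CCF), which reduces to the mutation-level mean CCF:
  1 = entirely clonal, → 0 = entirely subclonal. Per-patient deltas
  (recurrence − baseline) are compared between immune groups by Wilcoxon's
  rank-sum test.
- **Divergence vs an unmatched null.** Mutations (keyed by
  chrom/pos/ref/alt) are private or public across timepoints; percent
  public is `100·|A∩B|/|A∪B|`. To show divergence is not a filtering
  artefact, matched overlaps `100·|A∩B|/|A|` are tested against the
  distribution over all ordered unmatched profile pairs (N² values with
  self-pairs, N·(N−1) without).
- **Neoantigen delta-CCF dynamics.** Candidate neoantigens (affinity
  ≤ 100 nM strong, ≤ 500 nM weak, or a stringent boolean call) are compared
  with control mutations on delta-CCF = CCF_recurrence − CCF_baseline
  (absent → 0), per patient and pooled on patient-centred deltas. Depletion
  of neoantigen deltas is the immunoediting signature.
- **Immune-evasion LoF.** Samples carrying a nonsense / frameshift / other
  indel / nonstop mutation in a catalogue of antigen-presentation and
  CD8-killing-resistance genes are flagged; proportions compared by
  Fisher's exact test, immune covariates by rank-sum.
- **Promoter methylation.** EPIC-style probes in TSS200/TSS1500/1stExon are
  summarised per gene (mean and median beta) and shifts compared between
  neoantigen-bearing and other genes.

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
15-patient cohort (paired 100X FFPE exomes, ~20 artefacts per sample, 15%
neoantigens, no immunoediting):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_filter_variants.py
python analysis/04_divergence.py
```

which prints (abridged):

```
simulated 15 patients, 30 samples
observed calls: 6639
truth mutations: 6057 (640 FFPE artefacts, 781 neoantigens, 29 evasion LoF)

6639 calls in, 4465 retained
retention rate: mean 0.667, range 0.294-0.919
truth-artefact recall: 0.872

percent public: median 15.5% (range 11.4-33.3%) — most mutations are private to one timepoint
matched overlap: median 26.6% over 15 pairs
unmatched null: median 0.00% over 210 pairs
matched vs null: p = 1.56e-50 (matched significantly higher — divergence is not a filtering artefact)
```

The filter keeps two-thirds of calls while catching 87% of injected
artefacts; matched pairs still share far more mutations than unrelated
ones, so the observed divergence is real rather than an artefact of the
stringent filtering. Scripts 03 and 05–07 add clonality scores, neoantigen
dynamics, evasion flags and methylation shifts; on this unedited cohort
the neoantigen and methylation tests correctly find nothing, while a
positive-control cohort simulated with selection s = 0.5 yields depletion
p ≈ 1e-25.

The same stages are available as one orchestrated command with a manifest
and versioned output directories:

```bash
clonevo all --seed 1 --out results/pipeline
```

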