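# Methods

## The read model and CCF estimation

A somatic mutation present in a fraction CCF of tumour cells, at
multiplicity *m* (mutant copies per carrying cell), in a segment of tumour
total copy number CN_t and normal copy number CN_n, sequenced from a
specimen of purity *p*, has expected variant allele frequency

    E[VAF] = m · p · CCF / (p · CN_t + (1 − p) · CN_n).

Estimation inverts this: multiplicity is chosen from {1, …, major_cn} as
the value whose clonal (CCF = 1) expectation lies closest to the observed
VAF, ties broken toward the smaller (more conservative) *m*; then
CCF = VAF · (p·CN_t + (1−p)·CN_n) / (p·m), capped at 1. The uncapped value
is retained because CCF > 1 indicates purity or copy-number inconsistency
rather than biology. Variants with no covering segment are treated as
diploid (CN_t = CN_n, m = 1); homozygous-deletion segments (major_cn = 0)
make the call inconsistent and exclude it from clustering. Variant-segment
joining is by 1-based inclusive containment.

## Clone clustering

Clusters of mutations sharing a CCF are fitted as a binomial mixture over
alt read counts: component *c* has a clone CCF φ_c, and mutation *i*'s
success probability is φ_c · r_i where r_i = m_i·p / (p·CN_t,i + (1−p)·CN_n,i)
maps a CCF to that mutation's expected VAF. The fit is EM with components
initialised at quantiles of the per-mutation CCF estimates (plus tiny
seeded jitter to break exact ties), and the component count is selected by
BIC over 1..15 components — the cap mirrors the subclone limit used by
variational PyClone-style clustering, which this deliberately simple,
seeded stand-in replaces: the downstream statistics need CCF clusters, not
the full Bayesian machinery. Two numerical choices: the M-step updates
φ_c = Σγ·alt / Σγ·depth·r (the exact stationary point when r is constant
within a sample, a quasi-EM update otherwise), and the BIC sweep stops
after two consecutive worsening component counts, since the criterion is
effectively unimodal in k here and larger models only overfit. Components
that end up owning no mutation under hard assignment are dropped and
clusters renumbered by CCF.

Mutation ordering, phylogeny and timing are out of scope: without
multi-region data the clones are modelled as flat CCF clusters only.

## Clonality score

The score is Σ_c f_c · CCF_c over clones, with f_c the fraction of
mutations in clone c — algebraically the mutation-level mean CCF, which is
how it is computed (so it does not depend on the clustering). It is 1 for
a fully clonal tumour and tends to 0 as the mutanome becomes subclonal.
"Frequency" weighting could alternatively be read as VAF weighting; the
clone-fraction reading is used because it is the one that yields the
stated [0, 1] range with the stated extremes. Per-patient deltas
(recurrence − baseline) are compared between immune groups with a
two-sided tie-corrected Wilcoxon rank-sum test.

## Divergence and the unmatched null

Mutation identity is (chrom, pos, ref, alt); gene annotation is ignored.
Percent public uses the union denominator (symmetric); the overlap used
for the null, 100·|A∩B|/|A|, uses the first profile's size so that ordered
pairs are meaningful. `build_unmatched_null` enumerates all ordered pairs —
N² values when self-pairs are included, which is the convention that
reproduces a 360-profile null of exactly 129,600 values; a flag excludes
self-pairs for a more conservative null. For matched-vs-unmatched testing
inside one cohort the pipeline uses the cross-timepoint null
(baseline_i vs recurrence_j, i ≠ j), since self-pairs would place the
matched statistic inside its own null distribution.

## Neoantigen dynamics

Binding-affinity tiers are inclusive: ≤ 100 nM strong, ≤ 500 nM weak,
> 500 nM non-binder; missing affinity is unknown, non-positive affinities
are rejected. Delta-CCF is recurrence − baseline per mutation over the
union of timepoints with absent mutations contributing 0 (private
mutations dominate these cohorts, so intersection mode — also provided —
would discard most of the signal). The group comparison runs per patient
(two-sided rank-sum, neoantigen vs control) and pooled; the default
pooling subtracts each patient's mean delta before pooling into one
rank-sum test, which removes patient-level offsets while leaving the
within-patient label assignment exchangeable under the null (Fisher's
combined per-patient p is the alternative). The pooled result reports both
the two-sided p and the one-sided depletion p, depletion being the
immunoediting signature.

## Immune evasion

Loss of function means nonsense, frameshift (ins/del), other (in-frame)
indel, or nonstop — missense is excluded as functionally ambiguous, and
"other indels" maps to the in-frame indel class of MAF conventions. The
packaged catalogue is a small editable seed list of antigen-presentation
genes (HLA-DRA, HLA-DQA, HLA-DQB, CIITA, B2M, TAP1) and CD8-killing-
resistance screen hits (IRF2, IRF8, JAK2, PRKCD); it does not claim to
reproduce any full pathway-database release, which is version-dependent.
Flags aggregate per sample by default, per patient optionally. Proportions
are compared by Fisher's exact test (odds ratio with Haldane-Anscombe 0.5
correction when a cell is zero); covariates by rank-sum.

## Promoter methylation

Only probes annotated TSS200, TSS1500 or 1stExon enter the per-gene
summaries; both mean and median beta are always emitted (mean is treated
as primary). Probes mapping to several genes contribute to each. A gene
counts as neoantigen-bearing for a patient if it carries any
stringent-pass neoantigen there. Shifts (recurrence − baseline) are
compared between neoantigen-bearing and other genes overall and within
immune groups.

## The synthetic cohort generator

The generator emulates the study conditions: 15 patients (two thirds
immunocompromised), paired baseline/recurrence FFPE exomes at a mean
tumour depth of 100 reads (normal coverage of 50 is recorded as a study
condition but does not enter the model — germline reads are not
simulated), purity uniform on (0.3, 0.9), 100-300 mutations per sample in
3-6 clones. A configurable fraction of mutations (default 0.2, reflecting
that the bulk of mutations in such cohorts are private; the divergence
acceptance study uses 0.3) is truncal/shared, the rest truly absent
(CCF 0) at the other timepoint — an optional detection-limit censoring
toggle exists but is off by default. Copy number is one segment per
chromosome drawn from common allele-specific states; multiplicity is
uniform on {1..major_cn}. Reads are drawn alt ~ Binomial(depth, E[VAF])
with depth ~ Poisson(100) floored at 10; a mutation is "called" only if at
least one alt read is drawn. FFPE artefacts are Poisson(20) per sample,
C>T/G>A, true VAF ~ Beta(1.5, 30) (mean ≈ 0.05), forced to carry at least
one supporting read (a caller would not emit a zero-read variant — this
also keeps the injected count exactly Poisson). Neoantigen labels are
Bernoulli(0.15) with affinities drawn log-uniform below 500 nM (binders)
or above (non-binders); immunoediting multiplies neoantigen recurrence
CCFs by (1 − s) and re-draws the recurrence reads, s = 0 being the
escape null. About one immune-evasion LoF mutation per sample is planted
in a catalogue gene. Promoter methylation is a per-gene baseline level
plus probe offsets and Gaussian noise clipped to [0, 1], with an optional
neoantigen-specific recurrence shift for power studies.

What the generator does **not** emulate: read-level errors and mapping
(no FASTQ/BAM), trinucleotide signature spectra, germline variation,
segment-level CCF correlation, clonal phylogenies, or inter-mutation LD
within clones beyond shared CCFs. Passing tests therefore demonstrate the
statistical machinery's correctness and calibration under the stated
generative model, not performance on real FFPE exomes.

## Numerical and degenerate-input conventions

The VAF filter boundary is strict ("below 10%" removes VAF < 0.10
exactly); the signature filter runs first and claims its removals. Empty
inputs are signalled (retention rate on zero input, clonality on no
mutations, overlap on an empty first profile); all-tied rank-sum inputs
report p = 1 with a warning. Multi-allelic VCF records are split per
allele before filtering; VAF is always recomputed from read counts when
both are present. All randomness flows from explicit seeds; identical
config + seed reproduces byte-identical tables.

## Problem sizes used in validation

The replicate studies use the default 15-patient cohorts: 500 replicates
for the immunoediting null calibration, 200 for power at s = 0.5, 100 for
the divergence direction at 30% trunk sharing; the unmatched-null
enumeration check simulates 180 patients (360 profiles); clone recovery
uses 300 mutations at depth 500 over 20 seeds. These sizes keep each
study's Monte Carlo error well below the margins being asserted.

## Known limitations

Multiplicity is estimated per mutation without uncertainty; CCF capping
biases fully clonal mutations slightly below 1 in noisy data. The EM
stand-in does not share statistical strength across samples or model
overdispersion. The pooled dynamics test treats mutations as independent
within patients, ignoring clone co-membership, which can make its
effective sample size optimistic on strongly clustered mutanomes — the
per-patient results are reported alongside for that reason.
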