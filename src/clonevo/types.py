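"""Shared domain types.

Tabular data (mutation tables, segments, truth labels) moves through the
package as pandas DataFrames with documented column contracts; the small
dataclasses here give names and invariants to the records those tables hold
and to the scalar results the statistics return.
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: Functional classes treated as loss-of-function: nonsense, frameshifts,
#: other (in-frame) indels, and nonstop mutations.
LOF_CLASSES = frozenset(
    {"nonsense", "frameshift_ins", "frameshift_del", "in_frame_indel", "nonstop"}
)

VARIANT_CLASSES = (
    "missense",
    "nonsense",
    "frameshift_ins",
    "frameshift_del",
    "in_frame_indel",
    "nonstop",
    "silent",
    "splice",
    "other",
)

TIMEPOINTS = ("baseline", "recurrence", "recurrence2", "recurrence3")


@dataclass(frozen=True)
class VariantCall:
    """One somatic mutation call in one sample."""

    patient: str
    sample: str
    timepoint: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    t_ref_count: int
    t_alt_count: int
    vaf: float
    variant_classification: str = "missense"
    gene_symbol: str = ""
    filter_flags: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf must lie in [0, 1], got {self.vaf}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class CopyNumberSegment:
    """Allele-specific absolute copy number over a 1-based inclusive interval."""

    chrom: str
    start: int
    end: int
    major_cn: int
    minor_cn: int
    normal_cn: int = 2  # 1 for male sex chromosomes

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"start > end ({self.start} > {self.end})")
        if self.major_cn < self.minor_cn:
            raise ValueError("major_cn must be >= minor_cn")
        if self.minor_cn < 0:
            raise ValueError("copy numbers must be non-negative")

    @property
    def total_cn(self) -> int:
        return self.major_cn + self.minor_cn

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass(frozen=True)
class SampleMeta:
    """Purity, ploidy and grouping metadata for one sequenced sample."""

    sample: str
    patient: str
    timepoint: str
    purity: float
    ploidy: float = 2.0
    immune_group: str = "immunocompetent"

    def __post_init__(self):
        if not 0.0 < self.purity <= 1.0:
            raise ValueError(f"purity must lie in (0, 1], got {self.purity}")
        if self.ploidy <= 0:
            raise ValueError("ploidy must be positive")


@dataclass
class CCFAssignment:
    """Cancer cell fraction and multiplicity estimate for one mutation."""

    key: tuple[str, int, str, str]
    multiplicity: int
    ccf: float  # capped at 1
    ccf_uncapped: float
    clone_id: int | None = None
    inconsistent: bool = False  # e.g. homozygous-deletion segment


@dataclass
class CloneSet:
    """Clusters of mutations sharing a cancer cell fraction.

    ``clusters`` holds ``(clone_id, ccf_centre, mutation_fraction)`` triples;
    ``labels`` maps each input mutation (by position in the input order) to
    its maximum-responsibility cluster.
    """

    clusters: list[tuple[int, float, float]]
    labels: list[int]
    bic: float = float("nan")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def __post_init__(self):
        if self.clusters:
            total = sum(f for _, _, f in self.clusters)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"mutation fractions must sum to 1, got {total}")


@dataclass
class FilterReport:
    """Bookkeeping for the artefact-filtering stage."""

    n_input: int
    n_removed_signature: int
    n_removed_vaf: int
    n_retained: int

    def __post_init__(self):
        if self.n_input != self.n_retained + self.n_removed_signature + self.n_removed_vaf:
            raise ValueError("filter report counts do not reconcile")

    @property
    def retention_rate(self) -> float:
        if self.n_input == 0:
            raise ZeroDivisionError("retention rate undefined for empty input")
        return self.n_retained / self.n_input

    def to_dict(self) -> dict:
        d = {
            "n_input": self.n_input,
            "n_removed_signature": self.n_removed_signature,
            "n_removed_vaf": self.n_removed_vaf,
            "n_retained": self.n_retained,
        }
        d["retention_rate"] = self.retention_rate if self.n_input else float("nan")
        return d


@dataclass
class OverlapNull:
    """Null distribution of overlap percentages from unmatched profile pairs."""

    values: list[float]
    n_profiles: int
    includes_self_pairs: bool

    @property
    def n_pairs(self) -> int:
        return len(self.values)

    def __post_init__(self):
        n = self.n_profiles
        expected = n * n if self.includes_self_pairs else n * (n - 1)
        if len(self.values) != expected:
            raise ValueError(
                f"expected {expected} ordered pairs for {n} profiles, got {len(self.values)}"
            )
        if any(v < 0 or v > 100 for v in self.values):
            raise ValueError("overlap percentages must lie in [0, 100]")


@dataclass
class EvasionCatalog:
    """Immune-evasion gene catalogue with per-gene provenance.

    Provenance is one of ``antigen_presentation_kegg``, ``crispr_screen_hit``
    or ``both`` — antigen-presentation pathway membership versus a
    loss-of-function hit conferring resistance to CD8 T-cell killing in
    CRISPR screens.
    """

    provenance: dict[str, str]

    def __post_init__(self):
        if not self.provenance:
            raise ValueError("catalogue must be non-empty")
        self.provenance = {g.upper(): p for g, p in self.provenance.items()}

    @property
    def gene_symbols(self) -> frozenset:
        return frozenset(self.provenance)

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.provenance
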