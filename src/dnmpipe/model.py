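"""Shared data model for the trio de novo mutation (DNM) pipeline.

A *trio* is a sequenced father-mother-child unit. DNMs appear as Mendelian
violations: both parents homozygous reference, child heterozygous for an
alternate allele. Every downstream quantity (callability, per-generation
rate, parental-age regression, spectrum) is defined on top of the types here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

MUTATION_CLASSES = ("A>C", "A>G", "A>T", "C>A", "C>G", "C>T")

#: filters applied to a candidate DNM, in reporting order (evaluation is
#: order-independent; all verdicts are always filled)
FILTER_NAMES = (
    "depth",
    "genotype_quality",
    "both_strands",
    "parent_alt_reads",
    "nondescendant_absence",
    "allelic_balance",
)


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees."""


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's evidence at one site.

    ``gt`` is one of ``hom_ref``, ``het``, ``hom_alt``, ``missing``. Depth
    and quality fields may be None when the VCF omits them; a missing value
    is never coerced to zero.
    """

    __slots__ = ("gt", "dp", "gq", "ad_ref", "ad_alt", "adf", "adr")
    gt: str
    dp: Optional[int]
    gq: Optional[int]
    ad_ref: Optional[int]
    ad_alt: Optional[int]
    adf: Optional[int]
    adr: Optional[int]

    @property
    def allelic_balance(self) -> Optional[float]:
        if self.ad_ref is None or self.ad_alt is None:
            return None
        tot = self.ad_ref + self.ad_alt
        return self.ad_alt / tot if tot > 0 else None


@dataclass
class SiteGenotypes:
    """A biallelic SNV site with per-sample genotype evidence (1-based pos)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    calls: dict[str, GenotypeCall]

    def call(self, sample: str) -> GenotypeCall:
        return self.calls[sample]


@dataclass
class Pedigree:
    """A validated pedigree with per-child parental ages at conception.

    ``parent_map`` maps child -> (father, mother); founders are absent from
    the map. ``ages`` maps child -> (paternal_age, maternal_age) in years;
    either entry may be None (unknown age). Ages are attached to the child:
    they are each parent's age at that child's conception.
    """

    individuals: list[str]
    parent_map: dict[str, tuple[str, str]]
    ages: dict[str, tuple[Optional[float], Optional[float]]] = field(default_factory=dict)
    sex: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        known = set(self.individuals)
        seen_children = set()
        for child, (father, mother) in self.parent_map.items():
            if child in seen_children:
                raise PedigreeError(f"duplicated proband {child!r}")
            seen_children.add(child)
            for parent in (father, mother):
                if parent not in known:
                    raise PedigreeError(
                        f"parent {parent!r} of {child!r} is not in the pedigree"
                    )
        # acyclicity: DFS from each node through parent links
        state: dict[str, int] = {}

        def visit(node: str) -> None:
            state[node] = 1
            for parent in self.parent_map.get(node, ()):
                if state.get(parent) == 1:
                    raise PedigreeError(f"pedigree cycle involving {parent!r}")
                if state.get(parent, 0) == 0:
                    visit(parent)
            state[node] = 2

        for ind in self.individuals:
            if state.get(ind, 0) == 0:
                visit(ind)
        for child, (fa, ma) in self.ages.items():
            for a in (fa, ma):
                if a is not None and not (a > 0 and a == a and a != float("inf")):
                    raise PedigreeError(f"age for {child!r} must be finite and > 0")

    @property
    def founders(self) -> set[str]:
        return set(self.individuals) - set(self.parent_map)

    def children_of(self, individual: str) -> list[str]:
        return [c for c, (f, m) in self.parent_map.items() if individual in (f, m)]

    def descendants_of_couple(self, father: str, mother: str) -> set[str]:
        """Transitive closure of descent from the couple (children, their
        children, ...)."""
        out: set[str] = set()
        frontier = [
            c for c, (f, m) in self.parent_map.items() if (f, m) == (father, mother)
        ]
        while frontier:
            node = frontier.pop()
            if node in out:
                continue
            out.add(node)
            frontier.extend(self.children_of(node))
        return out

    def descendant_sets(self) -> dict[tuple[str, str], set[str]]:
        couples = {pm for pm in self.parent_map.values()}
        return {cp: self.descendants_of_couple(*cp) for cp in couples}

    def trios(self) -> list[tuple[str, str, str]]:
        """(proband, father, mother) for every child with both parents."""
        return [(c, f, m) for c, (f, m) in sorted(self.parent_map.items())]


@dataclass
class TrioCallability:
    """Per-member probabilities that a true DNM site survives the filters.

    The trio callability ``C`` multiplies the three member probabilities,
    assuming the three genotype calls are disturbed independently:
    C = C_child * C_father * C_mother.
    """

    c_child: float
    c_father: float
    c_mother: float
    n_pass_child: int = 0
    n_informative_child: int = 0
    n_pass_father: int = 0
    n_informative_father: int = 0
    n_pass_mother: int = 0
    n_informative_mother: int = 0

    def __post_init__(self) -> None:
        for name in ("child", "father", "mother"):
            c = getattr(self, f"c_{name}")
            if not (0.0 < c <= 1.0):
                raise ValueError(f"c_{name}={c} outside (0, 1]")
            n_pass = getattr(self, f"n_pass_{name}")
            n_info = getattr(self, f"n_informative_{name}")
            if n_pass > n_info:
                raise ValueError(f"n_pass_{name} > n_informative_{name}")

    @property
    def C(self) -> float:
        return self.c_child * self.c_father * self.c_mother


@dataclass
class TrioRecord:
    """One proband with parents, conception ages, and callable-genome
    accounting.

    ``haploid_span_bp`` is the post-coverage-filter haploid genome span G;
    the diploid callable site total is 2 * C * G and the per-trio rate is
    n_mutations / (2 * C * G).
    """

    proband: str
    father: str = ""
    mother: str = ""
    paternal_age: Optional[float] = None
    maternal_age: Optional[float] = None
    n_mutations: int = 0
    callability: Optional[TrioCallability] = None
    haploid_span_bp: int = 0
    mean_depth: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_mutations < 0:
            raise ValueError("n_mutations must be >= 0")

    @property
    def callable_diploid_sites(self) -> float:
        if self.callability is None or self.haploid_span_bp <= 0:
            raise ValueError(f"trio {self.proband}: callability/span not set")
        return 2.0 * self.callability.C * self.haploid_span_bp

    @property
    def rate(self) -> float:
        return self.n_mutations / self.callable_diploid_sites


@dataclass
class FilterConfig:
    """Thresholds for the stringent DNM filters.

    Depth bounds are inclusive; GQ and allelic-balance thresholds are strict
    (``>``). Allelic balance is alt/(ref+alt) from AD.
    """

    depth_min: int = 20
    depth_max: int = 60
    gq_min: int = 70
    require_both_strands: bool = True
    parent_alt_reads_max: int = 0
    allelic_balance_min: float = 0.35
    check_nondescendants: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.depth_min < self.depth_max):
            raise ValueError("require 0 < depth_min < depth_max")
        if not (0.0 <= self.allelic_balance_min < 1.0):
            raise ValueError("allelic_balance_min must be in [0, 1)")
        if self.gq_min < 0:
            raise ValueError("gq_min must be >= 0")


@dataclass
class CandidateMutation:
    """A site-level DNM candidate with genotype evidence and filter verdicts.

    ``status`` is ``high_confidence`` iff every verdict is ``pass``;
    a single ``fail`` (or ``unevaluable``) verdict makes it ``rejected``.
    """

    trio: str
    chrom: str
    pos: int
    ref: str
    alt: str
    child_call: GenotypeCall
    father_call: GenotypeCall
    mother_call: GenotypeCall
    nondescendant_carriers: int = 0
    filter_verdicts: dict[str, str] = field(default_factory=dict)
    status: str = "candidate"
    cpg_flag: Optional[bool] = None

    @property
    def mutation_class(self) -> str:
        from .discovery import classify_mutation

        return classify_mutation(self.ref, self.alt)

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.trio, self.chrom, self.pos)


@dataclass
class RateEstimate:
    """A per-bp mutation rate with its Poisson confidence interval."""

    rate_per_bp_per_gen: float
    ci_low: float
    ci_high: float
    n_mutations_total: int
    callable_diploid_sites: float
    rate_per_bp_per_year: Optional[float] = None
    mean_parental_age: Optional[float] = None
    pooled_rate: Optional[float] = None
    pooled_ci: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if not (0 <= self.ci_low <= self.rate_per_bp_per_gen <= self.ci_high):
            raise ValueError("require 0 <= ci_low <= rate <= ci_high")


@dataclass(frozen=True)
class PhaseAssignment:
    """Parent-of-origin call for one DNM.

    ``source`` records the evidence route: third-generation transmission,
    external read-based phasing, or the merge of both.
    """

    trio: str
    chrom: str
    pos: int
    source: str  # transmission | read_based | combined
    parent: str  # paternal | maternal | undetermined
    n_informative_sites: int = 0
    conflict_flag: bool = False
    reason: str = ""

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.trio, self.chrom, self.pos)


@dataclass
class LongevityConfig:
    """Puberty ages used to align species on post-puberty elapsed time."""

    puberty_age_target: float = 0.5   # cat
    puberty_age_reference: float = 13.0  # human

    def __post_init__(self) -> None:
        if self.puberty_age_target <= 0 or self.puberty_age_reference <= 0:
            raise ValueError("puberty ages must be > 0")
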