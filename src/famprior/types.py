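"""Core data model for family-based exome variant prioritization.

The pipeline moves three kinds of objects around:

* a :class:`Pedigree` describing one nuclear or extended family (who is
  affected, who is whose parent),
* :class:`VariantRecord` objects — one normalized biallelic site with a
  per-sample :class:`GenotypeCall` and an :class:`AnnotationBundle` of
  population frequencies, in-silico predictor calls and a phred-scaled
  deleteriousness (CADD-style) score,
* a :class:`CandidateReport` of surviving variants, each carrying the
  full trace of every filter decision made on its way through.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


class Genotype(enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    @property
    def is_carrier(self) -> bool:
        """Carries at least one copy of the alternate allele."""
        return self in (Genotype.HET, Genotype.HOM_ALT)


class Consequence(enum.Enum):
    MISSENSE = "missense"
    STOP_GAIN = "stop_gain"
    SYNONYMOUS = "synonymous"
    OTHER = "other"
    UNKNOWN = "unknown"


class PredictorCall(enum.Enum):
    DAMAGING = "damaging"
    TOLERATED = "tolerated"
    UNKNOWN = "unknown"


class PedigreeError(ValueError):
    """Malformed pedigree: duplicate ids, dangling parents, or cycles."""


@dataclass(frozen=True)
class Individual:
    id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    sex: Sex
    affected: Affection


@dataclass
class Pedigree:
    """One family. Parental links are within-family; ``None`` means founder."""

    family_id: str
    individuals: list[Individual]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [ind.id for ind in self.individuals]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PedigreeError(
                f"family {self.family_id!r}: duplicate individual id(s) {dupes}"
            )
        known = set(ids)
        for ind in self.individuals:
            for parent in (ind.father_id, ind.mother_id):
                if parent is not None and parent not in known:
                    raise PedigreeError(
                        f"family {self.family_id!r}: individual {ind.id!r} "
                        f"references parent {parent!r} not in the family"
                    )
        # cycle check: walk up from every member; the ancestor chain must
        # terminate (an individual can never be its own ancestor)
        by_id = {ind.id: ind for ind in self.individuals}
        for start in ids:
            seen: set[str] = set()
            stack = [start]
            while stack:
                cur = stack.pop()
                if cur in seen:
                    raise PedigreeError(
                        f"family {self.family_id!r}: pedigree cycle involving "
                        f"{start!r}"
                    )
                seen.add(cur)
                ind = by_id[cur]
                stack.extend(
                    p for p in (ind.father_id, ind.mother_id) if p is not None
                )

    def __len__(self) -> int:
        return len(self.individuals)

    @property
    def members(self) -> dict[str, Individual]:
        return {ind.id: ind for ind in self.individuals}

    @property
    def sample_ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def affected_members(self) -> list[Individual]:
        return [i for i in self.individuals if i.affected is Affection.AFFECTED]

    def unaffected_members(self) -> list[Individual]:
        return [i for i in self.individuals if i.affected is Affection.UNAFFECTED]


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's call at one site.

    ``alt_fraction`` is alternate reads over total reads (allele balance);
    it is ``None`` when read counts are unavailable. A ``MISSING`` genotype
    may leave depth/GQ/alt_fraction unset.
    """

    sample_id: str
    gt: Genotype
    depth: Optional[int] = None
    gq: Optional[int] = None
    alt_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.alt_fraction is not None and not (0.0 <= self.alt_fraction <= 1.0):
            raise ValueError(f"alt_fraction {self.alt_fraction} outside [0, 1]")
        if self.depth is not None and self.depth < 0:
            raise ValueError("negative depth")
        if self.gq is not None and self.gq < 0:
            raise ValueError("negative GQ")

    def masked(self) -> "GenotypeCall":
        """Copy of this call with the genotype set to missing (QC mask)."""
        return replace(self, gt=Genotype.MISSING)


@dataclass
class AnnotationBundle:
    """Per-variant annotation: gene context, population AFs, predictor calls.

    ``pop_afs`` maps database name -> allele frequency; a database absent
    from the map reported nothing for this variant (distinct from an
    explicit 0.0, which is an observed-absent call used for novelty).
    ``predictor_calls`` is an ordered tool -> call map; ``unknown`` calls
    are excluded from damaging-fraction denominators.
    """

    gene: Optional[str] = None
    transcript: Optional[str] = None
    cdna_pos: Optional[int] = None
    hgvs_c: Optional[str] = None
    hgvs_p: Optional[str] = None
    consequence: Consequence = Consequence.UNKNOWN
    pop_afs: dict[str, float] = field(default_factory=dict)
    predictor_calls: dict[str, PredictorCall] = field(default_factory=dict)
    cadd: Optional[float] = None

    def __post_init__(self) -> None:
        for db, af in self.pop_afs.items():
            if not (0.0 <= af <= 1.0):
                raise ValueError(f"population AF {af} for {db!r} outside [0, 1]")
        if self.cadd is not None and self.cadd < 0:
            raise ValueError("CADD score must be non-negative")

    @property
    def max_pop_af(self) -> Optional[float]:
        """Largest observed AF across databases; None when none reported."""
        return max(self.pop_afs.values()) if self.pop_afs else None


@dataclass
class VariantRecord:
    """One biallelic site (after multiallelic decomposition)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    calls: dict[str, GenotypeCall]
    annotation: AnnotationBundle = field(default_factory=AnnotationBundle)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if "," in self.alt:
            raise ValueError("VariantRecord is biallelic; decompose first")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def with_masked_calls(self, mask: set[str]) -> "VariantRecord":
        """Copy with the genotypes of ``mask`` samples set to missing."""
        calls = {
            s: (c.masked() if s in mask else c) for s, c in self.calls.items()
        }
        return replace(self, calls=calls)


@dataclass(frozen=True)
class FilterDecision:
    stage: str
    passed: bool
    reason: str = ""

    def __str__(self) -> str:
        verdict = "pass" if self.passed else "fail"
        return f"{self.stage}:{verdict}" + (f"({self.reason})" if self.reason else "")


UNREACHABLE = "unreachable"


@dataclass
class Candidate:
    """One variant's full journey through the cascade."""

    variant: VariantRecord
    filter_trace: list[FilterDecision]
    segregation: Optional["SegregationResult"] = None  # noqa: F821
    tier: Optional[int] = None
    rank: Optional[int] = None
    network_distance: Optional[int] = None  # None = not computed / unreachable
    assessment: Optional["PathogenicityAssessment"] = None  # noqa: F821

    @property
    def passed_all(self) -> bool:
        return all(d.passed for d in self.filter_trace)

    def first_failed_stage(self) -> Optional[str]:
        for d in self.filter_trace:
            if not d.passed:
                return d.stage
        return None


@dataclass
class CandidateReport:
    """Ranked candidates plus the variants set aside along the way.

    ``candidates`` hold contiguous ranks 1..k and passed every hard
    filter. ``panel_hits`` are variants in known disease genes, reported
    separately (in clinical triage a pathogenic panel hit would end the
    exome-wide search). ``rejected`` is populated only in verbose mode.
    """

    candidates: list[Candidate] = field(default_factory=list)
    panel_hits: list[Candidate] = field(default_factory=list)
    rejected: list[Candidate] = field(default_factory=list)

    def validate(self) -> None:
        ranks = [c.rank for c in self.candidates]
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValueError(f"ranks not contiguous from 1: {ranks}")
        for c in self.candidates:
            if not c.passed_all:
                raise ValueError(
                    f"candidate {c.variant.key} has a failed filter stage"
                )
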