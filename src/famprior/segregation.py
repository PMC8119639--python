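"""Pedigree segregation under explicit inheritance models.

Four models are supported:

``dominant_complete``
    every affected member carries the alternate allele and every
    unaffected member is homozygous reference (fully penetrant dominant);
``dominant_incomplete``
    every affected member is a carrier, unaffected members are
    unconstrained — the pattern of a dominant variant with incomplete
    penetrance, where an obligate carrier can remain healthy;
``de_novo``
    the proband carries the allele while both parents are *confidently*
    homozygous reference (hom-ref with depth and GQ above the QC
    thresholds, guarding against allele dropout in a parent);
``recessive_hom``
    every affected member is homozygous alternate, every genotyped parent
    of an affected is heterozygous, and no unaffected member is
    homozygous alternate.

Carrier status means het or hom-alt. Individuals with unknown affection
status are excluded from model constraints. When a genotype the model
needs is missing, the result is uninformative (and not compatible).

:func:`brute_force_segregation` re-states each model as a direct
predicate on a genotype vector, sharing no code with :func:`segregate`;
it exists so the engine can be checked by exhaustive enumeration over
all genotype assignments of a small pedigree.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence, Union

from .qc import FilterConfig
from .types import Affection, Genotype, GenotypeCall, Pedigree, VariantRecord


class InheritanceModel(enum.Enum):
    DOMINANT_COMPLETE = "dominant_complete"
    DOMINANT_INCOMPLETE = "dominant_incomplete"
    DE_NOVO = "de_novo"
    RECESSIVE_HOM = "recessive_hom"


class IncompleteTrioError(ValueError):
    """De novo analysis requested but no affected member has both parents."""


@dataclass
class SegregationResult:
    compatible: bool
    model: InheritanceModel
    affected_carriers: int
    unaffected_carriers: int
    affected_noncarriers: int
    informative: bool

    def __post_init__(self) -> None:
        if min(self.affected_carriers, self.unaffected_carriers, self.affected_noncarriers) < 0:
            raise ValueError("negative carrier count")
        if self.compatible and not self.informative:
            raise ValueError("compatible result cannot be uninformative")


def find_proband(pedigree: Pedigree, proband_id: Optional[str] = None) -> str:
    """The designated proband for de novo analysis.

    Default: the first affected individual (pedigree order) whose father
    and mother are both in the pedigree. An explicit ``proband_id``
    overrides the default but must still have both parents present.
    """
    members = pedigree.members
    if proband_id is not None:
        ind = members.get(proband_id)
        if ind is None or ind.father_id is None or ind.mother_id is None:
            raise IncompleteTrioError(
                f"family {pedigree.family_id!r}: proband {proband_id!r} "
                f"does not have both parents in the pedigree"
            )
        return proband_id
    for ind in pedigree.individuals:
        if (
            ind.affected is Affection.AFFECTED
            and ind.father_id is not None
            and ind.mother_id is not None
        ):
            return ind.id
    raise IncompleteTrioError(
        f"family {pedigree.family_id!r}: no affected member with both "
        f"parents in the pedigree (incomplete trio)"
    )


def _confident_hom_ref(call: GenotypeCall, config: FilterConfig) -> bool:
    return (
        call.gt is Genotype.HOM_REF
        and call.depth is not None
        and call.depth >= config.min_depth
        and call.gq is not None
        and call.gq >= config.min_gq
    )


def segregate(
    variant: VariantRecord,
    pedigree: Pedigree,
    model: InheritanceModel,
    config: Optional[FilterConfig] = None,
    proband_id: Optional[str] = None,
) -> SegregationResult:
    """Evaluate one variant against one inheritance model in one family.

    Genotype QC is assumed to have been applied already (failing
    genotypes masked to missing); the depth/GQ thresholds in ``config``
    are used here only for the confident-hom-ref requirement on de novo
    parents.
    """
    config = config or FilterConfig()
    members = pedigree.members
    calls = {iid: variant.calls.get(iid) for iid in members}
    for iid, call in calls.items():
        if call is None:
            calls[iid] = GenotypeCall(sample_id=iid, gt=Genotype.MISSING)

    # carrier tallies over non-missing genotypes, regardless of model
    aff_car = aff_non = unaff_car = 0
    for ind in pedigree.individuals:
        gt = calls[ind.id].gt
        if gt is Genotype.MISSING:
            continue
        if ind.affected is Affection.AFFECTED:
            if gt.is_carrier:
                aff_car += 1
            else:
                aff_non += 1
        elif ind.affected is Affection.UNAFFECTED:
            if gt.is_carrier:
                unaff_car += 1

    affected = [i.id for i in pedigree.affected_members()]
    unaffected = [i.id for i in pedigree.unaffected_members()]

    if model is InheritanceModel.DE_NOVO:
        proband = find_proband(pedigree, proband_id)
        father = members[proband].father_id
        mother = members[proband].mother_id
        required = [proband, father, mother]
    elif model is InheritanceModel.DOMINANT_INCOMPLETE:
        required = list(affected)
    else:  # dominant_complete, recessive_hom constrain both phenotype classes
        required = affected + unaffected

    informative = all(calls[iid].gt is not Genotype.MISSING for iid in required)

    compatible = False
    if informative:
        if model is InheritanceModel.DOMINANT_COMPLETE:
            compatible = True
            for iid in affected:
                if not calls[iid].gt.is_carrier:
                    compatible = False
                    break
            if compatible:
                for iid in unaffected:
                    if calls[iid].gt is not Genotype.HOM_REF:
                        compatible = False
                        break
        elif model is InheritanceModel.DOMINANT_INCOMPLETE:
            compatible = True
            for iid in affected:
                if not calls[iid].gt.is_carrier:
                    compatible = False
                    break
        elif model is InheritanceModel.DE_NOVO:
            compatible = (
                calls[proband].gt.is_carrier
                and _confident_hom_ref(calls[father], config)
                and _confident_hom_ref(calls[mother], config)
            )
        elif model is InheritanceModel.RECESSIVE_HOM:
            compatible = True
            for iid in affected:
                if calls[iid].gt is not Genotype.HOM_ALT:
                    compatible = False
                    break
            if compatible:
                for iid in unaffected:
                    if calls[iid].gt is Genotype.HOM_ALT:
                        compatible = False
                        break
            if compatible:
                for iid in affected:
                    for parent in (members[iid].father_id, members[iid].mother_id):
                        if parent is None:
                            continue
                        pgt = calls[parent].gt
                        if pgt is not Genotype.MISSING and pgt is not Genotype.HET:
                            compatible = False
                            break
                    if not compatible:
                        break

    return SegregationResult(
        compatible=compatible,
        model=model,
        affected_carriers=aff_car,
        unaffected_carriers=unaff_car,
        affected_noncarriers=aff_non,
        informative=informative,
    )


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

_MAX_BRUTE_FORCE = 8

GenotypeCode = Union[Genotype, str]


def brute_force_segregation(
    genotype_vector: Sequence[GenotypeCode],
    pedigree: Pedigree,
    model: InheritanceModel,
    proband_id: Optional[str] = None,
) -> bool:
    """Declarative restatement of the model predicates, for testing.

    ``genotype_vector`` is aligned with ``pedigree.individuals`` and
    holds non-missing genotype codes. Written independently of
    :func:`segregate` (set comprehensions over the raw definitions, no
    shared helpers) so exhaustive enumeration over all 3^n assignments
    can act as an oracle. Refuses pedigrees larger than 8 members.
    """
    if len(pedigree) > _MAX_BRUTE_FORCE:
        raise ValueError(
            f"pedigree of size {len(pedigree)} exceeds brute-force guard "
            f"({_MAX_BRUTE_FORCE})"
        )
    if len(genotype_vector) != len(pedigree):
        raise ValueError("genotype vector length does not match pedigree")

    g = {
        ind.id: (code.value if isinstance(code, Genotype) else str(code))
        for ind, code in zip(pedigree.individuals, genotype_vector)
    }
    aff = {i.id for i in pedigree.individuals if i.affected is Affection.AFFECTED}
    unaff = {i.id for i in pedigree.individuals if i.affected is Affection.UNAFFECTED}
    carries = {s for s, gt in g.items() if gt in ("het", "hom_alt")}

    if model is InheritanceModel.DOMINANT_COMPLETE:
        return aff <= carries and all(g[s] == "hom_ref" for s in unaff)

    if model is InheritanceModel.DOMINANT_INCOMPLETE:
        return aff <= carries

    if model is InheritanceModel.DE_NOVO:
        if proband_id is None:
            with_parents = [
                i.id
                for i in pedigree.individuals
                if i.id in aff and i.father_id is not None and i.mother_id is not None
            ]
            if not with_parents:
                raise IncompleteTrioError("incomplete trio")
            proband_id = with_parents[0]
        parents = next(
            (i.father_id, i.mother_id)
            for i in pedigree.individuals
            if i.id == proband_id
        )
        if None in parents:
            raise IncompleteTrioError("incomplete trio")
        return proband_id in carries and all(g[p] == "hom_ref" for p in parents)

    if model is InheritanceModel.RECESSIVE_HOM:
        parents_of_affected = {
            p
            for i in pedigree.individuals
            if i.id in aff
            for p in (i.father_id, i.mother_id)
            if p is not None
        }
        return (
            all(g[s] == "hom_alt" for s in aff)
            and all(g[s] != "hom_alt" for s in unaff)
            and all(g[p] == "het" for p in parents_of_affected)
        )

    raise ValueError(f"unknown model {model}")
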