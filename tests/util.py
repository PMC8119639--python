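"""Shared builders for pedigrees, calls and variants used across tests."""

from __future__ import annotations

from typing import Optional

from famprior import (
    Affection,
    AnnotationBundle,
    Genotype,
    GenotypeCall,
    Individual,
    Pedigree,
    Sex,
    VariantRecord,
)

_DEFAULT_AB = {
    Genotype.HOM_REF: 0.0,
    Genotype.HET: 0.5,
    Genotype.HOM_ALT: 1.0,
    Genotype.MISSING: None,
}


def ind(
    iid: str,
    father: Optional[str] = None,
    mother: Optional[str] = None,
    sex: str = "female",
    affected: str = "unaffected",
) -> Individual:
    return Individual(
        id=iid,
        father_id=father,
        mother_id=mother,
        sex=Sex(sex),
        affected=Affection(affected),
    )


def trio_ped() -> Pedigree:
    return Pedigree(
        family_id="TRIO",
        individuals=[
            ind("DAD", sex="male"),
            ind("MOM"),
            ind("KID", father="DAD", mother="MOM", affected="affected"),
        ],
    )


def quartet_ped() -> Pedigree:
    return Pedigree(
        family_id="QUAD",
        individuals=[
            ind("DAD", sex="male"),
            ind("MOM"),
            ind("KID", father="DAD", mother="MOM", affected="affected"),
            ind("SIB", father="DAD", mother="MOM", sex="male"),
        ],
    )


def six_ped() -> Pedigree:
    """Index case and her affected daughter, an unaffected sibling of the
    index, and three more unaffected relatives."""
    return Pedigree(
        family_id="SIX",
        individuals=[
            ind("PROBAND", affected="affected"),
            ind("SPOUSE", sex="male"),
            ind("SIBLING"),
            ind("DAUGHTER", father="SPOUSE", mother="PROBAND", affected="affected"),
            ind("SON", father="SPOUSE", mother="PROBAND", sex="male"),
            ind("NIECE", mother="SIBLING"),
        ],
    )


def call(
    sid: str,
    gt: Genotype,
    depth: Optional[int] = 60,
    gq: Optional[int] = 99,
    ab: Optional[float] = "auto",
) -> GenotypeCall:
    if ab == "auto":
        ab = _DEFAULT_AB[gt]
    return GenotypeCall(sample_id=sid, gt=gt, depth=depth, gq=gq, alt_fraction=ab)


def variant(
    genotypes: dict[str, Genotype],
    annotation: Optional[AnnotationBundle] = None,
    chrom: str = "1",
    pos: int = 100,
) -> VariantRecord:
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref="A",
        alt="T",
        calls={sid: call(sid, gt) for sid, gt in genotypes.items()},
        annotation=annotation or AnnotationBundle(),
    )
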