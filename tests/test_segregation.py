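"""Inheritance-model semantics, checked against a brute-force oracle."""

from itertools import product

import pytest

from famprior import (
    FilterConfig,
    Genotype,
    InheritanceModel,
    brute_force_segregation,
    segregate,
)
from famprior.segregation import IncompleteTrioError

from util import call, quartet_ped, six_ped, trio_ped, variant

ALL_MODELS = list(InheritanceModel)
GTS = (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)


def fig1_variant():
    """The extended-family pattern: both patients het, the index's
    unaffected sibling het, everyone else hom-ref."""
    return variant(
        {
            "PROBAND": Genotype.HET,
            "DAUGHTER": Genotype.HET,
            "SIBLING": Genotype.HET,
            "SPOUSE": Genotype.HOM_REF,
            "SON": Genotype.HOM_REF,
            "NIECE": Genotype.HOM_REF,
        }
    )


def test_dominant_incomplete_accepts_unaffected_carrier():
    res = segregate(fig1_variant(), six_ped(), InheritanceModel.DOMINANT_INCOMPLETE)
    assert res.compatible and res.informative
    assert res.affected_carriers == 2
    assert res.unaffected_carriers == 1
    assert res.affected_noncarriers == 0


def test_dominant_complete_rejects_unaffected_carrier():
    """Full penetrance forbids healthy carriers, so the same genotype
    pattern is incompatible under the complete-penetrance model."""
    res = segregate(fig1_variant(), six_ped(), InheritanceModel.DOMINANT_COMPLETE)
    assert not res.compatible and res.informative


def test_de_novo_trio():
    v = variant(
        {"DAD": Genotype.HOM_REF, "MOM": Genotype.HOM_REF, "KID": Genotype.HET}
    )
    res = segregate(v, trio_ped(), InheritanceModel.DE_NOVO)
    assert res.compatible


def test_de_novo_requires_confident_parental_reference():
    """A hom-ref parent at depth 5 cannot rule out allele dropout, so the
    de novo call is rejected even though no alt allele was seen."""
    v = variant({"MOM": Genotype.HOM_REF, "KID": Genotype.HET})
    v.calls["DAD"] = call("DAD", Genotype.HOM_REF, depth=5)
    assert not segregate(v, trio_ped(), InheritanceModel.DE_NOVO).compatible
    # lowering min_depth re-admits it: the de novo set grows monotonically
    assert segregate(
        v, trio_ped(), InheritanceModel.DE_NOVO, FilterConfig(min_depth=5)
    ).compatible


def test_de_novo_without_parents_is_incomplete_trio():
    from util import ind
    from famprior import Pedigree

    broken = Pedigree(
        family_id="X",
        individuals=[
            ind("A", affected="affected"),
            ind("B", sex="male"),
        ],
    )
    v = variant({"A": Genotype.HET, "B": Genotype.HOM_REF})
    with pytest.raises(IncompleteTrioError):
        segregate(v, broken, InheritanceModel.DE_NOVO)


def test_missing_genotype_is_uninformative_never_compatible():
    v = variant(
        {
            "PROBAND": Genotype.MISSING,
            "DAUGHTER": Genotype.HET,
            "SIBLING": Genotype.HET,
            "SPOUSE": Genotype.HOM_REF,
            "SON": Genotype.HOM_REF,
            "NIECE": Genotype.HOM_REF,
        }
    )
    for model in (
        InheritanceModel.DOMINANT_COMPLETE,
        InheritanceModel.DOMINANT_INCOMPLETE,
    ):
        res = segregate(v, six_ped(), model)
        assert not res.informative and not res.compatible


def test_recessive_hom():
    v = variant(
        {"DAD": Genotype.HET, "MOM": Genotype.HET, "KID": Genotype.HOM_ALT}
    )
    assert segregate(v, trio_ped(), InheritanceModel.RECESSIVE_HOM).compatible
    v2 = variant(
        {"DAD": Genotype.HOM_REF, "MOM": Genotype.HET, "KID": Genotype.HOM_ALT}
    )
    assert not segregate(v2, trio_ped(), InheritanceModel.RECESSIVE_HOM).compatible


# ---------------------------------------------------------------------------
# Oracle equivalence and model nesting
# ---------------------------------------------------------------------------


def _exhaustive_check(ped, model):
    n = len(ped)
    ids = ped.sample_ids
    mismatches = []
    for assignment in product(GTS, repeat=n):
        v = variant(dict(zip(ids, assignment)))
        engine = segregate(v, ped, model).compatible
        oracle = brute_force_segregation(list(assignment), ped, model)
        if engine != oracle:
            mismatches.append((assignment, engine, oracle))
    assert not mismatches, mismatches[:5]


@pytest.mark.parametrize("model", ALL_MODELS, ids=lambda m: m.value)
@pytest.mark.parametrize(
    "ped_factory", [trio_ped, quartet_ped, six_ped], ids=["trio", "quartet", "six"]
)
def test_engine_matches_brute_force_exhaustively(ped_factory, model):
    """The segregation engine and the independent declarative predicate
    agree on every genotype assignment (3^n enumeration)."""
    _exhaustive_check(ped_factory(), model)


def test_dominant_complete_nests_in_incomplete():
    ped = six_ped()
    for assignment in product(GTS, repeat=len(ped)):
        if brute_force_segregation(
            list(assignment), ped, InheritanceModel.DOMINANT_COMPLETE
        ):
            assert brute_force_segregation(
                list(assignment), ped, InheritanceModel.DOMINANT_INCOMPLETE
            )


def test_brute_force_refuses_large_pedigrees():
    from famprior import Pedigree
    from util import ind

    big = Pedigree(
        family_id="BIG", individuals=[ind(f"I{k}") for k in range(9)]
    )
    with pytest.raises(ValueError, match="brute-force"):
        brute_force_segregation([Genotype.HOM_REF] * 9, big, InheritanceModel.DOMINANT_COMPLETE)
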