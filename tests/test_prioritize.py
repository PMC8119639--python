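"""Pathogenicity aggregation, HGVS arithmetic, tiering, ranking, cascade."""

import pytest

from famprior import (
    AnnotationBundle,
    Candidate,
    Consequence,
    Genotype,
    PredictorCall,
    PrioritizationConfig,
    aggregate_predictors,
    assign_tier,
    codon_of,
    load_config,
    parse_hgvs_p,
    rank_candidates,
    run_prioritization,
)
from famprior.io import read_annotated_vcf, read_pedigrees
from famprior.prioritize import PathogenicityAssessment, assess_variant, prioritize_records

from util import variant


def _calls(n_damaging, n_tolerated, n_unknown=0):
    calls = {}
    for i in range(n_damaging):
        calls[f"d{i}"] = PredictorCall.DAMAGING
    for i in range(n_tolerated):
        calls[f"t{i}"] = PredictorCall.TOLERATED
    for i in range(n_unknown):
        calls[f"u{i}"] = PredictorCall.UNKNOWN
    return calls


@pytest.mark.parametrize(
    "n_dam, n_tol, n_unk, exp_inf, exp_frac",
    [
        (12, 7, 0, 19, 12 / 19),
        (5, 4, 10, 9, 5 / 9),
        (0, 7, 0, 7, 0.0),
        (0, 0, 5, 0, None),
        (0, 0, 0, 0, None),
    ],
)
def test_aggregate_predictors(n_dam, n_tol, n_unk, exp_inf, exp_frac):
    """Unknown calls drop out of the denominator; no informative call
    leaves the fraction undefined rather than zero."""
    n_damaging, n_informative, fraction = aggregate_predictors(
        _calls(n_dam, n_tol, n_unk)
    )
    assert (n_damaging, n_informative) == (n_dam, exp_inf)
    if exp_frac is None:
        assert fraction is None
    else:
        assert fraction == pytest.approx(exp_frac)


@pytest.mark.parametrize(
    "cdna, codon", [(697, 233), (417, 139), (1, 1), (3, 1), (4, 2)]
)
def test_codon_arithmetic(cdna, codon):
    assert codon_of(cdna) == codon


def test_codon_of_rejects_nonpositive():
    with pytest.raises(ValueError):
        codon_of(0)


@pytest.mark.parametrize(
    "hgvs, ref, codon, alt, csq",
    [
        ("p.Cys139Ter", "Cys", 139, "Ter", Consequence.STOP_GAIN),
        ("p.(Ser233Gly)", "Ser", 233, "Gly", Consequence.MISSENSE),
        ("NP_077285.3:p.Ser233Gly", "Ser", 233, "Gly", Consequence.MISSENSE),
        ("p.Ala5Ala", "Ala", 5, "Ala", Consequence.SYNONYMOUS),
        ("p.Arg100*", "Arg", 100, "*", Consequence.STOP_GAIN),
    ],
)
def test_parse_hgvs_p(hgvs, ref, codon, alt, csq):
    parsed = parse_hgvs_p(hgvs)
    assert (parsed.ref_aa, parsed.codon, parsed.alt_aa) == (ref, codon, alt)
    assert parsed.consequence is csq


def test_unparseable_hgvs_is_unknown_not_error():
    assert parse_hgvs_p("garbage").consequence is Consequence.UNKNOWN


def test_hgvs_codon_consistency_on_worked_examples():
    """cDNA position 697 -> codon 233 (Ser233Gly) and 417 -> codon 139
    (Cys139Ter): the codon arithmetic agrees with the protein HGVS."""
    for cdna, hgvs in [(697, "p.(Ser233Gly)"), (417, "p.Cys139Ter")]:
        assert parse_hgvs_p(hgvs).codon == codon_of(cdna)


# ---------------------------------------------------------------------------
# Tiers and ranking
# ---------------------------------------------------------------------------

PCFG = PrioritizationConfig()


def _assessment(csq, frac, cadd, n_inf=19):
    n_dam = 0 if frac is None else round(frac * n_inf)
    return PathogenicityAssessment(
        n_damaging=n_dam,
        n_informative=0 if frac is None else n_inf,
        damaging_fraction=frac,
        cadd=cadd,
        consequence=csq,
    )


@pytest.mark.parametrize(
    "csq, frac, cadd, tier",
    [
        (Consequence.STOP_GAIN, 5 / 9, 35.0, 1),
        (Consequence.MISSENSE, 12 / 19, 25.8, 2),
        (Consequence.MISSENSE, 1 / 19, 3.0, 3),
        (Consequence.MISSENSE, 12 / 19, 10.0, 3),  # fails the CADD gate
        (Consequence.MISSENSE, None, 30.0, 2),  # no predictors: CADD alone
        (Consequence.SYNONYMOUS, None, 30.0, 3),
    ],
)
def test_assign_tier(csq, frac, cadd, tier):
    assert assign_tier(_assessment(csq, frac, cadd), PCFG) == tier


def _cand(csq, frac, cadd, chrom="1", pos=100):
    rec = variant({"S": Genotype.HET}, chrom=chrom, pos=pos)
    a = _assessment(csq, frac, cadd)
    return Candidate(
        variant=rec, filter_trace=[], assessment=a, tier=assign_tier(a, PCFG)
    )


def test_rank_tier_one_dominates():
    truncating = _cand(Consequence.STOP_GAIN, 5 / 9, 35.0, pos=500)
    missense = _cand(Consequence.MISSENSE, 12 / 19, 25.8, pos=100)
    ranked = rank_candidates([missense, truncating])
    assert [c.rank for c in ranked] == [1, 2]
    assert ranked[0] is truncating


def test_rank_by_cadd_within_tier():
    low = _cand(Consequence.MISSENSE, 0.6, 25.0, pos=100)
    high = _cand(Consequence.MISSENSE, 0.6, 30.0, pos=200)
    assert rank_candidates([low, high])[0] is high


def test_rank_ties_break_by_coordinate():
    a = _cand(Consequence.MISSENSE, 0.6, 25.0, chrom="2", pos=100)
    b = _cand(Consequence.MISSENSE, 0.6, 25.0, chrom="1", pos=900)
    c = _cand(Consequence.MISSENSE, 0.6, 25.0, chrom="1", pos=100)
    assert [x.variant.key for x in rank_candidates([a, b, c])] == [
        c.variant.key,
        b.variant.key,
        a.variant.key,
    ]


# ---------------------------------------------------------------------------
# End-to-end cascade
# ---------------------------------------------------------------------------


def test_cascade_recovers_exactly_the_spiked_variants(two_family_report):
    genes = [c.variant.annotation.gene for c in two_family_report.candidates]
    assert genes == ["TRAF2", "TNIP2"]
    assert [c.rank for c in two_family_report.candidates] == [1, 2]
    assert two_family_report.candidates[0].tier == 1
    assert two_family_report.candidates[0].assessment.consequence is Consequence.STOP_GAIN


def test_cascade_drops_causal_variant_if_common(two_family_fixture):
    """Raising the causal variant's population AF above 1% removes it."""
    cfg = load_config(two_family_fixture.config)
    peds = read_pedigrees(two_family_fixture.ped)
    records = read_annotated_vcf(two_family_fixture.vcf, cfg.schema, peds.values())
    for rec in records:
        if rec.annotation.gene == "TNIP2":
            rec.annotation.pop_afs = {"gnomad_exomes": 0.05}
    report = prioritize_records(records, peds, cfg)
    assert [c.variant.annotation.gene for c in report.candidates] == ["TRAF2"]


def test_empty_vcf_gives_empty_report(tmp_path, two_family_fixture):
    cfg = load_config(two_family_fixture.config)
    peds = read_pedigrees(two_family_fixture.ped)
    report = prioritize_records([], peds, cfg)
    assert report.candidates == []


def test_empty_pedigree_is_error(tmp_path, two_family_fixture):
    empty = tmp_path / "empty.ped"
    empty.write_text("")
    with pytest.raises(ValueError, match="empty pedigree"):
        run_prioritization(two_family_fixture.vcf, empty, two_family_fixture.config)


def test_rerun_is_byte_identical(tmp_path, two_family_fixture):
    """No hidden randomness: the same inputs give the same report bytes."""
    from famprior import write_candidate_report

    outs = []
    for name in ("a.tsv", "b.tsv"):
        report = run_prioritization(
            two_family_fixture.vcf, two_family_fixture.ped, two_family_fixture.config
        )
        out = tmp_path / name
        write_candidate_report(report, out)
        outs.append(out.read_bytes())
    assert outs[0] == outs[1]


def test_panel_hit_reported_separately(two_family_report):
    assert [c.variant.annotation.gene for c in two_family_report.panel_hits] == ["BMPR2"]
    panel_stage = [d for d in two_family_report.panel_hits[0].filter_trace if d.stage == "panel"]
    assert panel_stage and not panel_stage[0].passed


def test_network_distances_annotated(two_family_report):
    by_gene = {c.variant.annotation.gene: c for c in two_family_report.candidates}
    assert by_gene["TRAF2"].network_distance == 1
    assert by_gene["TNIP2"].network_distance == 4
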