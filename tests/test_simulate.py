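"""The synthetic-family generator: determinism, Mendelian transmission,
spike recovery and single-fault decoys."""

import pytest

from famprior import (
    Affection,
    Genotype,
    InheritanceModel,
    SyntheticFamilyConfig,
    TNIP2_SPIKE,
    TRAF2_SPIKE,
    generate_vcf,
    run_prioritization,
    simulate_family,
)
from famprior.simulate import (
    ALL_DECOYS,
    DECOY_GENES,
    _maybe_corrupt,
    build_scenario,
    make_two_family_fixture,
)


def _cfg(**kw):
    base = dict(family_id="FAM1", seed=11)
    base.update(kw)
    return SyntheticFamilyConfig(**base)


# ---------------------------------------------------------------------------
# Family simulation
# ---------------------------------------------------------------------------


def test_de_novo_trio_by_construction():
    ped, gts = simulate_family(
        _cfg(pedigree_template="trio", model=InheritanceModel.DE_NOVO)
    )
    assert gts["FAM1_PROBAND"] is Genotype.HET
    assert gts["FAM1_FATHER"] is Genotype.HOM_REF
    assert gts["FAM1_MOTHER"] is Genotype.HOM_REF
    assert ped.members["FAM1_PROBAND"].affected is Affection.AFFECTED


def test_full_penetrance_dominant_has_no_unaffected_carriers():
    for seed in range(20):
        ped, gts = simulate_family(
            _cfg(
                seed=seed,
                pedigree_template="six_member_two_affected",
                model=InheritanceModel.DOMINANT_COMPLETE,
                penetrance=1.0,
            )
        )
        for ind_ in ped.individuals:
            if gts[ind_.id].is_carrier:
                assert ind_.affected is Affection.AFFECTED


def test_dominant_always_yields_affected_carriers_only():
    """Under a dominant model every affected member is a carrier, whatever
    the penetrance draw did."""
    for seed in range(20):
        ped, gts = simulate_family(
            _cfg(
                seed=seed,
                pedigree_template="six_member_two_affected",
                penetrance=0.5,
            )
        )
        assert ped.affected_members()
        for ind_ in ped.affected_members():
            assert gts[ind_.id].is_carrier


def test_unknown_decoy_class_rejected():
    with pytest.raises(ValueError, match="bogus"):
        SyntheticFamilyConfig(family_id="F", seed=1, decoy_plan=frozenset({"bogus"}))


def test_recessive_simulation_produces_hom_alt_affected():
    ped, gts = simulate_family(
        _cfg(
            pedigree_template="quartet",
            model=InheritanceModel.RECESSIVE_HOM,
            penetrance=1.0,
        )
    )
    for ind_ in ped.affected_members():
        assert gts[ind_.id] is Genotype.HOM_ALT


# ---------------------------------------------------------------------------
# VCF generation
# ---------------------------------------------------------------------------


def _generate(tmp_path, seed, **kw):
    cfg = _cfg(
        seed=seed,
        pedigree_template="six_member_two_affected",
        n_background_variants=8,
        decoy_plan=ALL_DECOYS,
        **kw,
    )
    ped, gts = simulate_family(cfg)
    return generate_vcf(
        [(ped, gts)], [TNIP2_SPIKE], cfg, tmp_path / "c.vcf", tmp_path / "c.ped"
    )


def test_same_seed_byte_identical(tmp_path):
    (tmp_path / "a").mkdir(), (tmp_path / "b").mkdir()
    va, _ = _generate(tmp_path / "a", seed=5)
    vb, _ = _generate(tmp_path / "b", seed=5)
    assert va.read_bytes() == vb.read_bytes()
    vc, _ = _generate(tmp_path, seed=6)
    assert va.read_bytes() != vc.read_bytes()


def test_decoy_rows_present_with_expected_annotations(tmp_path):
    vcf, _ = _generate(tmp_path, seed=5)
    text = vcf.read_text()
    for gene in DECOY_GENES.values():
        assert gene in text
    # the common-AF decoy carries an above-cutoff frequency
    af_line = next(l for l in text.splitlines() if "DECOYAF" in l)
    assert "AF_GNOMAD_E=0.05" in af_line


def test_spiked_stop_gain_annotations(tmp_path):
    ped, gts = simulate_family(
        _cfg(pedigree_template="trio", model=InheritanceModel.DE_NOVO)
    )
    cfg = _cfg(pedigree_template="trio", model=InheritanceModel.DE_NOVO)
    vcf, _ = generate_vcf(
        [(ped, gts)], [TRAF2_SPIKE], cfg, tmp_path / "t.vcf", tmp_path / "t.ped"
    )
    line = next(l for l in vcf.read_text().splitlines() if "TRAF2" in l)
    assert "CADD=35" in line and "CSQ_CLASS=stop_gain" in line
    # 5 damaging + 4 tolerated + 10 unknown
    pred = next(f for f in line.split("\t")[7].split(";") if f.startswith("PRED="))
    codes = pred.removeprefix("PRED=").split("|")
    assert codes.count("D") == 5 and codes.count("T") == 4 and codes.count(".") == 10


def test_mendelian_consistency_of_generated_genotypes(tmp_path):
    """With zero genotype error, every child genotype is reachable from
    its parents' genotypes — checked with an independent per-trio
    predicate on the emitted VCF text."""
    from famprior import AnnotationSchema, read_annotated_vcf, read_pedigrees

    vcf, ped_path = _generate(tmp_path, seed=9)
    peds = read_pedigrees(ped_path)
    records = read_annotated_vcf(vcf, AnnotationSchema(), peds.values())

    transmit = {Genotype.HOM_REF: {0}, Genotype.HET: {0, 1}, Genotype.HOM_ALT: {1}}
    alt_copies = {Genotype.HOM_REF: 0, Genotype.HET: 1, Genotype.HOM_ALT: 2}

    def consistent(child, father, mother):
        if Genotype.MISSING in (child, father, mother):
            return True
        options = {a + b for a in transmit[father] for b in transmit[mother]}
        return alt_copies[child] in options

    for rec in records:
        for ped in peds.values():
            for ind_ in ped.individuals:
                if ind_.father_id and ind_.mother_id:
                    assert consistent(
                        rec.calls[ind_.id].gt,
                        rec.calls[ind_.father_id].gt,
                        rec.calls[ind_.mother_id].gt,
                    ), (rec.key, ind_.id)


# ---------------------------------------------------------------------------
# Error injection
# ---------------------------------------------------------------------------


def test_error_draws_nest_across_rates():
    """The per-genotype corruption decision uses a rate-independent
    random draw, so genotypes corrupted at a low rate are a subset of
    those corrupted at a higher rate."""
    grid = [((1, i), s) for i in range(30) for s in range(6)]
    for lo, hi in [(0.01, 0.1), (0.1, 0.5)]:
        flipped_lo = {
            k
            for k, s in grid
            if _maybe_corrupt(Genotype.HOM_REF, 7, k, s, lo) is not Genotype.HOM_REF
        }
        flipped_hi = {
            k
            for k, s in grid
            if _maybe_corrupt(Genotype.HOM_REF, 7, k, s, hi) is not Genotype.HOM_REF
        }
        assert flipped_lo <= flipped_hi


def test_recovery_degrades_with_genotype_errors(tmp_path):
    """Spike recovery is perfect with clean genotypes and no better at a
    heavy error rate (coupled error draws make this monotone)."""
    n = 15
    recovered = {0.0: 0, 0.5: 0}
    for rate in recovered:
        for seed in range(n):
            out = tmp_path / f"r{rate}_{seed}"
            paths = build_scenario(
                "dominant", seed=seed + 1, out_dir=out,
                genotype_error_rate=rate, n_background_variants=2,
                decoy_plan=frozenset(),
            )
            report = run_prioritization(paths.vcf, paths.ped, paths.config)
            genes = [c.variant.annotation.gene for c in report.candidates]
            recovered[rate] += "TNIP2" in genes
    assert recovered[0.0] == n
    assert recovered[0.5] < recovered[0.0]


# ---------------------------------------------------------------------------
# Worked-example fixture
# ---------------------------------------------------------------------------


def test_two_family_fixture_families(two_family_fixture):
    from famprior import read_pedigrees

    peds = read_pedigrees(two_family_fixture.ped)
    assert set(peds) == {"FAM1", "FAM2"}
    assert len(peds["FAM1"]) == 6 and len(peds["FAM1"].affected_members()) == 2
    assert len(peds["FAM2"]) == 3 and len(peds["FAM2"].affected_members()) == 1


def test_two_family_fixture_deterministic(tmp_path):
    a = make_two_family_fixture(tmp_path / "a")
    b = make_two_family_fixture(tmp_path / "b")
    assert a.vcf.read_bytes() == b.vcf.read_bytes()
    assert a.ped.read_bytes() == b.ped.read_bytes()
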