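"""Synthetic families and annotated multi-sample VCFs for pipeline testing.

The generator builds the two study designs the pipeline targets — an
extended family segregating a dominant variant with incomplete
penetrance, and a trio with a de novo variant — entirely in silico:

* pedigrees from small templates (trio, quartet, six-member two-affected),
* a spiked causal variant whose genotypes follow Mendelian transmission
  from founder carriers (or de novo placement in the proband),
* decoy variants, each engineered to violate exactly one filter
  (genotype QC, panel membership, segregation, population frequency, or
  predicted pathogenicity),
* background variants that are common or predicted benign, gene-dropped
  through each pedigree so transmission is always Mendelian-consistent,
* per-genotype DP/GQ/AD sampled from a negative-binomial coverage model
  (mean 60x by default, typical of clinical exomes).

Randomness is split per variant and per sample from the master seed, so
adding background variants never perturbs the spiked genotypes, and the
same seed always yields byte-identical output. Generated calls are
QC-clean by construction; miscalls enter only through the explicit
``genotype_error_rate``, whose per-genotype random draws are independent
of the rate itself (raising the rate corrupts a superset of genotypes).

Coordinates live on a small synthetic contig set; no genome build is
referenced and nothing is downloaded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from .io import (
    DEFAULT_POP_AF_KEYS,
    DEFAULT_PREDICTOR_TOOLS,
    write_ped,
)
from .segregation import InheritanceModel
from .types import (
    Affection,
    Consequence,
    Genotype,
    Individual,
    Pedigree,
    Sex,
)

PathLike = Union[str, Path]

CONTIGS: dict[str, int] = {
    "1": 5_000_000,
    "2": 5_000_000,
    "4": 2_000_000,
    "9": 3_000_000,
}

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# Spike specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpikeSpec:
    """Annotation card for a causal variant to spike into a family.

    ``n_damaging``/``n_informative`` give the in-silico predictor tally;
    the remaining tools (up to the roster size) are emitted as unknown
    calls. Population AFs are an explicit zero in every control database
    (the variant is novel). The codon implied by ``cdna_pos`` must match
    the protein HGVS string.
    """

    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    cdna_pos: int
    hgvs_c: str
    hgvs_p: str
    consequence: Consequence
    n_damaging: int
    n_informative: int
    cadd: float
    pop_afs: dict[str, float] = field(
        default_factory=lambda: {db: 0.0 for db in DEFAULT_POP_AF_KEYS}
    )

    def __post_init__(self) -> None:
        if self.n_damaging > self.n_informative:
            raise ValueError("n_damaging exceeds n_informative")
        if self.n_informative > len(DEFAULT_PREDICTOR_TOOLS):
            raise ValueError("predictor tally exceeds tool roster")
        implied = -(-self.cdna_pos // 3)  # ceil
        import re

        m = re.search(r"p\.\(?[A-Z][a-z]{2}(\d+)", self.hgvs_p)
        if m and int(m.group(1)) != implied:
            raise ValueError(
                f"{self.gene}: cDNA position {self.cdna_pos} implies codon "
                f"{implied}, but HGVS says {m.group(1)}"
            )

    def predictor_string(self) -> str:
        codes = (
            ["D"] * self.n_damaging
            + ["T"] * (self.n_informative - self.n_damaging)
            + ["."] * (len(DEFAULT_PREDICTOR_TOOLS) - self.n_informative)
        )
        return "|".join(codes)


#: Missense variant carried by two affected relatives and one unaffected
#: sibling in the dominant/incomplete-penetrance family. 12 of 19
#: informative predictors call it damaging; CADD 25.8; novel everywhere.
TNIP2_SPIKE = SpikeSpec(
    gene="TNIP2",
    chrom="4",
    pos=1_000_697,
    ref="A",
    alt="G",
    cdna_pos=697,
    hgvs_c="NM_024309.3:c.697A>G",
    hgvs_p="NP_077285.3:p.Ser233Gly",
    consequence=Consequence.MISSENSE,
    n_damaging=12,
    n_informative=19,
    cadd=25.8,
)

#: Stop-gain (nonsense) variant arising de novo in the trio proband.
#: 5 of 9 informative predictors damaging; CADD 35; novel everywhere.
TRAF2_SPIKE = SpikeSpec(
    gene="TRAF2",
    chrom="9",
    pos=2_000_417,
    ref="C",
    alt="A",
    cdna_pos=417,
    hgvs_c="NM_021138.3:c.417C>A",
    hgvs_p="NP_066961.2:p.Cys139Ter",
    consequence=Consequence.STOP_GAIN,
    n_damaging=5,
    n_informative=9,
    cadd=35.0,
)


# ---------------------------------------------------------------------------
# Pedigree templates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Slot:
    id: str
    father: Optional[str]
    mother: Optional[str]
    sex: Sex


def _trio(prefix: str) -> list[_Slot]:
    return [
        _Slot(f"{prefix}FATHER", None, None, Sex.MALE),
        _Slot(f"{prefix}MOTHER", None, None, Sex.FEMALE),
        _Slot(f"{prefix}PROBAND", f"{prefix}FATHER", f"{prefix}MOTHER", Sex.FEMALE),
    ]


def _quartet(prefix: str) -> list[_Slot]:
    return _trio(prefix) + [
        _Slot(f"{prefix}SIB", f"{prefix}FATHER", f"{prefix}MOTHER", Sex.MALE),
    ]


def _six_member(prefix: str) -> list[_Slot]:
    """Extended family: index case, spouse, index's sibling, two children
    of the index couple, and the sibling's child. The sibling pair are
    founders here (their parents were never sampled)."""
    return [
        _Slot(f"{prefix}PROBAND", None, None, Sex.FEMALE),
        _Slot(f"{prefix}SPOUSE", None, None, Sex.MALE),
        _Slot(f"{prefix}SIBLING", None, None, Sex.FEMALE),
        _Slot(f"{prefix}DAUGHTER", f"{prefix}SPOUSE", f"{prefix}PROBAND", Sex.FEMALE),
        _Slot(f"{prefix}SON", f"{prefix}SPOUSE", f"{prefix}PROBAND", Sex.MALE),
        _Slot(f"{prefix}NIECE", None, f"{prefix}SIBLING", Sex.FEMALE),
    ]


PEDIGREE_TEMPLATES = {
    "trio": _trio,
    "quartet": _quartet,
    "six_member_two_affected": _six_member,
}


# ---------------------------------------------------------------------------
# Family simulation
# ---------------------------------------------------------------------------


@dataclass
class SyntheticFamilyConfig:
    """Parameters of one simulated family and the dataset around it.

    ``penetrance`` is the probability that an obligate carrier (or
    hom-alt individual under the recessive model) is affected; 1.0 gives
    complete penetrance. ``decoy_plan`` names the filters to plant one
    violating decoy for. ``seed`` is mandatory — there is no implicit
    randomness anywhere in the generator.
    """

    family_id: str
    seed: int
    pedigree_template: Union[str, Pedigree] = "trio"
    model: InheritanceModel = InheritanceModel.DOMINANT_INCOMPLETE
    penetrance: float = 0.8
    n_background_variants: int = 30
    decoy_plan: frozenset[str] = frozenset()
    depth_mean: float = 60.0
    depth_dispersion: float = 10.0
    genotype_error_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.penetrance <= 1.0):
            raise ValueError("penetrance must be in (0, 1]")
        if not (0.0 <= self.genotype_error_rate < 1.0):
            raise ValueError("genotype_error_rate must be in [0, 1)")
        known = {"qc_fail", "common_af", "non_segregating", "benign_prediction", "panel_gene"}
        self.decoy_plan = frozenset(self.decoy_plan)
        bad = self.decoy_plan - known
        if bad:
            raise ValueError(f"unknown decoy class(es): {sorted(bad)}")


class ImpossibleConfiguration(ValueError):
    pass


def _transmit(rng: np.random.Generator, parent_gt: Genotype) -> int:
    """Number of alt alleles (0/1) transmitted by one parent."""
    if parent_gt is Genotype.HOM_REF:
        return 0
    if parent_gt is Genotype.HOM_ALT:
        return 1
    return int(rng.integers(0, 2))


def _gene_drop(
    rng: np.random.Generator,
    slots: Sequence[_Slot],
    founder_gts: dict[str, Genotype],
) -> dict[str, Genotype]:
    """Drop alleles down the pedigree; a missing parent transmits ref."""
    gts: dict[str, Genotype] = {}
    for slot in slots:  # templates list parents before children
        if slot.father is None and slot.mother is None:
            gts[slot.id] = founder_gts.get(slot.id, Genotype.HOM_REF)
            continue
        copies = 0
        for parent in (slot.father, slot.mother):
            if parent is None:
                continue
            copies += _transmit(rng, gts[parent])
        gts[slot.id] = (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)[copies]
    return gts


def simulate_family(
    config: SyntheticFamilyConfig,
) -> tuple[Pedigree, dict[str, Genotype]]:
    """Simulate one family and the genotypes of its spiked variant.

    Dominant models place a het allele in the first founder and
    gene-drop; the recessive model makes every founder het; the de novo
    model makes the first child with both parents het and everyone else
    hom-ref. Affection is then drawn: qualifying carriers are affected
    with probability ``penetrance``, everyone else is unaffected. If a
    draw yields no affected member, the simulation resamples on an
    incremented sub-seed, deterministically.
    """
    if isinstance(config.pedigree_template, Pedigree):
        raise ValueError(
            "explicit pedigrees carry their own affection status; use "
            "generate_vcf with hand-built genotypes instead"
        )
    try:
        slots = PEDIGREE_TEMPLATES[config.pedigree_template](
            f"{config.family_id}_"
        )
    except KeyError:
        raise ValueError(f"unknown pedigree template {config.pedigree_template!r}")

    model = config.model
    for attempt in range(1000):
        rng = np.random.default_rng([config.seed % (2**31), 11, attempt])

        if model in (
            InheritanceModel.DOMINANT_COMPLETE,
            InheritanceModel.DOMINANT_INCOMPLETE,
        ):
            founders = {slots[0].id: Genotype.HET}
            gts = _gene_drop(rng, slots, founders)
            risk = {s.id for s in slots if gts[s.id].is_carrier}
        elif model is InheritanceModel.RECESSIVE_HOM:
            founders = {
                s.id: Genotype.HET
                for s in slots
                if s.father is None and s.mother is None
            }
            if not any(s.father or s.mother for s in slots):
                raise ImpossibleConfiguration(
                    "recessive model needs at least one non-founder offspring"
                )
            gts = _gene_drop(rng, slots, founders)
            risk = {s.id for s in slots if gts[s.id] is Genotype.HOM_ALT}
        elif model is InheritanceModel.DE_NOVO:
            child = next(
                (s for s in slots if s.father is not None and s.mother is not None),
                None,
            )
            if child is None:
                raise ImpossibleConfiguration(
                    "de novo model needs a child with both parents sampled"
                )
            gts = {s.id: Genotype.HOM_REF for s in slots}
            gts[child.id] = Genotype.HET
            risk = {child.id}
        else:
            raise ValueError(f"unknown model {model}")

        # iterate in template order so the draws are reproducible
        affected = {
            s.id for s in slots if s.id in risk and rng.random() < config.penetrance
        }
        if affected:
            individuals = [
                Individual(
                    id=s.id,
                    father_id=s.father,
                    mother_id=s.mother,
                    sex=s.sex,
                    affected=(
                        Affection.AFFECTED
                        if s.id in affected
                        else Affection.UNAFFECTED
                    ),
                )
                for s in slots
            ]
            return Pedigree(family_id=config.family_id, individuals=individuals), gts
    raise ImpossibleConfiguration(
        f"no affected member after 1000 resamples (model {model.value}, "
        f"penetrance {config.penetrance})"
    )


# ---------------------------------------------------------------------------
# Variant rows and call sampling
# ---------------------------------------------------------------------------


@dataclass
class _Row:
    chrom: str
    pos: int
    ref: str
    alt: str
    info: dict[str, str]
    gts: dict[str, Genotype]
    stream_key: tuple[int, int]  # stable per-row RNG key, rate-independent
    forced_depth: dict[str, int] = field(default_factory=dict)


def _sample_depth(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    p = dispersion / (dispersion + mean)
    return int(max(1, rng.negative_binomial(dispersion, p)))


def _sample_call(
    rng: np.random.Generator,
    gt: Genotype,
    mean: float,
    dispersion: float,
    forced_depth: Optional[int] = None,
) -> tuple[int, int, int, int]:
    """(DP, GQ, ref reads, alt reads) for one clean genotype.

    Clean means the call would pass default QC: depth is resampled above
    the standard minimum and het allele balance is kept inside the
    accepted band, so only explicit error injection (or a forced depth,
    used by the QC decoy) produces failing calls.
    """
    if forced_depth is not None:
        dp = forced_depth
    else:
        dp = _sample_depth(rng, mean, dispersion)
        for _ in range(50):
            if dp >= 12:
                break
            dp = _sample_depth(rng, mean, dispersion)
    gq = int(rng.integers(60, 100))
    if gt is Genotype.HET:
        alt = int(rng.binomial(dp, 0.5))
        for _ in range(50):
            if dp == 0 or 0.28 <= alt / dp <= 0.72:
                break
            alt = int(rng.binomial(dp, 0.5))
    elif gt is Genotype.HOM_ALT:
        alt = dp - int(rng.binomial(dp, 0.01))
        if dp and alt / dp < 0.9:
            alt = dp
    else:  # hom_ref or missing
        alt = int(rng.binomial(dp, 0.002))
    return dp, gq, dp - alt, alt


def _af_info(pop_afs: dict[str, float]) -> dict[str, str]:
    return {DEFAULT_POP_AF_KEYS[db]: f"{af:g}" for db, af in pop_afs.items()}


def _spike_info(spec: SpikeSpec) -> dict[str, str]:
    info = {
        "GENE": spec.gene,
        "TRANSCRIPT": spec.hgvs_c.split(":", 1)[0],
        "CDNA_POS": str(spec.cdna_pos),
        "HGVSC": spec.hgvs_c,
        "HGVSP": spec.hgvs_p,
        "CSQ_CLASS": spec.consequence.value,
        "CADD": f"{spec.cadd:g}",
        "PRED": spec.predictor_string(),
    }
    info.update(_af_info(spec.pop_afs))
    return info


# ---------------------------------------------------------------------------
# Decoys
# ---------------------------------------------------------------------------

#: Each decoy is a causal-like variant broken in exactly one way. The
#: table rows are (gene, pos-on-contig-2, cdna, hgvs_p tail, tally,
#: cadd); the builder fills in the violation.
_DECOY_CARDS = {
    "qc_fail": ("DECOYQC", 4_500_000, 300, "p.(Thr100Met)", 14, 19, 27.1),
    "common_af": ("DECOYAF", 4_510_000, 150, "p.(Arg50Gln)", 13, 19, 26.0),
    "non_segregating": ("DECOYSEG", 4_520_000, 600, "p.(Gly200Asp)", 12, 19, 24.3),
    "benign_prediction": ("DECOYBENIGN", 4_530_000, 90, "p.(Ala30Val)", 1, 19, 3.2),
    "panel_gene": ("BMPR2", 4_540_000, 1200, "p.(Cys400Arg)", 16, 19, 29.5),
}

DECOY_GENES = {cls: card[0] for cls, card in _DECOY_CARDS.items()}


def _causal_like_gts(
    families: Sequence[tuple[Pedigree, dict[str, Genotype]]],
) -> dict[str, Genotype]:
    """Genotypes that mirror the first family's spike pattern and are
    hom-ref in every other family."""
    gts: dict[str, Genotype] = {}
    for i, (ped, spike_gts) in enumerate(families):
        for sid in ped.sample_ids:
            gts[sid] = spike_gts.get(sid, Genotype.HOM_REF) if i == 0 else Genotype.HOM_REF
    return gts


def _non_segregating_gts(
    families: Sequence[tuple[Pedigree, dict[str, Genotype]]],
) -> dict[str, Genotype]:
    """Affected members hom-ref in every family (so no inheritance model
    fits anywhere); one unaffected founder of the first family carries
    the allele so the site is still variant."""
    gts: dict[str, Genotype] = {}
    carrier_placed = False
    for ped, _ in families:
        for ind in ped.individuals:
            gts[ind.id] = Genotype.HOM_REF
        if not carrier_placed:
            for ind in ped.individuals:
                # a het founder with hom-ref kin stays Mendelian-consistent
                if (
                    ind.affected is Affection.UNAFFECTED
                    and ind.father_id is None
                    and ind.mother_id is None
                ):
                    gts[ind.id] = Genotype.HET
                    carrier_placed = True
                    break
    return gts


def _build_decoys(
    plan: frozenset[str],
    families: Sequence[tuple[Pedigree, dict[str, Genotype]]],
) -> list[_Row]:
    rows: list[_Row] = []
    for j, cls in enumerate(sorted(plan)):
        gene, pos, cdna, hgvs_p, n_dam, n_inf, cadd = _DECOY_CARDS[cls]
        spec = SpikeSpec(
            gene=gene,
            chrom="2",
            pos=pos,
            ref="G",
            alt="T",
            cdna_pos=cdna,
            hgvs_c=f"NM_900{j:03d}.1:c.{cdna}G>T",
            hgvs_p=f"NP_900{j:03d}.1:{hgvs_p}",
            consequence=Consequence.MISSENSE,
            n_damaging=n_dam,
            n_informative=n_inf,
            cadd=cadd,
        )
        info = _spike_info(spec)
        if cls == "common_af":
            info[DEFAULT_POP_AF_KEYS["gnomad_exomes"]] = "0.05"
            info[DEFAULT_POP_AF_KEYS["gnomad_genomes"]] = "0.04"
        if cls == "non_segregating":
            gts = _non_segregating_gts(families)
        else:
            gts = _causal_like_gts(families)
        row = _Row(
            chrom=spec.chrom,
            pos=spec.pos,
            ref=spec.ref,
            alt=spec.alt,
            info=info,
            gts=gts,
            stream_key=(2, j),
        )
        if cls == "qc_fail":
            row.forced_depth = {
                sid: 4 for sid, gt in gts.items() if gt.is_carrier
            }
        rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# Background variants
# ---------------------------------------------------------------------------


def _build_background(
    n: int,
    families: Sequence[tuple[Pedigree, dict[str, Genotype]]],
    seed: int,
) -> list[_Row]:
    rows: list[_Row] = []
    used: set[tuple[str, int]] = set()
    for i in range(n):
        rng = np.random.default_rng([seed % (2**31), 3, i])
        chrom = str(rng.choice(["1", "2"]))
        pos = int(rng.integers(10_000, 4_000_000))
        while (chrom, pos) in used:
            pos = int(rng.integers(10_000, 4_000_000))
        used.add((chrom, pos))
        ref, alt = rng.choice(list(_BASES), size=2, replace=False)

        benign_by_prediction = rng.random() < 0.3
        if benign_by_prediction:
            # novel but predicted harmless
            af = 0.0
            cadd = float(rng.uniform(0, 8))
            codes = ["T"] * 19
        else:
            # ordinary polymorphism above the 1% cutoff
            af = float(np.round(rng.uniform(0.02, 0.30), 4))
            cadd = float(rng.uniform(0, 15))
            n_dam = int(rng.integers(0, 4))
            codes = ["D"] * n_dam + ["T"] * (19 - n_dam)
        csq = str(rng.choice(["missense", "synonymous"]))
        cdna = int(rng.integers(1, 2000))

        carrier_q = af if af > 0 else 0.10
        gts: dict[str, Genotype] = {}
        for ped, _ in families:
            founder_gts = {}
            for ind in ped.individuals:
                if ind.father_id is None and ind.mother_id is None:
                    copies = int(rng.binomial(2, carrier_q))
                    founder_gts[ind.id] = (
                        Genotype.HOM_REF,
                        Genotype.HET,
                        Genotype.HOM_ALT,
                    )[copies]
            slots = [
                _Slot(ind.id, ind.father_id, ind.mother_id, ind.sex)
                for ind in ped.individuals
            ]
            gts.update(_gene_drop(rng, slots, founder_gts))

        info = {
            "GENE": f"BG{i:04d}",
            "CDNA_POS": str(cdna),
            "CSQ_CLASS": csq,
            "CADD": f"{cadd:.2f}",
            "PRED": "|".join(codes),
        }
        info.update(
            {key: f"{af:g}" for key in DEFAULT_POP_AF_KEYS.values()}
        )
        rows.append(
            _Row(
                chrom=chrom,
                pos=pos,
                ref=str(ref),
                alt=str(alt),
                info=info,
                gts=gts,
                stream_key=(3, i),
            )
        )
    return rows


# ---------------------------------------------------------------------------
# VCF assembly
# ---------------------------------------------------------------------------

_GT_FIELD = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.MISSING: "./.",
}

_INFO_HEADER_LINES = [
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
    '##INFO=<ID=TRANSCRIPT,Number=1,Type=String,Description="Transcript accession">',
    '##INFO=<ID=CDNA_POS,Number=1,Type=Integer,Description="1-based coding-sequence position">',
    '##INFO=<ID=HGVSC,Number=1,Type=String,Description="HGVS cDNA description">',
    '##INFO=<ID=HGVSP,Number=1,Type=String,Description="HGVS protein description">',
    '##INFO=<ID=CSQ_CLASS,Number=1,Type=String,Description="Consequence class">',
    '##INFO=<ID=CADD,Number=1,Type=Float,Description="Phred-scaled combined deleteriousness score">',
    '##INFO=<ID=PRED,Number=1,Type=String,Description="Pipe-joined per-tool predictor calls (D/T/.)">',
] + [
    f'##INFO=<ID={key},Number=1,Type=Float,Description="Population allele frequency ({db})">'
    for db, key in DEFAULT_POP_AF_KEYS.items()
]

_FORMAT_HEADER_LINES = [
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
]


def _maybe_corrupt(
    gt: Genotype, seed: int, row_key: tuple[int, int], sample_index: int, rate: float
) -> Genotype:
    """Flip a genotype with probability ``rate``.

    The uniform draw and the replacement choice come from a stream keyed
    only by (seed, row, sample) — not by the rate — so the set of
    corrupted genotypes at a lower rate is a subset of the set at any
    higher rate under the same seed.
    """
    if rate <= 0.0:
        return gt
    rng = np.random.default_rng([seed % (2**31), 4, *row_key, sample_index])
    if rng.random() >= rate:
        return gt
    others = [g for g in (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT) if g is not gt]
    return others[int(rng.integers(0, len(others)))]


def generate_vcf(
    families: Sequence[tuple[Pedigree, dict[str, Genotype]]],
    spikes: Sequence[Optional[SpikeSpec]],
    config: SyntheticFamilyConfig,
    vcf_path: PathLike,
    ped_path: PathLike,
) -> tuple[Path, Path]:
    """Write a multi-sample VCF and the matching PED file.

    ``families`` pairs each pedigree with the spike genotypes simulated
    (or hand-specified) for it; ``spikes[i]`` is the annotation card for
    family *i*'s causal variant, or ``None``. Samples of other families
    are hom-ref at each spike. Decoys and background variants are added
    per ``config``; all sampling is reproducible from ``config.seed``.
    """
    if len(families) != len(spikes):
        raise ValueError("families and spikes must align")
    seed = config.seed

    rows: list[_Row] = []
    for i, ((ped, spike_gts), spec) in enumerate(zip(families, spikes)):
        if spec is None:
            continue
        gts: dict[str, Genotype] = {}
        for k, (other_ped, _) in enumerate(families):
            for sid in other_ped.sample_ids:
                gts[sid] = (
                    spike_gts.get(sid, Genotype.HOM_REF)
                    if k == i
                    else Genotype.HOM_REF
                )
        rows.append(
            _Row(
                chrom=spec.chrom,
                pos=spec.pos,
                ref=spec.ref,
                alt=spec.alt,
                info=_spike_info(spec),
                gts=gts,
                stream_key=(1, i),
            )
        )

    rows.extend(_build_decoys(config.decoy_plan, families))
    rows.extend(_build_background(config.n_background_variants, families, seed))

    contig_order = {c: i for i, c in enumerate(CONTIGS)}
    rows.sort(key=lambda r: (contig_order.get(r.chrom, 99), r.pos))

    samples: list[str] = []
    for ped, _ in families:
        samples.extend(ped.sample_ids)

    vcf_path, ped_path = Path(vcf_path), Path(ped_path)
    with open(vcf_path, "w", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=famprior-simulate\n")
        for contig, length in CONTIGS.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        for line in _INFO_HEADER_LINES + _FORMAT_HEADER_LINES:
            fh.write(line + "\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for row in rows:
            info = ";".join(f"{k}={v}" for k, v in row.info.items())
            fields = [
                row.chrom,
                str(row.pos),
                ".",
                row.ref,
                row.alt,
                "100",
                "PASS",
                info,
                "GT:DP:GQ:AD",
            ]
            for si, sid in enumerate(samples):
                gt = row.gts.get(sid, Genotype.HOM_REF)
                gt = _maybe_corrupt(
                    gt, seed, row.stream_key, si, config.genotype_error_rate
                )
                rng = np.random.default_rng(
                    [seed % (2**31), 5, *row.stream_key, si]
                )
                dp, gq, ad_ref, ad_alt = _sample_call(
                    rng,
                    gt,
                    config.depth_mean,
                    config.depth_dispersion,
                    forced_depth=row.forced_depth.get(sid),
                )
                fields.append(f"{_GT_FIELD[gt]}:{dp}:{gq}:{ad_ref},{ad_alt}")
            fh.write("\t".join(fields) + "\n")

    write_ped([ped for ped, _ in families], ped_path)
    return vcf_path, ped_path


# ---------------------------------------------------------------------------
# Ready-made scenarios
# ---------------------------------------------------------------------------

PANEL_GENES = ("BMPR2", "CAV1", "TBX4", "SOX17", "KDR")

#: Illustrative interaction edges: the two candidate genes, the seed
#: panel, and the NF-kB axis connecting them. This is a small synthetic
#: stand-in for a full interaction-database export.
ILLUSTRATIVE_EDGES = (
    ("TRAF2", "CAV1"),
    ("CAV1", "BMPR2"),
    ("BMPR2", "TBX4"),
    ("TNIP2", "TNFAIP3"),
    ("TNIP2", "NFKB1"),
    ("NFKB1", "RELA"),
    ("TRAF2", "RELA"),
)

ALL_DECOYS = frozenset(_DECOY_CARDS)

_TWO_FAMILY_SEED = 1207


@dataclass(frozen=True)
class FixturePaths:
    vcf: Path
    ped: Path
    config: Path
    panel: Path
    edges: Path


def _write_support_files(
    out_dir: Path,
    models: dict[str, list[str]],
) -> tuple[Path, Path, Path]:
    panel = out_dir / "panel_genes.txt"
    panel.write_text(
        "# known disease-gene panel (stand-in list)\n"
        + "\n".join(PANEL_GENES)
        + "\n"
    )
    edges = out_dir / "interactions.tsv"
    edges.write_text(
        "# illustrative interaction edge list (synthetic stand-in)\n"
        + "\n".join(f"{a}\t{b}" for a, b in ILLUSTRATIVE_EDGES)
        + "\n"
    )
    cfg_path = out_dir / "config.yaml"
    doc = {
        "filters": {
            "min_depth": 10,
            "min_gq": 20,
            "het_ab_range": [0.25, 0.75],
            "min_hom_alt_fraction": 0.85,
            "max_pop_af": 0.01,
        },
        "panel": "panel_genes.txt",
        "models": models,
        "prioritization": {
            "min_damaging_fraction": 0.5,
            "min_cadd": 20.0,
            "max_report_tier": 2,
        },
        "network": {"edges": "interactions.tsv", "seeds": list(PANEL_GENES)},
    }
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return cfg_path, panel, edges


def _family1_fixed() -> tuple[Pedigree, dict[str, Genotype]]:
    """The six-member dominant family with hard-coded carrier states:
    two affected het carriers (index case and her daughter), one
    unaffected het carrier (the index's sibling), three hom-ref
    unaffected relatives. Carrier/affection states are fixed rather than
    sampled — the family's penetrance is unknown, only its realization."""
    slots = _six_member("F1_")
    affected = {"F1_PROBAND", "F1_DAUGHTER"}
    ped = Pedigree(
        family_id="FAM1",
        individuals=[
            Individual(
                id=s.id,
                father_id=s.father,
                mother_id=s.mother,
                sex=s.sex,
                affected=(
                    Affection.AFFECTED if s.id in affected else Affection.UNAFFECTED
                ),
            )
            for s in slots
        ],
    )
    gts = {
        "F1_PROBAND": Genotype.HET,
        "F1_DAUGHTER": Genotype.HET,
        "F1_SIBLING": Genotype.HET,
        "F1_SPOUSE": Genotype.HOM_REF,
        "F1_SON": Genotype.HOM_REF,
        "F1_NIECE": Genotype.HOM_REF,
    }
    return ped, gts


def _family2_fixed() -> tuple[Pedigree, dict[str, Genotype]]:
    """Trio with a de novo variant: affected proband het, both parents
    confidently hom-ref."""
    slots = _trio("F2_")
    ped = Pedigree(
        family_id="FAM2",
        individuals=[
            Individual(
                id=s.id,
                father_id=s.father,
                mother_id=s.mother,
                sex=s.sex,
                affected=(
                    Affection.AFFECTED
                    if s.id == "F2_PROBAND"
                    else Affection.UNAFFECTED
                ),
            )
            for s in slots
        ],
    )
    gts = {
        "F2_FATHER": Genotype.HOM_REF,
        "F2_MOTHER": Genotype.HOM_REF,
        "F2_PROBAND": Genotype.HET,
    }
    return ped, gts


def make_two_family_fixture(
    out_dir: PathLike, seed: int = _TWO_FAMILY_SEED
) -> FixturePaths:
    """Write the two-family worked-example dataset.

    Family 1 (six members, two affected) carries the TNIP2 missense
    spike under dominant inheritance with an unaffected carrier; family
    2 (trio) carries the TRAF2 stop-gain spike de novo. One decoy per
    filter class and a batch of background variants are added. Running
    the pipeline on this dataset must return exactly the two spiked
    variants, the stop-gain ranked first.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fam1 = _family1_fixed()
    fam2 = _family2_fixed()
    config = SyntheticFamilyConfig(
        family_id="FAM1",
        seed=seed,
        pedigree_template="six_member_two_affected",
        model=InheritanceModel.DOMINANT_INCOMPLETE,
        n_background_variants=30,
        decoy_plan=ALL_DECOYS,
    )
    vcf, ped = generate_vcf(
        [fam1, fam2],
        [TNIP2_SPIKE, TRAF2_SPIKE],
        config,
        out_dir / "cohort.vcf",
        out_dir / "cohort.ped",
    )
    cfg, panel, edges = _write_support_files(
        out_dir,
        models={"FAM1": ["dominant_incomplete"], "FAM2": ["de_novo"]},
    )
    return FixturePaths(vcf=vcf, ped=ped, config=cfg, panel=panel, edges=edges)


def build_scenario(
    scenario: str,
    seed: int,
    out_dir: PathLike,
    genotype_error_rate: float = 0.0,
    n_background_variants: int = 10,
    decoy_plan: frozenset[str] = ALL_DECOYS,
) -> FixturePaths:
    """Write a single-family simulated dataset for a named scenario.

    ``two_family`` is the fixed two-family worked example (see
    :func:`make_two_family_fixture`); ``dominant`` simulates the six-member
    family under dominant inheritance with incomplete penetrance;
    ``denovo`` simulates a trio with a de novo spike.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if scenario == "two_family":
        return make_two_family_fixture(out_dir, seed=seed)
    if scenario == "dominant":
        config = SyntheticFamilyConfig(
            family_id="FAM1",
            seed=seed,
            pedigree_template="six_member_two_affected",
            model=InheritanceModel.DOMINANT_INCOMPLETE,
            penetrance=0.8,
            n_background_variants=n_background_variants,
            decoy_plan=decoy_plan,
            genotype_error_rate=genotype_error_rate,
        )
        spike = TNIP2_SPIKE
    elif scenario == "denovo":
        config = SyntheticFamilyConfig(
            family_id="FAM1",
            seed=seed,
            pedigree_template="trio",
            model=InheritanceModel.DE_NOVO,
            n_background_variants=n_background_variants,
            decoy_plan=decoy_plan,
            genotype_error_rate=genotype_error_rate,
        )
        spike = TRAF2_SPIKE
    else:
        raise ValueError(f"unknown scenario {scenario!r}")

    ped_obj, gts = simulate_family(config)
    vcf, ped = generate_vcf(
        [(ped_obj, gts)],
        [spike],
        config,
        out_dir / "cohort.vcf",
        out_dir / "cohort.ped",
    )
    cfg, panel, edges = _write_support_files(
        out_dir, models={"default": ["dominant_incomplete", "de_novo"]}
    )
    return FixturePaths(vcf=vcf, ped=ped, config=cfg, panel=panel, edges=edges)
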