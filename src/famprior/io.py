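"""Readers and writers for the formats the pipeline touches.

VCF parsing is delegated to :mod:`cyvcf2`; everything else (6-column PED,
gene-panel lists, the candidate-report TSV) is plain text. Annotation
INFO keys are not standardized across annotation suites, so the mapping
from INFO keys to the internal :class:`~famprior.types.AnnotationBundle`
fields is itself data: an :class:`AnnotationSchema`, loadable from YAML.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
import yaml
from cyvcf2 import VCF

from .types import (
    Affection,
    Sex,
    AnnotationBundle,
    Candidate,
    CandidateReport,
    Consequence,
    FilterDecision,
    Genotype,
    GenotypeCall,
    Individual,
    Pedigree,
    PedigreeError,
    PredictorCall,
    UNREACHABLE,
    VariantRecord,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

_SEX_FROM_CODE = {"1": "male", "2": "female", "0": "unknown"}
_SEX_TO_CODE = {"male": "1", "female": "2", "unknown": "0"}
_PHENO_FROM_CODE = {"2": "affected", "1": "unaffected", "0": "unknown"}
_PHENO_TO_CODE = {"affected": "2", "unaffected": "1", "unknown": "0"}


def read_pedigrees(path: PathLike) -> dict[str, Pedigree]:
    """Parse a 6-column PED file into one :class:`Pedigree` per family.

    Columns: family, individual, father, mother, sex (1=male, 2=female,
    0=unknown), phenotype (2=affected, 1=unaffected, 0=unknown). A "0"
    parent code means the parent is not in the pedigree (founder side).
    """
    rows: dict[str, list[Individual]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 6:
                raise PedigreeError(
                    f"{path}:{lineno}: expected 6 whitespace-delimited "
                    f"columns, got {len(fields)}"
                )
            fam, iid, father, mother, sex, pheno = fields
            if sex not in _SEX_FROM_CODE:
                raise PedigreeError(f"{path}:{lineno}: bad sex code {sex!r}")
            if pheno not in _PHENO_FROM_CODE:
                raise PedigreeError(
                    f"{path}:{lineno}: bad phenotype code {pheno!r}"
                )
            ind = Individual(
                id=iid,
                father_id=None if father == "0" else father,
                mother_id=None if mother == "0" else mother,
                sex=Sex(_SEX_FROM_CODE[sex]),
                affected=Affection(_PHENO_FROM_CODE[pheno]),
            )
            if fam not in rows:
                rows[fam] = []
                order.append(fam)
            rows[fam].append(ind)
    return {fam: Pedigree(family_id=fam, individuals=rows[fam]) for fam in order}


def read_ped(path: PathLike) -> Pedigree:
    """Parse a PED file that holds exactly one family."""
    peds = read_pedigrees(path)
    if len(peds) != 1:
        raise PedigreeError(
            f"{path}: expected a single family, found {sorted(peds)}"
        )
    return next(iter(peds.values()))


def write_ped(pedigrees: Iterable[Pedigree], path: PathLike) -> None:
    with open(path, "w") as fh:
        for ped in pedigrees:
            for ind in ped.individuals:
                fh.write(
                    "\t".join(
                        [
                            ped.family_id,
                            ind.id,
                            ind.father_id or "0",
                            ind.mother_id or "0",
                            _SEX_TO_CODE[ind.sex.value],
                            _PHENO_TO_CODE[ind.affected.value],
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Annotation schema
# ---------------------------------------------------------------------------

#: Tool labels for the in-silico predictor vector. The published tallies
#: report "m of n tools damaging" without naming the constituent tools, so
#: these labels follow the usual dbNSFP tool roster and are positional only.
DEFAULT_PREDICTOR_TOOLS: tuple[str, ...] = (
    "SIFT",
    "Polyphen2_HDIV",
    "Polyphen2_HVAR",
    "LRT",
    "MutationTaster",
    "MutationAssessor",
    "FATHMM",
    "PROVEAN",
    "MetaSVM",
    "MetaLR",
    "M-CAP",
    "PrimateAI",
    "DEOGEN2",
    "BayesDel_addAF",
    "ClinPred",
    "LIST-S2",
    "REVEL",
    "MVP",
    "MutPred",
)

#: Control population databases checked for novelty.
DEFAULT_POP_AF_KEYS: dict[str, str] = {
    "gnomad_exomes": "AF_GNOMAD_E",
    "gnomad_genomes": "AF_GNOMAD_G",
    "kaviar": "AF_KAVIAR",
    "beacon": "AF_BEACON",
    "bravo": "AF_BRAVO",
    "esp": "AF_ESP",
    "1kg_p3": "AF_1KG",
}


@dataclass
class AnnotationSchema:
    """Mapping from VCF INFO keys to internal annotation fields.

    Any key may be absent from a given VCF: the corresponding annotation
    field is then left missing, never invented. ``predictor_code``
    normalizes each tool's raw call to damaging / tolerated / unknown;
    codes not in the table are treated as unknown.
    """

    gene: str = "GENE"
    transcript: str = "TRANSCRIPT"
    cdna_pos: str = "CDNA_POS"
    hgvs_c: str = "HGVSC"
    hgvs_p: str = "HGVSP"
    consequence: str = "CSQ_CLASS"
    cadd: str = "CADD"
    pop_af_keys: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_POP_AF_KEYS)
    )
    predictor_key: str = "PRED"
    predictor_tools: tuple[str, ...] = DEFAULT_PREDICTOR_TOOLS
    predictor_delim: str = "|"
    predictor_code: dict[str, str] = field(
        default_factory=lambda: {"D": "damaging", "T": "tolerated", ".": "unknown"}
    )

    @classmethod
    def from_dict(cls, d: dict) -> "AnnotationSchema":
        kwargs = dict(d)
        if "predictor_tools" in kwargs:
            kwargs["predictor_tools"] = tuple(kwargs["predictor_tools"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: PathLike) -> "AnnotationSchema":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def parse_predictors(self, raw: Optional[str]) -> dict[str, PredictorCall]:
        """Split a delimiter-joined predictor string into per-tool calls."""
        if raw is None:
            return {}
        parts = str(raw).split(self.predictor_delim)
        calls: dict[str, PredictorCall] = {}
        for i, tool in enumerate(self.predictor_tools):
            if i >= len(parts):
                break
            code = parts[i].strip()
            calls[tool] = PredictorCall(self.predictor_code.get(code, "unknown"))
        return calls


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


class VcfFormatError(ValueError):
    pass


def read_annotated_vcf(
    path: PathLike,
    schema: AnnotationSchema,
    pedigree: Union[Pedigree, Iterable[Pedigree]],
) -> list[VariantRecord]:
    """Read an annotated multi-sample VCF into biallelic records.

    Multiallelic sites are decomposed into one record per ALT allele; for
    a decomposed record, copies of *other* ALT alleles are counted as
    reference. Samples present in the VCF but absent from the pedigree(s)
    are ignored with a warning; a pedigree member missing from the VCF is
    an error. INFO keys named in the schema but absent from a record (or
    from the whole file) leave the annotation field missing.
    """
    peds = [pedigree] if isinstance(pedigree, Pedigree) else list(pedigree)
    wanted: list[str] = []
    for ped in peds:
        wanted.extend(ped.sample_ids)

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise VcfFormatError(f"cannot open VCF {path}: {exc}") from exc

    vcf_samples = list(vcf.samples)
    missing = [s for s in wanted if s not in vcf_samples]
    if missing:
        raise VcfFormatError(
            f"pedigree sample(s) absent from VCF {path}: {missing}"
        )
    extra = [s for s in vcf_samples if s not in set(wanted)]
    if extra:
        logger.warning("ignoring %d VCF sample(s) not in pedigree: %s", len(extra), extra)
    sample_idx = {s: vcf_samples.index(s) for s in wanted}

    records: list[VariantRecord] = []
    for v in vcf:
        n_alts = len(v.ALT)
        if n_alts == 0:
            continue
        dp = _format_matrix(v, "DP")
        gq = _format_matrix(v, "GQ")
        ad = _format_matrix(v, "AD")
        for k, alt in enumerate(v.ALT):
            calls = {}
            for sid, idx in sample_idx.items():
                calls[sid] = _genotype_call(v, sid, idx, k, dp, gq, ad)
            ann = _annotation(v, schema, k, n_alts)
            records.append(
                VariantRecord(
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref=v.REF,
                    alt=alt,
                    calls=calls,
                    annotation=ann,
                )
            )
    return records


def _format_matrix(v, key):
    try:
        return v.format(key)
    except KeyError:
        return None


def _genotype_call(v, sample_id, idx, alt_k, dp, gq, ad) -> GenotypeCall:
    alleles = v.genotypes[idx][:-1]  # last element is the phasing flag
    if any(a < 0 for a in alleles) or not alleles:
        return GenotypeCall(sample_id=sample_id, gt=Genotype.MISSING)
    copies = sum(1 for a in alleles if a == alt_k + 1)
    gt = (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)[min(copies, 2)]

    depth = None
    if dp is not None:
        val = int(dp[idx][0]) if hasattr(dp[idx], "__len__") else int(dp[idx])
        depth = val if val >= 0 else None
    gqual = None
    if gq is not None:
        val = gq[idx][0] if hasattr(gq[idx], "__len__") else gq[idx]
        val = int(val)
        gqual = val if val >= 0 else None
    alt_fraction = None
    if ad is not None:
        row = [int(x) for x in ad[idx] if int(x) >= 0]
        total = sum(row)
        if total > 0 and len(ad[idx]) > alt_k + 1 and int(ad[idx][alt_k + 1]) >= 0:
            alt_fraction = int(ad[idx][alt_k + 1]) / total
    return GenotypeCall(
        sample_id=sample_id, gt=gt, depth=depth, gq=gqual, alt_fraction=alt_fraction
    )


def _per_alt(value, k: int, n_alts: int):
    """Pick the k-th entry of a Number=A INFO value; pass scalars through."""
    if isinstance(value, (tuple, list)):
        return value[k] if len(value) == n_alts else value[0]
    if isinstance(value, str) and n_alts > 1 and value.count(",") == n_alts - 1:
        return value.split(",")[k]
    return value


def _annotation(v, schema: AnnotationSchema, k: int, n_alts: int) -> AnnotationBundle:
    def info(key):
        val = v.INFO.get(key)
        return None if val is None else _per_alt(val, k, n_alts)

    pop_afs: dict[str, float] = {}
    for db, key in schema.pop_af_keys.items():
        val = info(key)
        if val is None:
            continue
        af = float(val)
        if math.isnan(af):
            continue
        pop_afs[db] = af

    cdna = info(schema.cdna_pos)
    cadd = info(schema.cadd)
    csq_raw = info(schema.consequence)
    try:
        consequence = Consequence(str(csq_raw)) if csq_raw is not None else Consequence.UNKNOWN
    except ValueError:
        consequence = Consequence.OTHER

    return AnnotationBundle(
        gene=_opt_str(info(schema.gene)),
        transcript=_opt_str(info(schema.transcript)),
        cdna_pos=int(cdna) if cdna is not None else None,
        hgvs_c=_opt_str(info(schema.hgvs_c)),
        hgvs_p=_opt_str(info(schema.hgvs_p)),
        consequence=consequence,
        pop_afs=pop_afs,
        predictor_calls=schema.parse_predictors(info(schema.predictor_key)),
        cadd=float(cadd) if cadd is not None else None,
    )


def _opt_str(val) -> Optional[str]:
    return None if val is None else str(val)


# ---------------------------------------------------------------------------
# Panel list
# ---------------------------------------------------------------------------


def read_panel(path: PathLike) -> set[str]:
    """One gene symbol per line; '#' comments allowed; symbols uppercased."""
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                genes.add(line.upper())
    return genes


# ---------------------------------------------------------------------------
# Candidate report TSV
# ---------------------------------------------------------------------------

REPORT_COLUMNS = [
    "rank",
    "tier",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "hgvs_c",
    "hgvs_p",
    "consequence",
    "max_pop_af",
    "n_damaging",
    "n_predictors",
    "cadd",
    "segregation_model",
    "affected_carriers",
    "unaffected_carriers",
    "network_distance",
    "filter_trace",
]


def _candidate_row(c: Candidate) -> dict:
    ann = c.variant.annotation
    seg = c.segregation
    if c.network_distance is None:
        nd = UNREACHABLE
    else:
        nd = c.network_distance
    return {
        "rank": c.rank,
        "tier": c.tier,
        "gene": ann.gene or ".",
        "chrom": c.variant.chrom,
        "pos": c.variant.pos,
        "ref": c.variant.ref,
        "alt": c.variant.alt,
        "hgvs_c": ann.hgvs_c or ".",
        "hgvs_p": ann.hgvs_p or ".",
        "consequence": ann.consequence.value,
        "max_pop_af": round(ann.max_pop_af, 6) if ann.max_pop_af is not None else ".",
        "n_damaging": c.assessment.n_damaging if c.assessment else ".",
        "n_predictors": c.assessment.n_informative if c.assessment else ".",
        # single-precision INFO floats round-trip as e.g. 25.799999237
        "cadd": round(ann.cadd, 4) if ann.cadd is not None else ".",
        "segregation_model": seg.model.value if seg else ".",
        "affected_carriers": seg.affected_carriers if seg else ".",
        "unaffected_carriers": seg.unaffected_carriers if seg else ".",
        "network_distance": nd,
        "filter_trace": ";".join(str(d) for d in c.filter_trace),
    }


def write_candidate_report(report: CandidateReport, path: PathLike) -> None:
    """Write the ranked candidates as a tab-separated table."""
    report.validate()
    df = pd.DataFrame(
        [_candidate_row(c) for c in report.candidates], columns=REPORT_COLUMNS
    )
    df.to_csv(path, sep="\t", index=False)


def read_candidate_report(path: PathLike) -> pd.DataFrame:
    """Read a report TSV back (same dialect as the writer)."""
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
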