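"""Pathogenicity assessment, tiering, ranking, and the end-to-end cascade.

Predicted pathogenicity is summarized from two ingredients the VCF
annotation already carries: the vector of per-tool in-silico calls
(dbNSFP-style, reported as "m of n tools damaging") and a phred-scaled
combined deleteriousness score (CADD-style, where >= 20 marks the top 1%
most deleterious substitutions). No score is recomputed here.

Tiers encode a qualitative impact ladder rather than a numeric weight:

* tier 1 — protein-truncating (stop-gain; frameshift/splice would
  qualify if annotated as such),
* tier 2 — missense passing both the damaging-fraction and CADD gates
  (CADD alone when no missense predictor covers the site),
* tier 3 — everything else that survived the hard filters.

Ranking is lexicographic: tier, then CADD descending, then damaging
fraction descending, then genomic coordinate — fully deterministic.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from typing import Optional, Union

from .config import PipelineConfig, PrioritizationConfig, load_config
from .io import PathLike, read_annotated_vcf, read_pedigrees
from .network import load_edge_list, proximity
from .qc import frequency_filter, genotype_passes_qc, panel_prescreen
from .segregation import InheritanceModel, SegregationResult, segregate
from .types import (
    Candidate,
    CandidateReport,
    Consequence,
    FilterDecision,
    Pedigree,
    PredictorCall,
    VariantRecord,
)

logger = logging.getLogger(__name__)


@dataclass
class PathogenicityAssessment:
    """Summary of in-silico evidence for one variant."""

    n_damaging: int
    n_informative: int
    damaging_fraction: Optional[float]  # None when no informative predictor
    cadd: Optional[float]
    consequence: Consequence
    codon: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_damaging > self.n_informative:
            raise ValueError("n_damaging exceeds n_informative")


def aggregate_predictors(
    calls: dict[str, PredictorCall],
) -> tuple[int, int, Optional[float]]:
    """Tally per-tool calls into (n_damaging, n_informative, fraction).

    ``unknown`` calls are excluded from the denominator, so tallies like
    12/19 and 5/9 can coexist under the same tool roster. The fraction is
    undefined (``None``), not zero, when no tool made an informative call.
    """
    n_damaging = sum(1 for c in calls.values() if c is PredictorCall.DAMAGING)
    n_informative = sum(
        1 for c in calls.values() if c is not PredictorCall.UNKNOWN
    )
    fraction = n_damaging / n_informative if n_informative else None
    return n_damaging, n_informative, fraction


def codon_of(cdna_pos: int) -> int:
    """Codon number of a 1-based coding-sequence position: ceil(pos / 3)."""
    if cdna_pos < 1:
        raise ValueError(f"cDNA position must be >= 1, got {cdna_pos}")
    return math.ceil(cdna_pos / 3)


_HGVS_P_RE = re.compile(
    r"""^ (?: [A-Za-z_0-9.]+ : )?      # optional protein accession
        p\. \(?                        # p. prefix, optional '(' for predicted
        (?P<ref>[A-Z][a-z]{2})
        (?P<codon>\d+)
        (?P<alt>[A-Z][a-z]{2} | Ter | \*)
        \)? $""",
    re.VERBOSE,
)


@dataclass(frozen=True)
class ProteinChange:
    ref_aa: str
    codon: int
    alt_aa: str
    consequence: Consequence


def parse_hgvs_p(hgvs_p: str) -> ProteinChange:
    """Parse a protein-level HGVS substitution like ``p.(Ser233Gly)``.

    Stop codons (``Ter``/``*``) classify as stop-gain, identical
    reference and alternate residues as synonymous, anything else as
    missense. Unparseable strings yield an ``unknown`` consequence with a
    warning rather than an error, since annotation text is third-party.
    """
    m = _HGVS_P_RE.match(hgvs_p.strip())
    if m is None:
        logger.warning("unparseable HGVS p. string: %r", hgvs_p)
        return ProteinChange(ref_aa="", codon=0, alt_aa="", consequence=Consequence.UNKNOWN)
    ref, alt = m.group("ref"), m.group("alt")
    if alt in ("Ter", "*"):
        csq = Consequence.STOP_GAIN
    elif alt == ref:
        csq = Consequence.SYNONYMOUS
    else:
        csq = Consequence.MISSENSE
    return ProteinChange(
        ref_aa=ref, codon=int(m.group("codon")), alt_aa=alt, consequence=csq
    )


def assess_variant(variant: VariantRecord) -> PathogenicityAssessment:
    """Build the full assessment, cross-checking HGVS and codon arithmetic."""
    ann = variant.annotation
    n_dam, n_inf, fraction = aggregate_predictors(ann.predictor_calls)
    consequence = ann.consequence
    codon = codon_of(ann.cdna_pos) if ann.cdna_pos is not None else None
    if ann.hgvs_p:
        parsed = parse_hgvs_p(ann.hgvs_p)
        if parsed.consequence is not Consequence.UNKNOWN:
            if consequence is Consequence.UNKNOWN:
                consequence = parsed.consequence
            if codon is not None and parsed.codon != codon:
                logger.warning(
                    "%s:%d %s: HGVS codon %d disagrees with cDNA position "
                    "%d (codon %d)",
                    variant.chrom, variant.pos, ann.hgvs_p,
                    parsed.codon, ann.cdna_pos, codon,
                )
            elif codon is None:
                codon = parsed.codon
    return PathogenicityAssessment(
        n_damaging=n_dam,
        n_informative=n_inf,
        damaging_fraction=fraction,
        cadd=ann.cadd,
        consequence=consequence,
        codon=codon,
    )


#: consequence classes treated as protein-truncating (tier 1)
_TRUNCATING = {Consequence.STOP_GAIN}


def assign_tier(
    assessment: PathogenicityAssessment, config: PrioritizationConfig
) -> int:
    """Impact tier: 1 truncating, 2 damaging missense, 3 the rest.

    A missense variant with no informative predictor is gated on CADD
    alone (truncating variants are sparsely covered by missense
    predictors, and the same logic extends to thinly annotated sites).
    """
    if assessment.consequence in _TRUNCATING:
        return 1
    if assessment.consequence is Consequence.MISSENSE:
        cadd_ok = assessment.cadd is not None and assessment.cadd >= config.min_cadd
        if assessment.damaging_fraction is None:
            if cadd_ok:
                return 2
        elif assessment.damaging_fraction >= config.min_damaging_fraction and cadd_ok:
            return 2
    return 3


def _chrom_key(chrom: str) -> tuple[int, int, str]:
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return (0, int(c), "") if c.isdigit() else (1, 0, c)


def _sort_key(c: Candidate):
    a = c.assessment
    cadd = a.cadd if (a and a.cadd is not None) else -math.inf
    frac = (
        a.damaging_fraction
        if (a and a.damaging_fraction is not None)
        else -math.inf
    )
    return (c.tier, -cadd, -frac, _chrom_key(c.variant.chrom), c.variant.pos)


def rank_candidates(assessed: list[Candidate]) -> list[Candidate]:
    """Sort candidates and assign contiguous ranks from 1."""
    ordered = sorted(assessed, key=_sort_key)
    for i, cand in enumerate(ordered, 1):
        cand.rank = i
    return ordered


# ---------------------------------------------------------------------------
# End-to-end cascade
# ---------------------------------------------------------------------------

STAGE_GENOTYPE_QC = "genotype_qc"
STAGE_PANEL = "panel"
STAGE_SEGREGATION = "segregation"
STAGE_FREQUENCY = "frequency"
STAGE_PATHOGENICITY = "pathogenicity"

#: stages whose failure removes a variant from the candidate list
HARD_STAGES = (STAGE_PANEL, STAGE_SEGREGATION, STAGE_FREQUENCY, STAGE_PATHOGENICITY)


def _segregation_stage(
    variant: VariantRecord,
    pedigrees: dict[str, Pedigree],
    config: PipelineConfig,
) -> tuple[bool, Optional[SegregationResult], str]:
    """Evaluate the configured models family by family.

    A variant is retained if it is compatible with at least one requested
    model in at least one family; the first compatible result (config
    model order, pedigree file order) is reported.
    """
    best: Optional[SegregationResult] = None
    tried: list[str] = []
    for fam_id, ped in pedigrees.items():
        for model in config.models_for(fam_id):
            if model is InheritanceModel.DE_NOVO:
                try:
                    res = segregate(
                        variant, ped, model, config.filters,
                        proband_id=config.proband.get(fam_id),
                    )
                except Exception as exc:  # incomplete trio in this family
                    tried.append(f"{fam_id}/{model.value}:error({exc})")
                    continue
            else:
                res = segregate(variant, ped, model, config.filters)
            if res.compatible:
                return True, res, f"{fam_id}/{model.value}"
            if best is None:
                best = res
            tried.append(f"{fam_id}/{model.value}")
    return False, best, "no compatible model (" + ", ".join(tried) + ")"


def prioritize_records(
    records: list[VariantRecord],
    pedigrees: dict[str, Pedigree],
    config: PipelineConfig,
    verbose_trace: bool = False,
) -> CandidateReport:
    """Run the cascade on already-parsed records.

    Order: genotype QC masking -> panel pre-screen -> segregation ->
    frequency/novelty -> pathogenicity tiering -> ranking. The QC stage
    masks failing genotypes instead of discarding the variant; its trace
    entry records what was masked. Every stage is evaluated for every
    variant so a rejected variant's trace shows all of its failures, not
    just the first.
    """
    fc = config.filters
    all_members = {s for ped in pedigrees.values() for s in ped.sample_ids}

    in_panel_set = {
        rec.key for rec in panel_prescreen(records, fc)[0]
    }

    candidates: list[Candidate] = []
    panel_hits: list[Candidate] = []
    rejected: list[Candidate] = []

    for rec in records:
        trace: list[FilterDecision] = []

        # per-genotype QC: mask, don't discard
        mask: set[str] = set()
        reasons: dict[str, int] = {}
        for sid in sorted(all_members & set(rec.calls)):
            verdict = genotype_passes_qc(rec.calls[sid], fc)
            if not verdict.passed and verdict.reason != "missing":
                mask.add(sid)
                reasons[verdict.reason] = reasons.get(verdict.reason, 0) + 1
        masked_rec = rec.with_masked_calls(mask) if mask else rec
        trace.append(
            FilterDecision(
                STAGE_GENOTYPE_QC,
                passed=not mask,
                reason=(
                    ""
                    if not mask
                    else "masked " + ",".join(f"{k}x{v}" for k, v in sorted(reasons.items()))
                ),
            )
        )

        hit_panel = rec.key in in_panel_set
        trace.append(
            FilterDecision(
                STAGE_PANEL,
                passed=not hit_panel,
                reason="known-gene panel hit" if hit_panel else "",
            )
        )

        seg_ok, seg, seg_reason = _segregation_stage(masked_rec, pedigrees, config)
        trace.append(
            FilterDecision(
                STAGE_SEGREGATION,
                passed=seg_ok,
                reason=seg_reason if seg_ok else seg_reason,
            )
        )

        freq = frequency_filter(rec.annotation, fc)
        max_af = rec.annotation.max_pop_af
        trace.append(
            FilterDecision(
                STAGE_FREQUENCY,
                passed=freq.retained,
                reason=(
                    ("novel" if freq.novel else f"max AF {max_af}")
                    if freq.retained
                    else f"max AF {max_af} above {fc.max_pop_af}"
                ),
            )
        )

        assessment = assess_variant(rec)
        tier = assign_tier(assessment, config.prioritization)
        tier_ok = tier <= config.prioritization.max_report_tier
        trace.append(
            FilterDecision(
                STAGE_PATHOGENICITY,
                passed=tier_ok,
                reason=f"tier {tier}",
            )
        )

        cand = Candidate(
            variant=rec,
            filter_trace=trace,
            segregation=seg,
            tier=tier,
            assessment=assessment,
        )
        if hit_panel:
            panel_hits.append(cand)
        elif cand.passed_all:
            candidates.append(cand)
        elif verbose_trace:
            rejected.append(cand)

    ranked = rank_candidates(candidates)

    if config.network_edges is not None and config.network_seeds:
        graph = load_edge_list(config.network_edges)
        seeds = set(config.network_seeds)
        for cand in ranked:
            gene = cand.variant.annotation.gene
            if gene:
                cand.network_distance = proximity(gene, seeds, graph).distance

    report = CandidateReport(
        candidates=ranked, panel_hits=panel_hits, rejected=rejected
    )
    report.validate()
    return report


def run_prioritization(
    vcf_path: PathLike,
    ped_path: PathLike,
    config: Union[PipelineConfig, PathLike],
    verbose_trace: bool = False,
) -> CandidateReport:
    """Read inputs and run the full prioritization cascade."""
    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    pedigrees = read_pedigrees(ped_path)
    if not pedigrees or all(len(p) == 0 for p in pedigrees.values()):
        raise ValueError(f"empty pedigree file: {ped_path}")
    records = read_annotated_vcf(vcf_path, config.schema, pedigrees.values())
    logger.info(
        "read %d biallelic records across %d families",
        len(records), len(pedigrees),
    )
    return prioritize_records(records, pedigrees, config, verbose_trace=verbose_trace)
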