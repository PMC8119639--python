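"""Hard pre-filters: genotype quality, population frequency, panel screen.

A genotype that fails QC is *masked* (set to missing), never used to
discard the whole variant: segregation downstream decides whether the
remaining genotypes still support an inheritance model. The frequency
filter removes variants whose largest allele frequency across the
configured control databases is strictly above the cutoff (1% by
default); "novel" is the stricter call that every database reports the
variant absent or at frequency exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

from .types import AnnotationBundle, Genotype, GenotypeCall, VariantRecord


@dataclass
class FilterConfig:
    """Thresholds for the hard pre-filters.

    Defaults are the field-standard short-read exome values: depth >= 10,
    GQ >= 20, heterozygous allele balance in [0.25, 0.75], hom-alt
    alternate-read fraction >= 0.85, population AF cutoff 1%.
    """

    min_depth: int = 10
    min_gq: int = 20
    het_ab_range: tuple[float, float] = (0.25, 0.75)
    min_hom_alt_fraction: float = 0.85
    max_pop_af: float = 0.01
    panel_genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        lo, hi = self.het_ab_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"het_ab_range {self.het_ab_range} invalid")
        if not (0.0 <= self.max_pop_af <= 1.0):
            raise ValueError("max_pop_af outside [0, 1]")
        self.panel_genes = frozenset(g.upper() for g in self.panel_genes)


class QCVerdict(NamedTuple):
    passed: bool
    reason: str  # empty when passed; else first violated rule


def genotype_passes_qc(call: GenotypeCall, config: FilterConfig) -> QCVerdict:
    """Check one genotype against depth, GQ and allele-balance rules.

    Fails with the first violated rule in the order missing, depth, gq,
    allele_balance. Allele balance constrains het calls to the configured
    band and hom-alt calls to ``>= min_hom_alt_fraction``; hom-ref calls
    carry no balance constraint here (confidence of reference calls is
    enforced where it matters, in de novo segregation).
    """
    if call.gt is Genotype.MISSING:
        return QCVerdict(False, "missing")
    if call.depth is None or call.depth < config.min_depth:
        return QCVerdict(False, "depth")
    if call.gq is None or call.gq < config.min_gq:
        return QCVerdict(False, "gq")
    if call.gt is Genotype.HET:
        lo, hi = config.het_ab_range
        if call.alt_fraction is None or not (lo <= call.alt_fraction <= hi):
            return QCVerdict(False, "allele_balance")
    elif call.gt is Genotype.HOM_ALT:
        if call.alt_fraction is None or call.alt_fraction < config.min_hom_alt_fraction:
            return QCVerdict(False, "allele_balance")
    return QCVerdict(True, "")


class FrequencyVerdict(NamedTuple):
    retained: bool
    novel: bool


def frequency_filter(
    annotation: AnnotationBundle, config: FilterConfig
) -> FrequencyVerdict:
    """Rare-variant retention and novelty.

    retained: no database reports AF strictly above ``max_pop_af`` (a
    variant at exactly the cutoff survives — the rule removes variants
    *above* it). novel: every database either reports nothing or reports
    an explicit zero.
    """
    max_af = annotation.max_pop_af
    retained = max_af is None or max_af <= config.max_pop_af
    novel = all(af == 0.0 for af in annotation.pop_afs.values())
    return FrequencyVerdict(retained=retained, novel=novel)


def panel_prescreen(
    records: list[VariantRecord], config: FilterConfig
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Split records into (in_panel, outside_panel) by gene symbol.

    Variants in known disease genes are triaged separately — a pathogenic
    hit there would end the exome-wide search — while the rest proceed to
    discovery prioritization. Matching is case-insensitive; records with
    no gene annotation fall outside the panel.
    """
    in_panel: list[VariantRecord] = []
    outside: list[VariantRecord] = []
    for rec in records:
        gene = (rec.annotation.gene or "").upper()
        (in_panel if gene in config.panel_genes else outside).append(rec)
    return in_panel, outside
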