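"""Pipeline configuration: thresholds, per-family models, file pointers.

A single YAML document configures the whole cascade::

    filters:
      min_depth: 10
      min_gq: 20
      het_ab_range: [0.25, 0.75]
      min_hom_alt_fraction: 0.85
      max_pop_af: 0.01
    panel: panel_genes.txt          # path, relative to this file
    models:
      default: [dominant_incomplete, de_novo]
      FAM2: [de_novo]               # per-family override
    proband:
      FAM2: F2_PROBAND              # optional de novo proband override
    prioritization:
      min_damaging_fraction: 0.5
      min_cadd: 20.0
      max_report_tier: 2
    network:
      edges: interactions.tsv
      seeds: [BMPR2, CAV1, TBX4, SOX17, KDR]
    annotation_schema: {...}        # INFO-key mapping, optional

Relative paths are resolved against the directory containing the YAML
file, so a simulated dataset directory is self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from .io import AnnotationSchema, read_panel
from .qc import FilterConfig
from .segregation import InheritanceModel

PathLike = Union[str, Path]

DEFAULT_MODELS = (
    InheritanceModel.DOMINANT_INCOMPLETE,
    InheritanceModel.DE_NOVO,
)


@dataclass
class PrioritizationConfig:
    """Pathogenicity gates and the reporting cutoff.

    ``min_damaging_fraction`` and ``min_cadd`` define tier 2 for missense
    variants; tier 1 is reserved for protein-truncating consequences.
    Variants whose tier exceeds ``max_report_tier`` are dropped from the
    candidate report (predicted-benign survivors are triaged out rather
    than listed).
    """

    min_damaging_fraction: float = 0.5
    min_cadd: float = 20.0
    max_report_tier: int = 2

    def __post_init__(self) -> None:
        if self.min_damaging_fraction < 0 or self.min_cadd < 0:
            raise ValueError("pathogenicity thresholds must be non-negative")


@dataclass
class PipelineConfig:
    filters: FilterConfig = field(default_factory=FilterConfig)
    prioritization: PrioritizationConfig = field(default_factory=PrioritizationConfig)
    schema: AnnotationSchema = field(default_factory=AnnotationSchema)
    #: family_id -> models to evaluate; "default" applies to unlisted families
    models: dict[str, tuple[InheritanceModel, ...]] = field(default_factory=dict)
    #: family_id -> designated de novo proband (optional)
    proband: dict[str, str] = field(default_factory=dict)
    network_edges: Optional[Path] = None
    network_seeds: tuple[str, ...] = ()

    def models_for(self, family_id: str) -> tuple[InheritanceModel, ...]:
        if family_id in self.models:
            return self.models[family_id]
        return self.models.get("default", DEFAULT_MODELS)


def load_config(path: PathLike) -> PipelineConfig:
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    base = path.parent

    def resolve(p: Optional[str]) -> Optional[Path]:
        if p is None:
            return None
        p = Path(p)
        return p if p.is_absolute() else base / p

    filters_kwargs = dict(doc.get("filters", {}))
    if "het_ab_range" in filters_kwargs:
        filters_kwargs["het_ab_range"] = tuple(filters_kwargs["het_ab_range"])
    panel_path = resolve(doc.get("panel"))
    if panel_path is not None:
        filters_kwargs["panel_genes"] = frozenset(read_panel(panel_path))
    filters = FilterConfig(**filters_kwargs)

    prior = PrioritizationConfig(**doc.get("prioritization", {}))

    schema_doc = doc.get("annotation_schema")
    schema = (
        AnnotationSchema.from_dict(schema_doc) if schema_doc else AnnotationSchema()
    )

    models = {
        fam: tuple(InheritanceModel(m) for m in mods)
        for fam, mods in (doc.get("models") or {}).items()
    }

    net = doc.get("network") or {}
    return PipelineConfig(
        filters=filters,
        prioritization=prior,
        schema=schema,
        models=models,
        proband=dict(doc.get("proband") or {}),
        network_edges=resolve(net.get("edges")),
        network_seeds=tuple(net.get("seeds") or ()),
    )
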