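"""Offline interaction-network triage for candidate genes.

A user-supplied two-column edge list (e.g., an export from a
protein–protein interaction resource) becomes an undirected, unweighted
graph; candidate genes are scored by breadth-first shortest-path
distance to the nearest member of a seed set of established disease
genes. Proximity is supporting context only — it annotates the candidate
report and is never used as a hard filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import networkx as nx

logger = logging.getLogger(__name__)


class EdgeListFormatError(ValueError):
    pass


def load_edge_list(path: Union[str, Path]) -> nx.Graph:
    """Read a two-column edge list into an undirected simple graph.

    Gene symbols are uppercased; duplicate edges collapse; self-loops are
    dropped with a warning; '#' starts a comment.
    """
    graph = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 2:
                raise EdgeListFormatError(
                    f"{path}:{lineno}: expected two gene symbols, got "
                    f"{len(fields)} field(s)"
                )
            a, b = (f.upper() for f in fields)
            if a == b:
                logger.warning("%s:%d: dropping self-loop %s-%s", path, lineno, a, b)
                continue
            graph.add_edge(a, b)
    return graph


@dataclass(frozen=True)
class Proximity:
    distance: Optional[int]  # None = unreachable (or gene absent from graph)
    nearest_seed: Optional[str]

    @property
    def reachable(self) -> bool:
        return self.distance is not None


def proximity(gene: str, seeds: Iterable[str], graph: nx.Graph) -> Proximity:
    """Shortest-path distance from ``gene`` to the nearest seed gene.

    A gene that is itself a seed scores 0 even if absent from the graph;
    a non-seed gene absent from the graph is unreachable. Ties between
    equally near seeds break alphabetically.
    """
    gene = gene.upper()
    seed_set = {s.upper() for s in seeds}
    if not seed_set:
        raise ValueError("seed set must be non-empty")
    if gene in seed_set:
        return Proximity(distance=0, nearest_seed=gene)
    if gene not in graph:
        return Proximity(distance=None, nearest_seed=None)
    lengths = nx.single_source_shortest_path_length(graph, gene)
    best: Optional[tuple[int, str]] = None
    for seed in sorted(seed_set):
        if seed in lengths:
            d = lengths[seed]
            if best is None or d < best[0]:
                best = (d, seed)
    if best is None:
        return Proximity(distance=None, nearest_seed=None)
    return Proximity(distance=best[0], nearest_seed=best[1])
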