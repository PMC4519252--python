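"""PPI subnetwork construction, topology, and DIF gene prioritization.

The decidualization subnetwork is the induced subgraph of a
genome-scale interaction table on the mined gene set, with edges
undirected, self-interactions excluded from degree, and isolated genes
dropped (but reported). Degree is the number of distinct neighbors.
Each gene is scored by the decidualization impact factor,
DIF = degree x number of supporting publications, and genes whose DIF
strictly exceeds mean + 2 standard deviations over the network's nodes
are selected as candidate key regulators. Scale-freeness is assessed
by a least-squares line on the log-log degree histogram.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionTable",
    "GeneNetwork",
    "DegreeDistribution",
    "PowerLawFit",
    "DifRecord",
    "PrioritizationResult",
    "load_interactions",
    "induce_network",
    "degree_map",
    "fit_power_law",
    "compute_dif",
    "prioritize_genes",
]


@dataclass
class InteractionTable:
    """Canonicalized undirected edge list."""

    edges: list[tuple[str, str, str]]  # (a, b, source tag), a < b
    self_pairs: list[str] = field(default_factory=list)
    n_duplicates: int = 0


def _first_identifier(mitab_field: str) -> str:
    # MITAB identifier fields look like "uniprotkb:P12345|other:x";
    # take the id part of the first entry.
    first = mitab_field.split("|")[0]
    return first.split(":", 1)[1] if ":" in first else first


def load_interactions(
    path: str | Path,
    id_map: Mapping[str, str] | None = None,
    strict: bool = True,
    source_tag: str | None = None,
) -> InteractionTable:
    """Load a two-column TSV or MITAB 2.5 file into a canonical edge list.

    Endpoint pairs are sorted, duplicates collapsed (count logged),
    self-pairs flagged but kept out of the edge list. In strict mode an
    unparseable line raises with its line number; in lenient mode it is
    skipped and logged.
    """
    path = Path(path)
    tag = source_tag or path.name
    seen: set[tuple[str, str]] = set()
    edges: list[tuple[str, str, str]] = []
    self_pairs: list[str] = []
    n_dup = 0
    for line_no, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
            if strict:
                raise ValueError(f"{path}:{line_no}: expected two identifier columns")
            logger.warning("%s:%d: unparseable line skipped", path, line_no)
            continue
        a, b = (_first_identifier(parts[0].strip()), _first_identifier(parts[1].strip()))
        if id_map is not None:
            a, b = id_map.get(a, a), id_map.get(b, b)
        if a == b:
            self_pairs.append(a)
            continue
        pair = (a, b) if a < b else (b, a)
        if pair in seen:
            n_dup += 1
            continue
        seen.add(pair)
        edges.append((*pair, tag))
    if n_dup:
        logger.info("%s: collapsed %d duplicate edges", path, n_dup)
    edges.sort()
    return InteractionTable(edges=edges, self_pairs=sorted(set(self_pairs)), n_duplicates=n_dup)


@dataclass
class GeneNetwork:
    """Undirected interaction subgraph on the mined genes.

    Isolated genes (no interaction partner inside the gene set) are not
    nodes; they are reported in ``isolated``.
    """

    graph: nx.Graph
    isolated: set[str] = field(default_factory=set)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def induce_network(genes: Iterable[str], interactions: InteractionTable) -> GeneNetwork:
    """Induced subgraph: keep edges with both endpoints in the gene set."""
    gene_set = set(genes)
    graph = nx.Graph()
    for a, b, tag in interactions.edges:
        if a in gene_set and b in gene_set:
            graph.add_edge(a, b, source=tag)
    isolated = gene_set - set(graph.nodes)
    if isolated:
        logger.info("%d genes isolated (no internal interaction)", len(isolated))
    return GeneNetwork(graph=graph, isolated=isolated)


@dataclass
class DegreeDistribution:
    degrees: dict[str, int]
    histogram: dict[int, int]


def degree_map(network: GeneNetwork) -> DegreeDistribution:
    degrees = {node: int(d) for node, d in network.graph.degree()}
    histogram: dict[int, int] = {}
    for d in degrees.values():
        histogram[d] = histogram.get(d, 0) + 1
    return DegreeDistribution(degrees=degrees, histogram=histogram)


@dataclass
class PowerLawFit:
    gamma: float
    prefactor: float
    r_squared: float


def fit_power_law(dist: DegreeDistribution) -> PowerLawFit:
    """Least-squares fit of log(count) on log(degree) over occupied bins.

    Returns the exponent gamma (negated slope), the prefactor, and the
    r-squared of the log-log line.
    """
    points = [(d, c) for d, c in sorted(dist.histogram.items()) if d >= 1 and c >= 1]
    if len(points) < 2:
        raise ValueError("power-law fit needs at least two distinct degree values")
    x = np.log(np.array([d for d, _ in points], dtype=float))
    y = np.log(np.array([c for _, c in points], dtype=float))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return PowerLawFit(gamma=float(-slope), prefactor=float(math.exp(intercept)), r_squared=r2)


@dataclass
class DifRecord:
    gene_id: str
    degree: int
    n_pubs: int
    dif: int
    selected: bool = False


def compute_dif(network: GeneNetwork, pubcounts: Mapping[str, int]) -> list[DifRecord]:
    """DIF = degree x publication count, exact integer arithmetic."""
    records = []
    degrees = degree_map(network).degrees
    for gene_id in sorted(degrees):
        n_pubs = pubcounts.get(gene_id)
        if n_pubs is None:
            logger.warning("no publication count for %s; using 0", gene_id)
            n_pubs = 0
        if n_pubs < 0:
            raise ValueError(f"negative publication count for {gene_id}")
        records.append(
            DifRecord(gene_id=gene_id, degree=degrees[gene_id], n_pubs=n_pubs, dif=degrees[gene_id] * n_pubs)
        )
    return records


@dataclass
class PrioritizationResult:
    threshold: float
    mean: float
    sd: float
    records: list[DifRecord]

    @property
    def selected(self) -> list[DifRecord]:
        return [r for r in self.records if r.selected]


def prioritize_genes(records: list[DifRecord], ddof: int = 1) -> PrioritizationResult:
    """Select genes whose DIF strictly exceeds mean + 2 sd.

    The standard deviation is the sample flavor by default (ddof=1,
    configurable); selection uses strict inequality ("exceeding" the
    threshold). Output sorted by DIF descending, ties by gene id.
    """
    if len(records) < 2:
        raise ValueError("threshold undefined for fewer than two records")
    difs = np.array([r.dif for r in records], dtype=float)
    mean = float(difs.mean())
    sd = float(difs.std(ddof=ddof))
    threshold = mean + 2.0 * sd
    out = [
        DifRecord(r.gene_id, r.degree, r.n_pubs, r.dif, selected=r.dif > threshold)
        for r in records
    ]
    out.sort(key=lambda r: (-r.dif, r.gene_id))
    return PrioritizationResult(threshold=threshold, mean=mean, sd=sd, records=out)


def write_edge_list(network: GeneNetwork, path: str | Path) -> None:
    lines = [f"{a}\t{b}" for a, b in sorted(map(lambda e: tuple(sorted(e)), network.graph.edges))]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_sif(network: GeneNetwork, path: str | Path, relation: str = "pp") -> None:
    """Plain SIF export for Cytoscape viewing."""
    lines = [
        f"{a}\t{relation}\t{b}"
        for a, b in sorted(map(lambda e: tuple(sorted(e)), network.graph.edges))
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
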