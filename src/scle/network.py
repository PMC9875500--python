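"""Template network construction from a PPI edge list.

The global template network is the undirected PPI graph restricted to
measured genes, with isolated nodes discarded; the scoring unit is the
local (ego) network of a gene and its first-order neighbors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

logger = logging.getLogger(__name__)

_HEADER_TOKENS = {
    "protein1", "protein2", "gene1", "gene2", "node1", "node2",
    "combined_score", "score", "source", "target",
}


@dataclass
class TemplateNetwork:
    """The measured-gene PPI graph (undirected, no self-loops, no isolates)."""

    graph: nx.Graph
    provenance: dict

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(sorted(self.graph.nodes))

    @property
    def node_set(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(tuple(sorted(e)) for e in self.graph.edges)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors(self, gene: str) -> tuple[str, ...]:
        return tuple(sorted(self.graph.neighbors(gene)))

    def degree(self, gene: str) -> int:
        return self.graph.degree(gene)


@dataclass(frozen=True)
class LocalNetwork:
    """A center gene with its first-order neighbors (lexicographically sorted)."""

    center: str
    neighbors: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.center in self.neighbors:
            raise ValueError(f"center {self.center!r} appears among its neighbors")
        if len(self.neighbors) < 1:
            raise ValueError(f"gene {self.center!r} has no neighbors")
        if tuple(sorted(self.neighbors)) != self.neighbors:
            object.__setattr__(self, "neighbors", tuple(sorted(self.neighbors)))

    @property
    def Q(self) -> int:
        return len(self.neighbors)


def load_edge_list(
    path: str | Path,
    score_column: str | None = None,
    min_score: float | None = None,
) -> set[tuple[str, str]]:
    """Read an undirected edge list (STRING-export dialect).

    Whitespace- or tab-delimited, two gene-symbol columns plus optional
    numeric score columns; a header row is auto-detected.  Symmetric
    duplicates are collapsed, self-loops dropped (logged), and edges with
    score below ``min_score`` removed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"edge list not found: {path}")
    with open(path) as fh:
        lines = fh.readlines()
    if not lines:
        raise ValueError(f"edge list {path} is empty")

    first = lines[0].split()
    has_header = any(tok.lower() in _HEADER_TOKENS for tok in first)
    score_idx: int | None = None
    if min_score is not None:
        if score_column is None:
            raise ValueError("min_score given but no score_column named")
        if has_header:
            try:
                score_idx = first.index(score_column)
            except ValueError:
                raise ValueError(
                    f"score column {score_column!r} not found in header {first}"
                ) from None
        else:
            score_idx = 2  # STRING convention: third column
    start = 1 if has_header else 0

    edges: set[tuple[str, str]] = set()
    self_loops = 0
    filtered = 0
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"malformed edge-list row at line {lineno}: {line.strip()!r}")
        a, b = parts[0].strip(), parts[1].strip()
        if score_idx is not None:
            if len(parts) <= score_idx:
                raise ValueError(
                    f"missing score at line {lineno}: {line.strip()!r}"
                )
            try:
                score = float(parts[score_idx])
            except ValueError:
                raise ValueError(
                    f"non-numeric score {parts[score_idx]!r} at line {lineno}"
                ) from None
            if score < min_score:
                filtered += 1
                continue
        if a == b:
            self_loops += 1
            continue
        edges.add((a, b) if a <= b else (b, a))
    if self_loops:
        logger.info("dropped %d self-loop edges", self_loops)
    if filtered:
        logger.info("filtered %d edges below min_score=%s", filtered, min_score)
    return edges


def build_template_network(
    edges: set[tuple[str, str]],
    measured_genes,
    provenance: dict | None = None,
) -> TemplateNetwork:
    """Restrict edges to measured genes and drop nodes left isolated.

    Restriction happens first, so "isolated" means isolated within the
    measured subgraph; by construction every surviving node is an endpoint
    of a surviving edge.
    """
    measured = {str(g).strip() for g in measured_genes}
    kept = [
        (a, b)
        for a, b in edges
        if a in measured and b in measured
    ]
    dropped_edges = len(edges) - len(kept)
    if dropped_edges:
        logger.info(
            "dropped %d edges with unmeasured endpoints (%d kept)",
            dropped_edges, len(kept),
        )
    g = nx.Graph()
    g.add_edges_from(kept)
    if g.number_of_nodes() == 0:
        raise ValueError("template network is empty after restriction to measured genes")
    prov = dict(provenance or {})
    prov.setdefault("n_input_edges", len(edges))
    prov.setdefault("n_kept_edges", len(kept))
    return TemplateNetwork(graph=g, provenance=prov)


def local_network(network: TemplateNetwork, gene: str) -> LocalNetwork:
    """The first-order ego network of ``gene`` in the template network."""
    if gene not in network.graph:
        raise KeyError(f"gene {gene!r} is not in the template network")
    return LocalNetwork(center=gene, neighbors=network.neighbors(gene))


def write_edge_list_tsv(network: TemplateNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein1\tprotein2\n")
        for a, b in sorted(network.edges):
            fh.write(f"{a}\t{b}\n")
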