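"""Signed directed molecular interaction maps (MIMs).

A MIM is a curated signed digraph whose nodes are either molecular species
(collapsed here to class ``gene``) or ``phenotype`` readouts -- sink nodes
representing inflammatory processes such as NETosis or apoptotic cell
clearance.  Edges carry a sign: +1 for activation, -1 for inhibition.

Phenotype nodes are readouts, never regulators: any edge leaving a phenotype
node is dropped at construction with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

#: SIF interaction vocabulary.  The downstream math only consumes a binary
#: sign, so the vocabulary is deliberately restricted.
INTERACTIONS: Mapping[str, int] = {"activates": 1, "inhibits": -1}
_SIGN_TO_WORD = {1: "activates", -1: "inhibits"}

PHASES = ("initiation", "transition", "resolution", "homeostasis")


class MapParseError(ValueError):
    """Raised on malformed SIF / node-attribute input."""


class MapValidationError(ValueError):
    """Raised when a map violates its structural invariants."""


def normalize_symbol(symbol: str) -> str:
    """Case-insensitive gene-symbol key used to match DEG tables to the map."""
    return symbol.strip().upper()


@dataclass(frozen=True)
class MIMNode:
    id: str
    label: str = ""
    node_class: str = "gene"  # "gene" or "phenotype"
    submaps: frozenset = field(default_factory=frozenset)
    phase: str | None = None

    def __post_init__(self):
        if self.node_class not in ("gene", "phenotype"):
            raise MapValidationError(
                f"node {self.id!r}: unknown node_class {self.node_class!r}"
            )
        if self.phase is not None and self.phase not in PHASES:
            raise MapValidationError(
                f"node {self.id!r}: unknown phase {self.phase!r}"
            )


@dataclass(frozen=True)
class MIMEdge:
    source: str
    target: str
    sign: int

    def __post_init__(self):
        if self.sign not in (1, -1):
            raise MapValidationError(
                f"edge {self.source}->{self.target}: sign must be +1 or -1, "
                f"got {self.sign!r}"
            )


class MolecularInteractionMap:
    """Validated signed digraph of gene and phenotype nodes.

    Backed by a :class:`networkx.DiGraph` with node attributes
    ``label``, ``node_class``, ``submaps`` (frozenset), ``phase`` and edge
    attribute ``sign``.
    """

    def __init__(self, nodes: Iterable[MIMNode], edges: Iterable[MIMEdge]):
        g = nx.DiGraph()
        for n in nodes:
            if n.id in g:
                raise MapValidationError(f"duplicate node id {n.id!r}")
            g.add_node(
                n.id,
                label=n.label or n.id,
                node_class=n.node_class,
                submaps=n.submaps,
                phase=n.phase,
            )
        seen: set[tuple[str, str]] = set()
        n_dropped = 0
        for e in edges:
            if (e.source, e.target) in seen:
                raise MapValidationError(
                    f"duplicate edge ({e.source!r}, {e.target!r})"
                )
            seen.add((e.source, e.target))
            for endpoint in (e.source, e.target):
                if endpoint not in g:
                    raise MapValidationError(
                        f"edge endpoint {endpoint!r} not among nodes"
                    )
            if g.nodes[e.source]["node_class"] == "phenotype":
                # phenotypes are readouts; they do not regulate
                n_dropped += 1
                continue
            g.add_edge(e.source, e.target, sign=int(e.sign))
        if n_dropped:
            logger.warning(
                "dropped %d edge(s) leaving phenotype nodes "
                "(phenotypes are sinks)", n_dropped,
            )
        self.graph = g
        # case-insensitive symbol lookup for DEG-table matching
        self._symbol_index = {normalize_symbol(n): n for n in g.nodes}

    # -- basic accessors ---------------------------------------------------

    @property
    def genes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True)
                if d["node_class"] == "gene"}

    @property
    def phenotypes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True)
                if d["node_class"] == "phenotype"}

    def node_class(self, node_id: str) -> str:
        return self.graph.nodes[node_id]["node_class"]

    def phase(self, node_id: str) -> str | None:
        return self.graph.nodes[node_id].get("phase")

    def sign(self, source: str, target: str) -> int:
        return self.graph.edges[source, target]["sign"]

    def resolve_symbol(self, symbol: str) -> str | None:
        """Map a gene symbol (any case) to a node id, or None if absent."""
        return self._symbol_index.get(normalize_symbol(symbol))

    def nodes(self) -> list[MIMNode]:
        return [
            MIMNode(
                id=n,
                label=d["label"],
                node_class=d["node_class"],
                submaps=d["submaps"],
                phase=d.get("phase"),
            )
            for n, d in sorted(self.graph.nodes(data=True))
        ]

    def edges(self) -> list[MIMEdge]:
        return [
            MIMEdge(u, v, d["sign"])
            for u, v, d in sorted(self.graph.edges(data=True))
        ]

    def __repr__(self) -> str:
        return (
            f"<MolecularInteractionMap | {len(self.genes)} genes, "
            f"{len(self.phenotypes)} phenotypes, "
            f"{self.graph.number_of_edges()} edges>"
        )

    # -- subgraph helpers used by propagation/motif code -------------------

    def gene_subgraph(self) -> nx.DiGraph:
        """The induced subgraph on gene-class nodes (phenotype-free)."""
        return self.graph.subgraph(self.genes)

    def admissible_subgraph(self, phenotype_id: str) -> nx.DiGraph:
        """Genes plus one phenotype: the node set on which paths into
        ``phenotype_id`` may run (other phenotypes block propagation)."""
        return self.graph.subgraph(self.genes | {phenotype_id})


# ---------------------------------------------------------------------------
# Operations


def submap_genes(mim: MolecularInteractionMap,
                 submap_names: Iterable[str]) -> set[str]:
    """Gene nodes whose submap annotation intersects ``submap_names``."""
    names = set(submap_names)
    if not names:
        raise ValueError("submap_names must be non-empty")
    known = set()
    for _, d in mim.graph.nodes(data=True):
        known |= d["submaps"]
    unknown = names - known
    if unknown:
        logger.warning("unknown submap name(s): %s", sorted(unknown))
    return {
        n for n, d in mim.graph.nodes(data=True)
        if d["node_class"] == "gene" and d["submaps"] & names
    }


def upstream_gene_universe(mim: MolecularInteractionMap, phenotype_id: str,
                           max_depth: int) -> set[str]:
    """Genes with a phenotype-free directed path into ``phenotype_id`` of
    length <= ``max_depth`` edges.

    Other phenotype nodes block paths: a regulator acting only through a
    second phenotype readout is not upstream of this one.
    """
    if phenotype_id not in mim.graph:
        raise KeyError(f"unknown node {phenotype_id!r}")
    if mim.node_class(phenotype_id) != "phenotype":
        raise ValueError(f"{phenotype_id!r} is not a phenotype node")
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    genes = mim.genes
    universe: set[str] = set()
    frontier = {phenotype_id}
    for _ in range(max_depth):
        nxt = set()
        for node in frontier:
            for pred in mim.graph.predecessors(node):
                if pred in genes and pred not in universe:
                    universe.add(pred)
                    nxt.add(pred)
        if not nxt:
            break
        frontier = nxt
    return universe


# ---------------------------------------------------------------------------
# I/O


def read_map(edge_file: str | Path,
             node_attr_file: str | Path | None = None) -> MolecularInteractionMap:
    """Read a map from a SIF edge list and an optional node-attribute table.

    SIF dialect: three tab-separated columns per line,
    ``source  interaction  target`` with interaction in
    ``{activates, inhibits}``; no header.  The node-attribute file is TSV
    with header ``id  label  node_class  submaps  phase`` where submaps is
    semicolon-joined.  Nodes seen only in the edge file default to class
    ``gene`` (logged).
    """
    nodes: dict[str, MIMNode] = {}
    if node_attr_file is not None:
        nodes = _read_node_attrs(node_attr_file)

    edges: list[MIMEdge] = []
    edge_path = Path(edge_file)
    with edge_path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise MapParseError(
                    f"{edge_path.name}:{lineno}: expected 3 tab-separated "
                    f"fields, got {len(parts)}"
                )
            source, interaction, target = (p.strip() for p in parts)
            if interaction not in INTERACTIONS:
                raise MapParseError(
                    f"{edge_path.name}:{lineno}: unsupported interaction "
                    f"{interaction!r} (expected one of "
                    f"{sorted(INTERACTIONS)})"
                )
            edges.append(MIMEdge(source, target, INTERACTIONS[interaction]))

    n_defaulted = 0
    for e in edges:
        for endpoint in (e.source, e.target):
            if endpoint not in nodes:
                nodes[endpoint] = MIMNode(id=endpoint)
                n_defaulted += 1
    if n_defaulted:
        logger.warning(
            "%d node(s) appeared only in the edge file; defaulted to class "
            "'gene'", n_defaulted,
        )
    return MolecularInteractionMap(nodes.values(), edges)


def _read_node_attrs(path: str | Path) -> dict[str, MIMNode]:
    path = Path(path)
    nodes: dict[str, MIMNode] = {}
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["id", "label", "node_class", "submaps", "phase"]
        if [h.strip() for h in header] != expected:
            raise MapParseError(
                f"{path.name}:1: expected header {expected}, got {header}"
            )
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise MapParseError(
                    f"{path.name}:{lineno}: expected 5 fields, got "
                    f"{len(parts)}"
                )
            node_id, label, node_class, submaps, phase = (
                p.strip() for p in parts)
            if node_id in nodes:
                raise MapValidationError(
                    f"{path.name}:{lineno}: duplicate node id {node_id!r}"
                )
            nodes[node_id] = MIMNode(
                id=node_id,
                label=label,
                node_class=node_class or "gene",
                submaps=frozenset(
                    s for s in submaps.split(";") if s),
                phase=phase or None,
            )
    return nodes


def write_map(mim: MolecularInteractionMap, edge_file: str | Path,
              node_attr_file: str | Path) -> None:
    """Write SIF edge list and node-attribute TSV (inverse of read_map)."""
    with Path(edge_file).open("w") as fh:
        for e in mim.edges():
            fh.write(f"{e.source}\t{_SIGN_TO_WORD[e.sign]}\t{e.target}\n")
    with Path(node_attr_file).open("w") as fh:
        fh.write("id\tlabel\tnode_class\tsubmaps\tphase\n")
        for n in mim.nodes():
            fh.write(
                f"{n.id}\t{n.label}\t{n.node_class}\t"
                f"{';'.join(sorted(n.submaps))}\t{n.phase or ''}\n"
            )


def to_graphml(graph_or_map, path: str | Path) -> None:
    """Export a map or any digraph to GraphML (Cytoscape-readable)."""
    g = (graph_or_map if isinstance(graph_or_map, nx.DiGraph)
         else graph_or_map.graph)
    out = nx.DiGraph()
    for n, d in g.nodes(data=True):
        attrs = {k: v for k, v in d.items() if v is not None}
        if isinstance(attrs.get("submaps"), frozenset):
            attrs["submaps"] = ";".join(sorted(attrs["submaps"]))
        out.add_node(n, **attrs)
    for u, v, d in g.edges(data=True):
        out.add_edge(u, v, **d)
    nx.write_graphml(out, str(path))
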