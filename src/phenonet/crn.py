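"""Core regulatory network (CRN) extraction by Pareto-ranked feedback loops.

A motif is a gene-triplet feedback loop: a directed simple 3-cycle among
genes upstream of a chosen phenotype.  Each motif carries three features,

    F_I  = sum over members i of I(i, p)      (net influence on p)
    F_ES = sum over members i of ES(i)        (upstream enrichment)
    F_FC = sum over members i of |log2FC_i|   (expression change; missing -> 0)

which are min-max normalized over the candidate population and combined
into a weighted score per weighting scenario j:

    S_j = w1j * F_I + w2j * F_ES + w3j * F_FC,   w in {0.33, 0.66, 1.0}.

Sweeping all 27 weight scenarios and taking the union of each scenario's
top-m motifs yields a Pareto-style set of loops that excel under at least
one feature weighting; merging their nodes and edges gives the CRN.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd

from .influence import InfluenceMatrix
from .mim import MolecularInteractionMap, upstream_gene_universe
from .overlay import OverlaySet

logger = logging.getLogger(__name__)

WEIGHT_VALUES = (0.33, 0.66, 1.0)
#: The full 27-scenario grid of (w1, w2, w3).
WEIGHT_GRID: tuple[tuple[float, float, float], ...] = tuple(
    itertools.product(WEIGHT_VALUES, repeat=3))


@dataclass(frozen=True)
class Motif:
    """A directed 3-cycle of genes with its raw and normalized features."""

    nodes: tuple[str, ...]              # sorted member ids
    edges: frozenset                    # {(u, v, sign)} of the cycle
    f_influence: float
    f_enrichment: float
    f_foldchange: float
    norm: tuple[float, float, float] | None = None

    @property
    def key(self) -> tuple:
        """Deterministic identity/tie-break key."""
        return (self.nodes, tuple(sorted(self.edges)))


def enumerate_motifs(mim: MolecularInteractionMap, phenotype_id: str,
                     infl: InfluenceMatrix,
                     es: pd.Series | None = None,
                     fc: pd.Series | None = None,
                     max_candidates: int | None = 20000) -> list[Motif]:
    """All gene-triplet feedback loops upstream of a phenotype.

    Cycles run within the phenotype's upstream gene universe at the
    influence parameters' depth; self-loops never participate.  Two opposite
    orientations on the same three nodes are distinct motifs (distinct edge
    sets).  When more than ``max_candidates`` cycles exist, the list is
    truncated by descending F_I with a lexicographic node-id tie-break.
    """
    universe = upstream_gene_universe(
        mim, phenotype_id, infl.params.max_depth)
    sub = nx.DiGraph(
        (u, v, d) for u, v, d in mim.graph.edges(data=True)
        if u in universe and v in universe and u != v)
    motifs: list[Motif] = []
    for cycle in nx.simple_cycles(sub, length_bound=3):
        if len(cycle) != 3:
            continue
        a, b, c = cycle
        edges = frozenset({
            (a, b, sub.edges[a, b]["sign"]),
            (b, c, sub.edges[b, c]["sign"]),
            (c, a, sub.edges[c, a]["sign"]),
        })
        members = tuple(sorted(cycle))
        f_i = sum(infl.score(m, phenotype_id) for m in members)
        f_es = (sum(float(es.get(m, 0.0)) for m in members)
                if es is not None else 0.0)
        f_fc = (sum(abs(float(fc.get(m, 0.0))) for m in members)
                if fc is not None else 0.0)
        motifs.append(Motif(members, edges, f_i, f_es, f_fc))
    motifs.sort(key=lambda m: (-m.f_influence, m.key))
    if max_candidates is not None and len(motifs) > max_candidates:
        logger.warning(
            "motif population truncated from %d to %d by descending F_I",
            len(motifs), max_candidates,
        )
        motifs = motifs[:max_candidates]
    return motifs


def normalize_features(motifs: list[Motif]) -> list[Motif]:
    """Min-max normalize each feature over the population to [0, 1].

    A feature constant across the population maps to 0.5 for every motif
    (no discriminating information, neutral weight contribution).
    """
    if not motifs:
        raise ValueError("cannot normalize an empty motif population")
    raw = np.array([
        (m.f_influence, m.f_enrichment, m.f_foldchange) for m in motifs])
    lo, hi = raw.min(axis=0), raw.max(axis=0)
    span = hi - lo
    normed = np.where(span > 0, (raw - lo) / np.where(span > 0, span, 1.0),
                      0.5)
    return [replace(m, norm=tuple(float(x) for x in row))
            for m, row in zip(motifs, normed)]


def score_motif(motif: Motif,
                scenario: tuple[float, float, float]) -> float:
    """Weighted sum S_j of the motif's normalized features."""
    if motif.norm is None:
        raise ValueError("motif features must be normalized before scoring")
    w1, w2, w3 = scenario
    n1, n2, n3 = motif.norm
    return w1 * n1 + w2 * n2 + w3 * n3


def pareto_select(motifs: list[Motif], top_m: int = 5) -> list[Motif]:
    """Union over the 27 weight scenarios of each scenario's top-m motifs.

    Ranking per scenario is by descending S_j with deterministic
    lexicographic node-id tie-break.  Fewer motifs than top_m -> all
    selected.  Returns motifs sorted by their identity key.
    """
    if top_m < 1:
        raise ValueError("top_m must be >= 1")
    if len(motifs) <= top_m:
        return sorted(motifs, key=lambda m: m.key)
    selected: dict[tuple, Motif] = {}
    for scenario in WEIGHT_GRID:
        ranked = sorted(
            motifs, key=lambda m: (-score_motif(m, scenario), m.key))
        for m in ranked[:top_m]:
            selected[m.key] = m
    return sorted(selected.values(), key=lambda m: m.key)


@dataclass
class CoreRegulatoryNetwork:
    """Merged graph of the selected motifs for one phenotype."""

    phenotype_id: str
    motifs: list[Motif]
    graph: nx.DiGraph  # node attr "regulation" in {"up", "down", "none"}

    def to_graphml(self, path) -> None:
        from .mim import to_graphml
        to_graphml(self.graph, path)


def build_crn(selected: list[Motif], phenotype_id: str,
              overlay_set: OverlaySet | None = None) -> CoreRegulatoryNetwork:
    """Merge selected motifs into one network, annotated by DEG direction.

    Node annotation ``regulation`` is the sign of the gene's significant
    log2FC in the overlay at the analysis time point, or ``none`` when the
    gene is not a significant DEG there.
    """
    if not selected:
        raise ValueError(
            "no motifs selected; relax top_m or the candidate cap")
    g = nx.DiGraph()
    for m in selected:
        for u, v, sign in m.edges:
            g.add_edge(u, v, sign=sign)
    sig = overlay_set.table if overlay_set is not None else None
    for node in g.nodes:
        regulation = "none"
        if sig is not None and node in sig.index:
            fc = float(sig.at[node, "log2fc"])
            regulation = "up" if fc > 0 else ("down" if fc < 0 else "none")
        g.nodes[node]["regulation"] = regulation
    return CoreRegulatoryNetwork(phenotype_id, list(selected), g)


def motif_table(motifs: list[Motif]) -> pd.DataFrame:
    """Summary table with each motif's best scenario and best score."""
    records = []
    for m in motifs:
        best_s, best_w = -np.inf, None
        if m.norm is not None:
            for scenario in WEIGHT_GRID:
                s = score_motif(m, scenario)
                if s > best_s:
                    best_s, best_w = s, scenario
        records.append({
            "nodes": ";".join(m.nodes),
            "f_influence": m.f_influence,
            "f_enrichment": m.f_enrichment,
            "f_foldchange": m.f_foldchange,
            "best_scenario": (";".join(f"{w:g}" for w in best_w)
                              if best_w else ""),
            "best_score": best_s if best_w else np.nan,
        })
    return pd.DataFrame(records)
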