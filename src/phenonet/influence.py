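"""Signed influence of genes on phenotypes and upstream enrichment scores.

The influence score I(i, p) of gene i on phenotype p is an attenuated sum
over admissible simple directed paths from i to p:

    I(i, p) = sum over simple paths q, len(q) <= D, of sgn(q) * alpha^(len(q)-1)

where sgn(q) is the product of edge signs along q, alpha in (0, 1] the
per-step attenuation, and D the maximum path length in edges.  Paths may not
pass through any phenotype node other than p (phenotypes are readouts, not
conduits), and simple paths -- no node revisited -- keep the sum finite on
feedback-rich maps.

The upstream enrichment score ES(i) of a gene i summarises how strongly
significantly regulated genes feed into i:

    ES(i) = sum over significant g in U_D(i) of |log2FC_g| * alpha^(d(g,i)-1)
            / |U_D(i)|

with U_D(i) the phenotype-free upstream universe of i within depth D and
d(g, i) the shortest admissible path length.  ES(i) = 0 when U_D(i) is empty.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mim import MolecularInteractionMap, upstream_gene_universe


@dataclass(frozen=True)
class InfluenceParams:
    """Attenuation and depth of the path sum.

    alpha: multiplicative damping per extra edge; 1.0 counts raw paths.
    max_depth: longest admissible path, in edges.
    """

    alpha: float = 0.5
    max_depth: int = 5

    def __post_init__(self):
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must be in (0, 1]")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


@dataclass
class InfluenceMatrix:
    """Gene x phenotype signed influence scores.

    ``I`` is a DataFrame indexed by gene id with one column per phenotype;
    genes with no admissible path to a phenotype hold exact 0.
    """

    I: pd.DataFrame
    params: InfluenceParams

    def column(self, phenotype_id: str) -> pd.Series:
        return self.I[phenotype_id]

    def score(self, gene_id: str, phenotype_id: str) -> float:
        if gene_id not in self.I.index:
            return 0.0
        return float(self.I.at[gene_id, phenotype_id])


def _accumulate_reverse_paths(mim: MolecularInteractionMap, phenotype_id: str,
                              params: InfluenceParams) -> dict[str, float]:
    """Depth-first enumeration of simple paths into ``phenotype_id``.

    Walks the reversed graph from the phenotype through gene nodes only.
    Every partial reverse path p <- ... <- v of d edges is a distinct simple
    directed path v -> ... -> p, contributing sgn * alpha^(d-1) to I(v, p).
    """
    genes = mim.genes
    g = mim.graph
    alpha, depth = params.alpha, params.max_depth
    scores: dict[str, float] = {}
    # stack frames: (node, sign product so far, depth, iterator over preds)
    on_path = {phenotype_id}
    stack = [(phenotype_id, 1, 0, iter(g.predecessors(phenotype_id)))]
    while stack:
        node, sign, d, preds = stack[-1]
        advanced = False
        for pred in preds:
            if pred not in genes or pred in on_path:
                continue
            s = sign * g.edges[pred, node]["sign"]
            nd = d + 1
            scores[pred] = scores.get(pred, 0.0) + s * alpha ** (nd - 1)
            if nd < depth:
                on_path.add(pred)
                stack.append((pred, s, nd, iter(g.predecessors(pred))))
                advanced = True
                break
        if not advanced:
            stack.pop()
            on_path.discard(node)
    return scores


def influence_score(mim: MolecularInteractionMap, gene_id: str,
                    phenotype_id: str,
                    params: InfluenceParams | None = None) -> float:
    """I(gene, phenotype) for a single pair.  Absent path -> 0.0."""
    params = params or InfluenceParams()
    if gene_id not in mim.graph or phenotype_id not in mim.graph:
        raise KeyError("gene or phenotype not in map")
    return _accumulate_reverse_paths(mim, phenotype_id, params).get(
        gene_id, 0.0)


def influence_matrix(mim: MolecularInteractionMap,
                     phenotypes: list[str] | None = None,
                     params: InfluenceParams | None = None) -> InfluenceMatrix:
    """Influence scores for every gene upstream of each phenotype.

    Rows cover the union of the phenotypes' upstream universes; entries for
    gene/phenotype pairs with no admissible path are exact zeros.
    """
    params = params or InfluenceParams()
    if phenotypes is None:
        phenotypes = sorted(mim.phenotypes)
    for p in phenotypes:
        if mim.node_class(p) != "phenotype":
            raise ValueError(f"{p!r} is not a phenotype node")
    columns = {p: _accumulate_reverse_paths(mim, p, params)
               for p in phenotypes}
    index = sorted(set().union(*columns.values())) if columns else []
    mat = pd.DataFrame(0.0, index=index, columns=list(phenotypes))
    for p, scores in columns.items():
        for gene, val in scores.items():
            mat.at[gene, p] = val
    return InfluenceMatrix(I=mat, params=params)


def _upstream_distances(mim: MolecularInteractionMap, gene_id: str,
                        max_depth: int) -> dict[str, int]:
    """Shortest phenotype-free reverse-path length from each upstream gene."""
    genes = mim.genes
    g = mim.graph
    dist: dict[str, int] = {}
    queue = deque([(gene_id, 0)])
    seen = {gene_id}
    while queue:
        node, d = queue.popleft()
        if d == max_depth:
            continue
        for pred in g.predecessors(node):
            if pred in genes and pred not in seen:
                seen.add(pred)
                dist[pred] = d + 1
                queue.append((pred, d + 1))
    return dist


def upstream_enrichment(mim: MolecularInteractionMap, gene_id: str,
                        deg_at_time: pd.DataFrame,
                        params: InfluenceParams | None = None,
                        tau: float = 0.05) -> float:
    """ES(gene) from significant upstream genes' absolute fold changes.

    ``deg_at_time`` is indexed by map gene id with columns ``log2fc`` and
    ``padj`` (one contrast, one time point).
    """
    params = params or InfluenceParams()
    if gene_id not in mim.genes:
        raise KeyError(f"{gene_id!r} is not a gene node")
    dist = _upstream_distances(mim, gene_id, params.max_depth)
    if not dist:
        return 0.0
    total = 0.0
    for g, d in dist.items():
        if g not in deg_at_time.index:
            continue
        row = deg_at_time.loc[g]
        if row["padj"] < tau:
            total += abs(row["log2fc"]) * params.alpha ** (d - 1)
    return total / len(dist)


def enrichment_vector(mim: MolecularInteractionMap, genes: list[str],
                      deg_at_time: pd.DataFrame,
                      params: InfluenceParams | None = None,
                      tau: float = 0.05) -> pd.Series:
    """ES(i) for a list of genes, as a Series indexed by gene id."""
    params = params or InfluenceParams()
    return pd.Series(
        {g: upstream_enrichment(mim, g, deg_at_time, params, tau)
         for g in genes},
        dtype=float,
        name="es",
    )


def write_influence(infl: InfluenceMatrix, path) -> None:
    """Long-format TSV export: gene, phenotype, influence."""
    long = (
        infl.I.rename_axis("gene")
        .reset_index()
        .melt(id_vars="gene", var_name="phenotype", value_name="influence")
    )
    long.to_csv(path, sep="\t", index=False)
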