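import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from phenonet import MIMEdge, MIMNode, MolecularInteractionMap

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def build_map(edges, phenotypes=(), submaps=None, phases=None, nodes=()):
    """Construct a small map from (source, target, sign) triples.

    ``phenotypes`` names phenotype-class nodes; everything else is a gene.
    ``nodes`` adds ids not appearing in any edge (isolated genes).
    """
    submaps = submaps or {}
    phases = phases or {}
    node_ids = {u for u, _, _ in edges} | {v for _, v, _ in edges}
    node_ids |= set(phenotypes) | set(nodes)
    nodes = [
        MIMNode(
            id=n,
            node_class="phenotype" if n in phenotypes else "gene",
            submaps=frozenset(submaps.get(n, ())),
            phase=phases.get(n),
        )
        for n in sorted(node_ids)
    ]
    return MolecularInteractionMap(
        nodes, [MIMEdge(u, v, s) for u, v, s in edges])


def random_signed_digraph(rng, n_nodes=8, p_edge=0.3, n_phenotypes=1):
    """Random signed digraph for oracle comparisons; last nodes are
    phenotype sinks."""
    genes = [f"g{i}" for i in range(n_nodes - n_phenotypes)]
    phenos = [f"p{i}" for i in range(n_phenotypes)]
    edges = []
    for u in genes:
        for v in genes + phenos:
            if u != v and rng.random() < p_edge:
                edges.append((u, v, 1 if rng.random() < 0.7 else -1))
    return build_map(edges, phenotypes=phenos, nodes=genes), genes, phenos


def oracle_influence(mim, gene_id, phenotype_id, alpha, max_depth):
    """Independent brute-force influence: exhaustive simple-path
    enumeration via networkx over the admissible subgraph."""
    sub = mim.admissible_subgraph(phenotype_id)
    total = 0.0
    try:
        paths = nx.all_simple_paths(sub, gene_id, phenotype_id,
                                    cutoff=max_depth)
    except nx.NodeNotFound:
        return 0.0
    for path in paths:
        sign = 1
        for u, v in zip(path, path[1:]):
            sign *= sub.edges[u, v]["sign"]
        total += sign * alpha ** (len(path) - 2)
    return total


def deg_frame(rows, contrast="A"):
    """Long DEG table from (time_h, gene, log2fc, padj[, base_mean])."""
    records = []
    for row in rows:
        time_h, gene, log2fc, padj = row[:4]
        base_mean = row[4] if len(row) > 4 else 100.0
        records.append((contrast, time_h, gene, log2fc, padj, base_mean))
    return pd.DataFrame(
        records,
        columns=["contrast", "time_h", "gene", "log2fc", "padj", "base_mean"],
    )


@pytest.fixture
def toy_map():
    """Six-node fixture: a 3-cycle feeding phenotype P, plus an isolated
    branch into phenotype Q."""
    return build_map(
        [
            ("A", "B", 1),
            ("B", "C", -1),
            ("C", "A", 1),
            ("B", "P", -1),
            ("A", "P", 1),
            ("D", "Q", 1),
        ],
        phenotypes=("P", "Q"),
        submaps={"A": {"initiation"}, "B": {"resolution"},
                 "C": {"initiation", "resolution"}, "D": {"metabolism"}},
        phases={"P": "initiation", "Q": "resolution"},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
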