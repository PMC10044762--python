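"""Seeded generators for every input the pipeline consumes.

The generators emulate the *statistical* structure of a time-series
wound-healing transcriptomics study analysed on a curated signed interaction
map -- not its biology:

* a signed scale-free-like gene network with phenotype sink nodes, planted
  regulator modules per phenotype, and planted gene-triplet feedback loops;
* negative-binomial read counts over 2 groups x 7 time points x replicates
  with log-normal library-size variation, planted differential expression
  and planted outlier samples;
* a marker panel of immune cell types with planted coherent shifts;
* optionally, DEG tables generated directly (the pipeline accepts DEG
  tables as first-class input, so benchmarks downstream of DE need not pay
  for count simulation).

Every generator is deterministic given the config seed; the returned ground
truth is sufficient to compute every recovery metric without re-reading the
config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mim import MIMEdge, MIMNode, MolecularInteractionMap

PHASE_CYCLE = ("initiation", "transition", "resolution", "homeostasis")


@dataclass(frozen=True)
class OutlierSpec:
    """One sample to distort: multiply a random fraction of its gene counts
    by ``factor``."""

    group: str
    time_h: int
    replicate: int
    factor: float = 20.0
    gene_fraction: float = 0.3


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic benchmark.

    Defaults mirror the emulated study design: two groups of seven
    replicates sampled at seven post-treatment time points, with treatment
    effects planted at the late 120 h time point.
    """

    seed: int
    n_genes: int = 150
    n_phenotypes: int = 4
    mean_out_degree: float = 2.0
    inhibition_fraction: float = 0.3
    n_planted_motifs: int = 1
    n_decoy_motifs: int = 10
    module_size: int = 8
    module_fc: float = 3.0
    motif_fc: float = 4.0
    extra_phenotype_inputs: int = 3
    time_points: tuple[int, ...] = (12, 24, 36, 72, 96, 120, 192)
    planted_times: tuple[int, ...] = (120,)
    n_replicates: int = 7
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.0
    nb_dispersion: float = 0.05
    dispersion_log_sd: float = 0.5
    libsize_log_sd: float = 0.2
    null_fc_sd: float = 0.25
    planted_fc_noise_sd: float = 0.3
    outliers: tuple[OutlierSpec, ...] = ()
    n_cell_types: int = 13
    markers_per_type: int = 7
    marker_shift: float = 1.5
    n_shifted_cell_types: int = 1

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for name in ("n_genes", "n_phenotypes", "n_replicates",
                     "module_size", "n_cell_types", "markers_per_type"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("inhibition_fraction",):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        needed = (3 * (self.n_planted_motifs + self.n_decoy_motifs)
                  + self.module_size * self.n_phenotypes)
        if needed > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} too small for the planted "
                f"structure ({needed} genes needed)")


@dataclass
class MapTruth:
    """Planted ground truth of a synthetic map."""

    target_phenotype: str
    planted_motifs: list[tuple[str, str, str]] = field(default_factory=list)
    decoy_motifs: list[tuple[str, str, str]] = field(default_factory=list)
    #: phenotype -> (+1 up / -1 down, module gene list)
    modules: dict[str, tuple[int, list[str]]] = field(default_factory=dict)
    #: (gene, time_h) -> planted log2FC in treatment vs control
    planted_fc: dict[tuple[str, int], float] = field(default_factory=dict)


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _sign(rng: np.random.Generator, cfg: SimConfig) -> int:
    return -1 if rng.random() < cfg.inhibition_fraction else 1


def make_map(cfg: SimConfig) -> tuple[MolecularInteractionMap, MapTruth]:
    """Signed scale-free-like gene digraph with phenotype sinks.

    Background edges follow preferential attachment on in-degree (hubs
    emerge early).  On top of the acyclic background, the generator plants
    ``n_planted_motifs`` all-activating 3-cycles whose members directly
    activate the target phenotype and carry the largest fold changes, plus
    ``n_decoy_motifs`` random-signed 3-cycles without planted expression.
    Each phenotype receives a direct activating module of ``module_size``
    genes planted up (even phenotypes) or down (odd), the directional signal
    the enrichment benchmark recovers.
    """
    rng = _rng(cfg, 0)
    genes = [f"G{i:04d}" for i in range(1, cfg.n_genes + 1)]
    phenos = [f"PHENO_{i}" for i in range(1, cfg.n_phenotypes + 1)]

    edges: dict[tuple[str, str], int] = {}
    in_deg = np.zeros(cfg.n_genes)
    for i in range(1, cfg.n_genes):
        k = min(i, rng.poisson(cfg.mean_out_degree))
        if k == 0:
            continue
        weights = in_deg[:i] + 1.0
        targets = rng.choice(i, size=k, replace=False,
                             p=weights / weights.sum())
        for t in targets:
            edges[(genes[i], genes[t])] = _sign(rng, cfg)
            in_deg[t] += 1

    truth = MapTruth(target_phenotype=phenos[0])

    # reserve genes for planted structure (disjoint by construction)
    pool = [str(g) for g in rng.permutation(genes)]

    def take(n: int) -> list[str]:
        return [pool.pop() for _ in range(n)]

    for _ in range(cfg.n_planted_motifs):
        a, b, c = take(3)
        for u, v in ((a, b), (b, c), (c, a)):
            edges[(u, v)] = 1
        for m in (a, b, c):
            edges[(m, phenos[0])] = 1
            for t in cfg.planted_times:
                truth.planted_fc[(m, t)] = cfg.motif_fc
        truth.planted_motifs.append(tuple(sorted((a, b, c))))

    for _ in range(cfg.n_decoy_motifs):
        a, b, c = take(3)
        for u, v in ((a, b), (b, c), (c, a)):
            edges[(u, v)] = _sign(rng, cfg)
        edges[(a, phenos[rng.integers(cfg.n_phenotypes)])] = _sign(rng, cfg)
        truth.decoy_motifs.append(tuple(sorted((a, b, c))))

    for k, p in enumerate(phenos):
        direction = 1 if k % 2 == 0 else -1
        module = take(cfg.module_size)
        for m in module:
            edges[(m, p)] = 1
            for t in cfg.planted_times:
                truth.planted_fc[(m, t)] = direction * cfg.module_fc
        truth.modules[p] = (direction, module)
        extras = rng.choice(
            [g for g in genes if (g, p) not in edges],
            size=cfg.extra_phenotype_inputs, replace=False)
        for g in extras:
            edges[(str(g), p)] = _sign(rng, cfg)

    submap_of = {g: PHASE_CYCLE[rng.integers(len(PHASE_CYCLE))]
                 for g in genes}
    nodes = [MIMNode(id=g, label=g, node_class="gene",
                     submaps=frozenset({submap_of[g]})) for g in genes]
    nodes += [
        MIMNode(id=p, label=p, node_class="phenotype",
                submaps=frozenset({PHASE_CYCLE[i % len(PHASE_CYCLE)]}),
                phase=PHASE_CYCLE[i % len(PHASE_CYCLE)])
        for i, p in enumerate(phenos)
    ]
    mim = MolecularInteractionMap(
        nodes, [MIMEdge(u, v, s) for (u, v), s in edges.items()])
    return mim, truth


def make_deg_table(cfg: SimConfig, truth_fc: dict[tuple[str, int], float],
                   genes: list[str],
                   contrast: str = "treatment_vs_control",
                   stream: int = 1) -> pd.DataFrame:
    """DEG table generated directly from planted fold changes.

    Null genes get log2FC ~ N(0, null_fc_sd) with uniform adjusted
    p-values; planted (gene, time) entries get the target FC plus noise and
    small padj.  Base means are log-normal per gene, inflated by induction
    at planted times so the induction filter has signal to find.
    """
    rng = _rng(cfg, stream)
    baseline = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd,
                             size=len(genes))
    records = []
    for t in cfg.time_points:
        fc = rng.normal(0.0, cfg.null_fc_sd, size=len(genes))
        padj = rng.uniform(0.0, 1.0, size=len(genes))
        base = baseline * np.exp(rng.normal(0.0, 0.1, size=len(genes)))
        for i, g in enumerate(genes):
            planted = truth_fc.get((g, t))
            if planted is not None:
                fc[i] = planted + rng.normal(0.0, cfg.planted_fc_noise_sd)
                padj[i] = 10.0 ** -rng.uniform(2.0, 6.0)
                base[i] *= 2.0 ** (abs(planted) / 2.0)
        for i, g in enumerate(genes):
            records.append((contrast, t, g, fc[i], padj[i], base[i]))
    return pd.DataFrame(
        records,
        columns=["contrast", "time_h", "gene", "log2fc", "padj", "base_mean"],
    )


def make_counts(cfg: SimConfig, genes: list[str],
                truth_fc: dict[tuple[str, int], float] | None = None,
                contrast: str = "treatment_vs_control",
                stream: int = 2,
                ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count matrix with planted DE and outliers.

    Counts are NB(mean = baseline * libsize * 2^FC, gene-wise dispersion)
    with FC applied in the treatment group at planted times only.  Returns
    (counts genes x samples, metadata, truth table of planted FCs).
    """
    rng = _rng(cfg, stream)
    truth_fc = truth_fc or {}
    n = len(genes)
    baseline = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd,
                             size=n)
    dispersion = rng.lognormal(np.log(cfg.nb_dispersion),
                               cfg.dispersion_log_sd, size=n)
    nb_n = 1.0 / dispersion

    columns, meta = {}, []
    for group in ("treatment", "control"):
        for t in cfg.time_points:
            fc = np.zeros(n)
            if group == "treatment":
                for i, g in enumerate(genes):
                    fc[i] = truth_fc.get((g, t), 0.0)
            for rep in range(1, cfg.n_replicates + 1):
                sample = f"{contrast}_{group[0]}{t}h_r{rep}"
                lib = rng.lognormal(0.0, cfg.libsize_log_sd)
                mu = baseline * lib * 2.0 ** fc
                counts = rng.negative_binomial(nb_n, nb_n / (nb_n + mu))
                for spec in cfg.outliers:
                    if (spec.group == group and spec.time_h == t
                            and spec.replicate == rep):
                        hit = rng.random(n) < spec.gene_fraction
                        counts = np.where(
                            hit, np.round(counts * spec.factor), counts)
                columns[sample] = counts.astype(np.int64)
                meta.append({
                    "sample": sample, "contrast": contrast, "group": group,
                    "time_h": t, "replicate": rep,
                })
    counts = pd.DataFrame(columns, index=pd.Index(genes, name="gene"))
    metadata = pd.DataFrame(meta)
    truth = pd.DataFrame(
        [(g, t, v) for (g, t), v in sorted(truth_fc.items())],
        columns=["gene", "time_h", "log2fc"],
    )
    return counts, metadata, truth


def make_marker_panel(cfg: SimConfig, genes: list[str],
                      exclude: set[str] = frozenset(),
                      stream: int = 3,
                      ) -> tuple[dict[str, set[str]],
                                 dict[tuple[str, int], float]]:
    """Disjoint marker sets per cell type, with planted coherent shifts.

    The first ``n_shifted_cell_types`` cell types carry a planted
    ``marker_shift`` log2FC on every marker at the planted times; returns
    (panel, planted FC entries) so the shift can be fed to
    :func:`make_counts` or :func:`make_deg_table`.
    """
    rng = _rng(cfg, stream)
    available = [g for g in genes if g not in exclude]
    needed = cfg.n_cell_types * cfg.markers_per_type
    if needed > len(available):
        raise ValueError(
            f"need {needed} marker genes, only {len(available)} available")
    chosen = [str(g) for g in rng.choice(available, size=needed,
                                         replace=False)]
    panel: dict[str, set[str]] = {}
    planted: dict[tuple[str, int], float] = {}
    for i in range(cfg.n_cell_types):
        name = f"cell_type_{i + 1:02d}"
        markers = set(chosen[i * cfg.markers_per_type:
                             (i + 1) * cfg.markers_per_type])
        panel[name] = markers
        if i < cfg.n_shifted_cell_types:
            for m in markers:
                for t in cfg.planted_times:
                    planted[(m, t)] = cfg.marker_shift
    return panel, planted
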