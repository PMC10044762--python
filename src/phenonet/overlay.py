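"""Mapping DEG tables onto the interaction map and comparing contrasts.

An overlay intersects a contrast's significant genes at each time point with
the map's gene nodes (optionally restricted to submaps).  Two contrasts'
overlays are then split into unique / common sets, with the common set
further screened for genes regulated in opposite directions -- the key
read-out when comparing treatments with different modes of action.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mim import MolecularInteractionMap, submap_genes

logger = logging.getLogger(__name__)


@dataclass
class OverlaySet:
    """Significant mapped genes for one (contrast, time point).

    ``table`` holds the significant genes (padj < tau) indexed by map node
    id with columns log2fc, padj; ``measured`` holds every mapped measured
    gene at this time point regardless of significance (the permutation
    null shuffles over these).
    """

    contrast: str
    time_h: int
    table: pd.DataFrame
    measured: pd.DataFrame
    n_unmapped: int = 0

    @property
    def genes(self) -> set[str]:
        return set(self.table.index)


@dataclass
class VennSplit:
    """Unique/common/opposite split of two contrasts' mapped DEGs."""

    unique_a: set[str] = field(default_factory=set)
    unique_b: set[str] = field(default_factory=set)
    common: set[str] = field(default_factory=set)
    opposite: set[str] = field(default_factory=set)
    #: True for opposite calls made without a shared significant time point
    #: (sign comparison of each contrast's max-|log2FC| significant estimate).
    fallback_rule_used: set[str] = field(default_factory=set)

    @property
    def opposite_fraction(self) -> float:
        """|opposite| / |common|; the share of shared DEGs regulated in
        opposite directions by the two treatments."""
        return opposite_fraction(len(self.common), len(self.opposite))

    def to_json(self, path: str | Path) -> None:
        payload = {
            key: {"count": len(genes), "genes": sorted(genes)}
            for key, genes in (
                ("unique_a", self.unique_a), ("unique_b", self.unique_b),
                ("common", self.common), ("opposite", self.opposite))
        }
        payload["opposite_fraction"] = (
            self.opposite_fraction if self.common else None)
        payload["fallback_rule_used"] = sorted(self.fallback_rule_used)
        Path(path).write_text(json.dumps(payload, indent=2))


def opposite_fraction(n_common: int, n_opposite: int) -> float:
    """Fraction of common DEGs with opposing regulation, in [0, 1]."""
    if n_opposite > n_common:
        raise ValueError("opposite count cannot exceed common count")
    if n_common == 0:
        return float("nan")
    return n_opposite / n_common


def overlay(mim: MolecularInteractionMap, deg_table: pd.DataFrame,
            contrast: str, tau: float = 0.05,
            submap_filter: set[str] | None = None) -> dict[int, OverlaySet]:
    """Per-time-point overlay of a contrast's DEGs onto the map.

    Returns a dict time_h -> OverlaySet.  Genes are matched to map nodes
    case-insensitively; unmatched measured genes are counted, not fatal.
    """
    sub = deg_table[deg_table["contrast"] == contrast]
    if sub.empty:
        raise ValueError(f"no rows for contrast {contrast!r}")
    allowed: set[str] | None = None
    if submap_filter is not None:
        allowed = submap_genes(mim, submap_filter)
    out: dict[int, OverlaySet] = {}
    for time_h, rows in sub.groupby("time_h"):
        mapped_ids = rows["gene"].map(mim.resolve_symbol)
        n_unmapped = int(mapped_ids.isna().sum())
        rows = rows.assign(node=mapped_ids).dropna(subset=["node"])
        # keep gene-class nodes only; phenotype labels can collide with symbols
        rows = rows[rows["node"].isin(mim.genes)]
        if allowed is not None:
            rows = rows[rows["node"].isin(allowed)]
        measured = (rows.set_index("node")[["log2fc", "padj"]]
                    .sort_index())
        sig = measured[measured["padj"] < tau]
        if n_unmapped:
            logger.info(
                "%s @ %s h: %d measured gene(s) not on the map",
                contrast, time_h, n_unmapped,
            )
        out[int(time_h)] = OverlaySet(
            contrast=contrast, time_h=int(time_h), table=sig,
            measured=measured, n_unmapped=n_unmapped,
        )
    return out


def _significant_profiles(overlays: dict[int, OverlaySet]) -> dict[str, dict[int, float]]:
    """gene -> {time_h: log2fc} over significant calls."""
    prof: dict[str, dict[int, float]] = {}
    for time_h, ov in overlays.items():
        for gene, row in ov.table.iterrows():
            prof.setdefault(gene, {})[time_h] = float(row["log2fc"])
    return prof


def venn_split(overlays_a: dict[int, OverlaySet],
               overlays_b: dict[int, OverlaySet]) -> VennSplit:
    """Unique/common split across all time points, plus opposite calls.

    A gene is unique to A when significant at some time in A and at no time
    in B; common when significant in both contrasts (not necessarily at the
    same time).  A common gene is opposite when some shared time point has
    both contrasts significant with opposing log2FC signs or, lacking any
    shared significant time point, when the two contrasts' maximum-|log2FC|
    significant estimates disagree in sign (recorded in
    ``fallback_rule_used``).
    """
    prof_a = _significant_profiles(overlays_a)
    prof_b = _significant_profiles(overlays_b)
    if not prof_a and not prof_b:
        logger.warning("both overlays empty; venn split is empty")
    genes_a, genes_b = set(prof_a), set(prof_b)
    split = VennSplit(
        unique_a=genes_a - genes_b,
        unique_b=genes_b - genes_a,
        common=genes_a & genes_b,
    )
    for gene in split.common:
        fa, fb = prof_a[gene], prof_b[gene]
        shared = set(fa) & set(fb)
        if shared:
            if any(np.sign(fa[t]) * np.sign(fb[t]) < 0 for t in shared):
                split.opposite.add(gene)
        else:
            peak_a = max(fa.values(), key=abs)
            peak_b = max(fb.values(), key=abs)
            if np.sign(peak_a) * np.sign(peak_b) < 0:
                split.opposite.add(gene)
                split.fallback_rule_used.add(gene)
    return split


def induction_filter(deg_table: pd.DataFrame, contrast: str,
                     focal_time: int = 120, tau: float = 0.05) -> set[str]:
    """Genes truly induced at the focal time point.

    Keeps genes that are significant and upregulated at ``focal_time`` and
    whose base-mean read count there strictly exceeds the base mean at every
    earlier time point -- separating genuine late induction from relative
    shifts caused by the control.  Genes lacking a base mean at some earlier
    time are excluded (the comparison is unavailable).
    """
    sub = deg_table[deg_table["contrast"] == contrast]
    times = sorted(sub["time_h"].unique())
    if focal_time not in times:
        raise ValueError(f"focal time {focal_time} h absent for {contrast!r}")
    earlier = [t for t in times if t < focal_time]
    if not earlier:
        raise ValueError("no time point earlier than the focal time")
    base = sub.pivot_table(index="gene", columns="time_h",
                           values="base_mean", aggfunc="first")
    focal = sub[sub["time_h"] == focal_time]
    candidates = focal[(focal["padj"] < tau) & (focal["log2fc"] > 0)]["gene"]
    selected: set[str] = set()
    for gene in candidates:
        row = base.loc[gene, earlier + [focal_time]]
        if row.isna().any():
            logger.warning(
                "gene %s lacks base_mean at some earlier time; excluded",
                gene,
            )
            continue
        if (row[focal_time] > row[earlier]).all():
            selected.add(gene)
    return selected
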