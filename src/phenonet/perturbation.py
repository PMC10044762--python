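"""In-silico node perturbations propagated to phenotype levels.

A perturbation assigns +1 (forced up) or -1 (forced down) to a set of genes;
the predicted phenotype level is the linear superposition of the perturbed
genes' influence scores,

    L_p = sum over perturbed genes g of I(g, p) * v_g.

Linear superposition is a deliberate modeling simplification: it reports a
static predicted level (no fixed-point or Boolean dynamics), is exactly
additive over disjoint perturbation sets, and antisymmetric under sign flip.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .influence import InfluenceMatrix
from .mim import MolecularInteractionMap

logger = logging.getLogger(__name__)


def validate_spec(mim: MolecularInteractionMap,
                  assignments: dict[str, int]) -> dict[str, int]:
    """Check a gene -> {+1, -1} perturbation spec against the map."""
    if not assignments:
        raise ValueError("perturbation spec must be non-empty")
    out: dict[str, int] = {}
    for gene, value in assignments.items():
        if value not in (1, -1):
            raise ValueError(
                f"perturbation value for {gene!r} must be +1 or -1, "
                f"got {value!r}")
        node = mim.resolve_symbol(gene)
        if node is None or node not in mim.genes:
            raise KeyError(f"perturbed gene {gene!r} not on the map")
        out[node] = value
    return out


def perturb(mim: MolecularInteractionMap, infl: InfluenceMatrix,
            assignments: dict[str, int]) -> pd.DataFrame:
    """Predicted phenotype levels after a +/-1 perturbation.

    Returns a DataFrame (phenotype, level, level_norm, direction) where
    level_norm is level / max |level| (all-zero -> 0) and direction is
    "up", "down" or "none".  Genes outside every influence universe
    contribute 0 with a warning.
    """
    spec = validate_spec(mim, assignments)
    phenos = list(infl.I.columns)
    level = np.zeros(len(phenos))
    for gene, value in spec.items():
        if gene not in infl.I.index:
            logger.warning(
                "perturbed gene %s is upstream of no phenotype; contributes 0",
                gene,
            )
            continue
        level += value * infl.I.loc[gene, phenos].to_numpy()
    peak = np.max(np.abs(level)) if level.size else 0.0
    norm = level / peak if peak > 0 else np.zeros_like(level)
    direction = np.where(level > 0, "up", np.where(level < 0, "down", "none"))
    return pd.DataFrame({
        "phenotype": phenos,
        "level": level,
        "level_norm": norm,
        "direction": direction,
    })


def perturbation_report(levels: pd.DataFrame,
                        phase_annotation: dict[str, str | None]) -> pd.DataFrame:
    """Phase-grouped signed phenotype levels (radial-layout order)."""
    rows = levels.copy()
    rows["phase"] = rows["phenotype"].map(
        lambda p: phase_annotation.get(p) or "unassigned")
    return (rows[["phase", "phenotype", "level", "level_norm", "direction"]]
            .sort_values(["phase", "phenotype"])
            .reset_index(drop=True))


def read_spec(path: str | Path) -> dict[str, int]:
    """Read a JSON perturbation spec {gene: +1 or -1}."""
    data = json.loads(Path(path).read_text())
    return {str(k): int(v) for k, v in data.items()}


def parse_spec_string(text: str) -> dict[str, int]:
    """Parse 'Fpr2:+1,Ddx58:-1' style CLI perturbation specs."""
    out: dict[str, int] = {}
    for item in text.split(","):
        gene, _, value = item.partition(":")
        if not value:
            raise ValueError(f"malformed assignment {item!r} (want gene:+1)")
        out[gene.strip()] = int(value)
    return out
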